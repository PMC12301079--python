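"""ROC construction, AUC/U equivalence, optimal threshold, significance
tests and the permutation Spearman correlation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pairwise
from psqa import (
    QARecord,
    ROCStudy,
    analyze_roc,
    auc,
    auc_significance,
    label_ground_truth,
    optimal_threshold,
    roc_curve,
    run_roc_study,
    spearman_permutation,
)
from psqa.exceptions import (
    DegenerateLabelsError,
    UndefinedCorrelationError,
    ValidationError,
)


def rec(gpr=90.0, d_calc=2.0, d_meas=2.0, mode="cumulative", uid="u"):
    return QARecord(unit_id=uid, mode=mode, gpr_by_criteria={"2%/1mm": gpr},
                    d_calc=d_calc, d_meas=d_meas)


class TestGroundTruth:
    @pytest.mark.parametrize(
        "d_meas,level,delta,label",
        [
            (2.030, 3.0, 1.5, "pass"),
            (2.080, 3.0, 4.0, "fail"),
            # boundary |delta| == level passes (exactly representable inputs)
            (2.500, 25.0, 25.0, "pass"),
            (1.500, 25.0, -25.0, "pass"),
            (1.900, 3.0, -5.0, "fail"),
        ],
    )
    def test_labelling(self, d_meas, level, delta, label):
        lab = label_ground_truth(rec(d_meas=d_meas), level)
        assert lab.delta_percent == pytest.approx(delta)
        assert lab.label == label

    def test_nonpositive_calc_dose_rejected(self):
        with pytest.raises(ValidationError):
            rec(d_calc=0.0)


class TestROCCurve:
    def test_separable_pair(self):
        roc = roc_curve([90.0, 99.0], [True, False])
        # at threshold 95 (i.e. the step at 99): sens 1, 1-spec 0
        i = np.where(roc.thresholds == 99.0)[0][0]
        assert roc.sensitivity[i] == 1.0
        assert roc.one_minus_specificity[i] == 0.0

    def test_endpoints_span_unit_square(self):
        roc = roc_curve([50.0, 60.0, 100.0], [True, False, False])
        assert roc.sensitivity[0] == 0.0
        assert roc.one_minus_specificity[0] == 0.0
        assert roc.sensitivity[-1] == 1.0
        assert roc.one_minus_specificity[-1] == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0, 100, 30)
        f = rng.random(30) < 0.4
        roc = roc_curve(g, f)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.one_minus_specificity) >= 0)

    def test_six_records_hand_enumerated(self):
        gprs = [70.0, 80.0, 85.0, 90.0, 95.0, 99.0]
        fails = [True, True, False, True, False, False]
        roc = roc_curve(gprs, fails)
        # brute-force confusion tables at every threshold
        for t, sens, fpr in zip(roc.thresholds, roc.sensitivity,
                                roc.one_minus_specificity):
            tp = sum(g < t and f for g, f in zip(gprs, fails))
            fp = sum(g < t and not f for g, f in zip(gprs, fails))
            assert sens == tp / 3
            assert fpr == fp / 3

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1.0, 2.0], [True, True])


class TestAUC:
    def test_perfect_separation(self):
        roc = analyze_roc([10.0, 20.0, 90.0, 95.0],
                          [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_ties_is_half(self):
        roc = analyze_roc([90.0] * 6, [True, True, False, False, False, True])
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            g = np.round(rng.uniform(0, 100, n), 1)
            f = rng.random(n) < 0.5
            if f.all() or not f.any():
                continue
            assert auc(roc_curve(g, f)) == pytest.approx(
                auc_pairwise(g, f), abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(9)
        g = rng.uniform(0, 100, 20)
        f = rng.random(20) < 0.5
        assert auc(roc_curve(g, f)) == pytest.approx(
            1.0 - auc(roc_curve(g, ~f)), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        g = rng.uniform(1, 99, 15)
        f = np.array([True] * 7 + [False] * 8)
        a1 = analyze_roc(g, f)
        a2 = analyze_roc(np.sqrt(g) * 10, f)  # strictly monotone rescale
        assert a2.auc == pytest.approx(a1.auc, abs=1e-12)
        assert a2.p_value == pytest.approx(a1.p_value, abs=1e-12)


class TestOptimalThreshold:
    def test_separable_pair_midpoint(self):
        roc = analyze_roc([90.0, 99.0], [True, False])
        assert roc.opth == pytest.approx(94.5)

    def test_degenerate_ties_prefer_specificity_then_low_threshold(self):
        # GPR carries no information: every point is distance 1 from (0,1);
        # the tie-break keeps the highest-specificity point (0,0), then the
        # lowest threshold reaching it
        roc = roc_curve([50.0, 50.0], [True, False])
        assert optimal_threshold(roc) == 0.0

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(5)
        g = np.round(rng.uniform(40, 100, 10), 1)
        f = np.array([True] * 4 + [False] * 6)
        roc = roc_curve(g, f)
        dist = np.hypot(1 - roc.sensitivity, roc.one_minus_specificity)
        best = dist.min()
        t = optimal_threshold(roc)
        # the reported midpoint classifies identically to some argmin point
        pred = g < t
        tp = (pred & f).sum() / f.sum()
        fp = (pred & ~f).sum() / (~f).sum()
        assert np.hypot(1 - tp, fp) == pytest.approx(best, abs=1e-12)


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        p = auc_significance([1, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3)
        assert p >= 0.99

    def test_exact_small_sample(self):
        # {1,2,3} fail vs {4,5,6} pass: exact two-sided p = 0.1
        p = auc_significance([1, 2, 3, 4, 5, 6], [True] * 3 + [False] * 3)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_fully_separated_10v10_exact_tail(self):
        g = list(range(10)) + list(range(20, 30))
        f = [True] * 10 + [False] * 10
        p = auc_significance(g, f)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_degenerate_classes_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc_significance([1.0, 2.0], [True, True])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_auc_equals_normalized_mannwhitney_U(seed):
    """Trapezoidal AUC over the step ROC == U/(n1*n2) with ties counted 0.5."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 25))
    # discrete doses force ties with non-trivial probability
    g = rng.choice(np.arange(0, 101, 5.0), n)
    f = rng.random(n) < rng.uniform(0.2, 0.8)
    if f.all() or not f.any():
        return
    assert auc(roc_curve(g, f)) == pytest.approx(auc_pairwise(g, f),
                                                 abs=1e-12)


class TestSpearmanPermutation:
    def test_monotone_gives_r_one(self):
        res = spearman_permutation([1, 2, 3, 4, 5], [2, 4, 9, 16, 30],
                                   seed=0)
        assert res.r_s == pytest.approx(1.0)
        assert res.exact  # n <= 7 enumerates all permutations

    def test_exact_enumeration_n4(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        res = spearman_permutation(x, y)
        # enumerate all 24 rank permutations by hand
        rx = np.array([1, 2, 3, 4], dtype=float)
        ry = np.array([1, 3, 2, 4], dtype=float)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        r_obs = corr(rx, ry)
        count = sum(
            abs(corr(rx, ry[list(p)])) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res.n_perm == 24
        assert res.p_perm == pytest.approx(count / 24)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_permutation([1, 1, 1, 1, 1, 1, 1, 1],
                                 [1, 2, 3, 4, 5, 6, 7, 8], seed=0)

    def test_independent_inputs_rarely_significant(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            res = spearman_permutation(x, y, n_perm=400, seed=s)
            hits += res.p_perm <= 0.05
        assert hits <= 10

    def test_permutation_p_has_floor(self):
        x = np.arange(20.0)
        res = spearman_permutation(x, x, n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1 / 1000)


class TestStudy:
    def make_records(self, n=24, seed=0, mode="cumulative"):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            delta = rng.normal(0, 2.5)
            gpr = float(np.clip(100 - 8 * abs(delta) - rng.normal(0, 3),
                                0, 100))
            records.append(QARecord(
                unit_id=f"u{i}", mode=mode,
                gpr_by_criteria={"3%/2mm": min(gpr + 5, 100.0),
                                 "2%/1mm": gpr},
                d_calc=10.0, d_meas=10.0 * (1 + delta / 100)))
        return records

    def test_row_count_per_mode(self):
        records = self.make_records() + self.make_records(mode="field_by_field",
                                                          seed=1)
        table = run_roc_study(records, levels=(1, 2, 3, 4, 5))
        assert len(table) == 2 * 2 * 5  # modes x criteria x levels
        assert set(table["mode"]) == {"cumulative", "field_by_field"}

    def test_all_pass_cohort_flagged_undefined(self):
        records = [rec(gpr=90 + i, uid=f"u{i}") for i in range(6)]
        table = run_roc_study(records, levels=(5.0,))
        assert not table["defined"].any()
        assert table["auc"].isna().all()

    def test_study_results_roundtrip_dataframe(self):
        records = self.make_records()
        study = ROCStudy(records, levels=(2.0, 3.0))
        res = study.fit()
        assert len(res.table) == 2 * 2
        row = res.table.iloc[0]
        roc = res.roc(row["mode"], row["criteria"], row["level_percent"])
        assert roc.auc == pytest.approx(row["auc"])
        text = res.summary()
        assert "cumulative" in text and "AUC" in text

    def test_from_dataframe_matches_direct(self):
        import pandas as pd

        records = self.make_records(n=12)
        rows = []
        for r in records:
            for crit, gpr in r.gpr_by_criteria.items():
                rows.append(dict(unit_id=r.unit_id, mode=r.mode,
                                 criteria=crit, gpr=gpr, d_calc=r.d_calc,
                                 d_meas=r.d_meas))
        study = ROCStudy.from_dataframe(pd.DataFrame(rows), levels=(3.0,))
        t1 = study.fit().table
        t2 = ROCStudy(records, levels=(3.0,)).fit().table
        pd.testing.assert_frame_equal(t1, t2)
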
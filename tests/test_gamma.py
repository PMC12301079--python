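"""Gamma engine: analytic cases, oracle agreement, and invariants."""

import numpy as np
import pytest

from oracles import gamma_brute
from psqa import (
    DoseGrid,
    FieldModel,
    GammaCriteria,
    MeasurementSet,
    STANDARD_CRITERIA,
    gamma_passing_rate,
    gamma_point,
    gamma_sweep,
    planar_layout,
    simulate_field,
    simulate_measurement,
)
from psqa.exceptions import (
    EmptyAnalysisError,
    OutOfBoundsError,
    ValidationError,
)


def uniform_grid(dose, half=10.0, spacing=1.0):
    n = int(2 * half / spacing) + 1
    return DoseGrid([-half, -half], [spacing, spacing],
                    np.full((n, n), dose))


class TestGammaPoint:
    def test_identity_is_zero(self, small_field):
        g = gamma_point([0.0, 0.0], float(small_field.sample([[0.0, 0.0]])[0]),
                        small_field, GammaCriteria(3, 2))
        assert g == pytest.approx(0.0, abs=1e-9)

    def test_uniform_dose_offset_analytic(self):
        # evaluated uniformly 2.09 Gy, reference 2.00 Gy, DD 3% of 2 Gy:
        # spatial term minimized to zero, dose term 0.09/0.06 = 1.5
        grid = uniform_grid(2.09)
        g = gamma_point([0, 0], 2.00, grid,
                        GammaCriteria(3, 2, norm_dose=2.0))
        assert g == pytest.approx(1.5, abs=1e-9)

    def test_1d_gradient_matches_dense_bruteforce(self):
        # D(x) = 1 + 0.02 x Gy, reference 1.03 Gy at x = 0, 3%/2mm, norm 1 Gy
        x = np.arange(-21.0, 22.0)
        vals = np.maximum(1 + 0.02 * x, 0)[:, None] * np.ones((1, 5))
        grid = DoseGrid([x[0], -2.0], [1.0, 1.0], vals)
        g = gamma_point([0.0, 0.0], 1.03, grid,
                        GammaCriteria(3, 2, norm_dose=1.0))
        xs = np.arange(-6.0, 6.0, 0.001)
        oracle = np.sqrt(xs**2 / 4 + (1 + 0.02 * xs - 1.03) ** 2 / 0.03**2).min()
        assert g == pytest.approx(oracle, abs=1e-3)

    def test_point_outside_inflated_bounds_rejected(self):
        grid = uniform_grid(1.0, half=5.0)
        with pytest.raises(OutOfBoundsError):
            gamma_point([20.0, 0.0], 1.0, grid,
                        GammaCriteria(3, 2, norm_dose=1.0))

    def test_zero_norm_rejected(self):
        grid = uniform_grid(1.0)
        with pytest.raises(Exception, match="[Nn]ormalization"):
            gamma_point([0, 0], 1.0, grid,
                        GammaCriteria(3, 2, norm_dose=0.0))


class TestPassingRate:
    def test_exact_match_gives_100(self, small_field, exact_measurement):
        res = gamma_passing_rate(exact_measurement, small_field,
                                 GammaCriteria(3, 2))
        assert res.gpr_percent == 100.0
        assert np.all(res.per_point_gamma <= 1e-9)

    def test_threshold_excludes_low_dose_points(self, small_field):
        ms = simulate_measurement(small_field, planar_layout(5.0, 25.0),
                                  np.zeros(2), 0.0, 0.0, seed=0)
        res = gamma_passing_rate(ms, small_field, GammaCriteria(3, 2))
        norm = res.norm_dose_used
        expected = ms.doses >= 0.10 * norm
        np.testing.assert_array_equal(res.included_mask, expected)
        assert expected.sum() < len(ms)  # the layout does reach low dose
        assert len(res.per_point_gamma) == expected.sum()

    def test_all_points_below_threshold_is_an_error(self, small_field):
        ms = MeasurementSet(positions=[[30.0, 30.0], [32.0, 30.0]],
                            doses=[0.01, 0.02])
        with pytest.raises(EmptyAnalysisError):
            gamma_passing_rate(ms, small_field, GammaCriteria(3, 2))

    def test_flat_field_pure_scale_error(self):
        # 2% uniform scale error, no shift: gamma = 2/DD everywhere, so
        # 3%/1mm passes everywhere and 1%/1mm fails everywhere (interior)
        eval_grid = uniform_grid(1.0, half=15.0)
        pts = [[float(x), float(y)] for x in range(-5, 6, 2)
               for y in range(-5, 6, 2)]
        ms = MeasurementSet(positions=pts, doses=[1.02] * len(pts))
        res3 = gamma_passing_rate(ms, eval_grid, GammaCriteria(3, 1))
        res1 = gamma_passing_rate(ms, eval_grid, GammaCriteria(1, 1))
        assert res3.gpr_percent == 100.0
        assert res1.gpr_percent == 0.0
        np.testing.assert_allclose(res3.per_point_gamma, 2 / 3, atol=1e-6)
        np.testing.assert_allclose(res1.per_point_gamma, 2.0, atol=1e-6)

    def test_rigid_subcriterion_shift_passes(self, small_field):
        # pure translation below DTA: every gamma <= s/DTA < 1, GPR = 100
        shift = np.array([0.6, -0.3])
        s = np.linalg.norm(shift)
        ms = simulate_measurement(small_field, planar_layout(5.0, 12.0),
                                  shift, 0.0, 0.0, seed=0)
        res = gamma_passing_rate(ms, small_field, GammaCriteria(3, 1))
        assert res.gpr_percent == 100.0
        assert np.all(res.per_point_gamma <= s / 1.0 + 0.01)

    def test_global_with_point_norm_equals_local(self, small_field):
        ms = simulate_measurement(small_field, planar_layout(8.0, 8.0),
                                  np.array([1.0, 0.5]), 0.02, 0.0, seed=1)
        local = gamma_passing_rate(
            ms, small_field, GammaCriteria(2, 1, normalization="local"))
        # all reference points share a dose only on a flat phantom; check
        # the per-point reduction instead: global with norm = that point's
        # dose reproduces the local gamma
        for i in np.flatnonzero(local.included_mask)[:5]:
            g = gamma_point(ms.positions[i], ms.doses[i], small_field,
                            GammaCriteria(2, 1, norm_dose=float(ms.doses[i])))
            j = int(np.flatnonzero(local.included_mask).tolist().index(i))
            assert g == pytest.approx(local.per_point_gamma[j], abs=1e-9)


class TestSweep:
    def test_identical_distributions_all_criteria_100(self, small_field,
                                                      exact_measurement):
        results = gamma_sweep(exact_measurement, small_field,
                              STANDARD_CRITERIA)
        assert [r.gpr_percent for r in results] == [100.0] * 6
        assert [r.criteria.label for r in results] == [
            "3%/2mm", "2%/2mm", "1%/2mm", "3%/1mm", "2%/1mm", "1%/1mm"]

    def test_criteria_nesting_monotonicity(self, small_field):
        ms = simulate_measurement(small_field, planar_layout(5.0, 12.0),
                                  np.array([1.2, 0.8]), 0.015, 0.005, seed=7)
        gpr = {r.criteria.label: r.gpr_percent
               for r in gamma_sweep(ms, small_field, STANDARD_CRITERIA)}
        assert gpr["3%/2mm"] >= gpr["2%/2mm"] >= gpr["1%/2mm"]
        assert gpr["3%/1mm"] >= gpr["2%/1mm"] >= gpr["1%/1mm"]
        for dd in ("3%", "2%", "1%"):
            assert gpr[f"{dd}/2mm"] >= gpr[f"{dd}/1mm"]

    def test_shared_threshold_shares_included_mask(self, small_field):
        ms = simulate_measurement(small_field, planar_layout(5.0, 22.0),
                                  np.zeros(2), 0.0, 0.0, seed=0)
        results = gamma_sweep(ms, small_field, STANDARD_CRITERIA)
        for r in results[1:]:
            np.testing.assert_array_equal(r.included_mask,
                                          results[0].included_mask)

    def test_empty_criteria_list_rejected(self, small_field,
                                          exact_measurement):
        with pytest.raises(ValidationError):
            gamma_sweep(exact_measurement, small_field, [])


class TestOracleAgreement:
    """Production search vs the independent dense-search oracle."""

    def test_steep_penumbra_with_shift(self):
        field = simulate_field(FieldModel(size_mm=30, penumbra_mm=4,
                                          dose_max_gy=10, margin_mm=10))
        ms = simulate_measurement(field, planar_layout(6.0, 18.0),
                                  np.array([3.0, 0.0]), 0.0, 0.0, seed=0)
        crit = GammaCriteria(2, 1)
        res = gamma_passing_rate(ms, field, crit)
        norm = res.norm_dose_used
        included = np.flatnonzero(res.included_mask)
        assert np.array_equal(res.included_mask,
                              ms.doses >= 0.10 * norm)
        delta_d = crit.dd_percent / 100 * norm
        for j, i in enumerate(included):
            oracle = gamma_brute(field, ms.positions[i], ms.doses[i],
                                 delta_d, crit.dta_mm)
            assert res.per_point_gamma[j] == pytest.approx(oracle, abs=1e-3)
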
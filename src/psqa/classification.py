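"""Ground-truth labelling, ROC analysis of gamma passing rates, and
rank-correlation testing.

The classification question: does the gamma passing rate (GPR), thresholded
at some cutoff, detect plans whose calculated and measured absolute dose at
the isocenter disagree by more than a stated level?  The *positive* class
is ground-truth **fail** (QA should catch bad plans) and a unit is
test-positive when its GPR falls strictly *below* the threshold, so

* sensitivity  = #(GPR < t among GT-fail) / #GT-fail,
* 1-specificity = #(GPR < t among GT-pass) / #GT-pass.

The curve is the exact step function obtained by sweeping the threshold
over 0, every observed GPR, 100 and "flag everything"; the area under it
(trapezoidal) equals the normalized Mann-Whitney statistic with ties
counted one half.  The optimal threshold is the ROC point closest to the
upper-left corner, reported as the midpoint of its threshold-equivalence
interval.

``ROCStudy`` wraps the full analysis the way statsmodels wraps a model:
build it from QA records (or a DataFrame), call :meth:`ROCStudy.fit`, and
read the resulting table / ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateLabelsError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "QARecord",
    "GroundTruthLabel",
    "ROCResult",
    "CorrelationResult",
    "DEFAULT_LEVELS",
    "label_ground_truth",
    "delta_percent",
    "roc_curve",
    "auc",
    "optimal_threshold",
    "auc_significance",
    "analyze_roc",
    "spearman_permutation",
    "run_roc_study",
    "fraction_significant",
    "ROCStudy",
    "ROCStudyResults",
]

DEFAULT_LEVELS: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

_EXACT_PERM_MAX_N = 7  # full enumeration of n! rank permutations up to here
_EXACT_MW_MAX_PRODUCT = 400  # exact U distribution while n1*n2 <= this


@dataclass
class QARecord:
    """One analysed unit (a plan, or one arc in field-by-field mode)."""

    unit_id: str
    mode: str  # cumulative | field_by_field
    gpr_by_criteria: dict[str, float]
    d_calc: float  # Gy, TPS dose at the isocenter
    d_meas: float  # Gy, measured absolute dose at the isocenter

    def __post_init__(self) -> None:
        if not self.d_calc > 0:
            raise ValidationError("d_calc must be > 0")
        for label, gpr in self.gpr_by_criteria.items():
            if not 0 <= gpr <= 100:
                raise ValidationError(f"GPR for {label} outside [0, 100]")


@dataclass
class GroundTruthLabel:
    level_percent: float
    delta_percent: float  # signed, 100*(d_meas - d_calc)/d_calc
    label: str  # pass | fail


@dataclass
class ROCResult:
    """An ROC curve with its headline statistics.

    ``thresholds`` may end with ``inf`` — the "flag everything" point that
    closes the curve at (1, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    n_pass: int
    n_fail: int
    auc: float = float("nan")
    opth: float = float("nan")
    p_value: float = float("nan")


@dataclass
class CorrelationResult:
    r_s: float
    p_perm: float
    n_perm: int
    seed: int | None
    exact: bool = False


def delta_percent(d_calc: float, d_meas: float) -> float:
    """Signed isocenter dose deviation, % of the calculated (TPS) dose."""
    if not d_calc > 0:
        raise ValidationError("d_calc must be > 0")
    return 100.0 * (d_meas - d_calc) / d_calc


def label_ground_truth(rec: QARecord, level_percent: float) -> GroundTruthLabel:
    """Pass/fail against the absolute-dose agreement level (boundary passes)."""
    delta = delta_percent(rec.d_calc, rec.d_meas)
    label = "fail" if abs(delta) > level_percent else "pass"
    return GroundTruthLabel(level_percent=level_percent, delta_percent=delta,
                            label=label)


def _as_arrays(gprs: Iterable[float], fails: Iterable[bool]):
    g = np.asarray(list(gprs), dtype=float)
    f = np.asarray(list(fails), dtype=bool)
    if g.shape != f.shape:
        raise ValidationError("gprs and labels must have equal length")
    return g, f


def roc_curve(gprs: Sequence[float], fails: Sequence[bool]) -> ROCResult:
    """Exact step-function ROC over thresholds {0} U observed GPRs U {100, inf}.

    ``fails[i]`` is True when unit *i* fails the ground truth (the positive
    class); the test flags unit *i* at threshold ``t`` when ``gprs[i] < t``.
    """
    g, f = _as_arrays(gprs, fails)
    n_fail = int(f.sum())
    n_pass = int((~f).sum())
    if n_fail == 0 or n_pass == 0:
        raise DegenerateLabelsError(
            "ROC undefined: both ground-truth classes must be present"
        )
    thresholds = np.unique(np.concatenate([[0.0, 100.0], g]))
    thresholds = np.append(thresholds, np.inf)  # flag-everything endpoint
    pred = g[None, :] < thresholds[:, None]
    tp = (pred & f[None, :]).sum(axis=1)
    fp = (pred & ~f[None, :]).sum(axis=1)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tp / n_fail,
        one_minus_specificity=fp / n_pass,
        n_pass=n_pass,
        n_fail=n_fail,
    )


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the step curve (equals normalized U with
    ties counted 0.5)."""
    order = np.lexsort((roc.sensitivity, roc.one_minus_specificity))
    x = roc.one_minus_specificity[order]
    y = roc.sensitivity[order]
    return float(np.trapezoid(y, x))


def optimal_threshold(roc: ROCResult, observed_gprs: Sequence[float] | None = None
                      ) -> float:
    """Threshold of the ROC point closest to (0, 1).

    Ties are broken toward higher specificity (fewer false alarms), then
    toward the lower threshold.  The returned value is the midpoint of the
    equivalence interval ``(previous grid value, t*]`` so it falls between
    observed GPRs rather than on one of them; the interval above the
    largest observed GPR is capped at 100.
    """
    dist = np.hypot(1.0 - roc.sensitivity, roc.one_minus_specificity)
    order = np.lexsort((roc.thresholds, roc.one_minus_specificity, dist))
    t_star = float(roc.thresholds[order[0]])
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    if not np.isfinite(t_star):
        lower = float(finite.max())
        return (lower + 100.0) / 2.0
    below = finite[finite < t_star]
    lower = float(below.max()) if below.size else 0.0
    return (lower + t_star) / 2.0


def auc_significance(gprs: Sequence[float], fails: Sequence[bool]) -> float:
    """Two-sided Mann-Whitney U test of the GPR distributions (fail vs pass).

    Exact when the sample-size product is small and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    g, f = _as_arrays(gprs, fails)
    x = g[f]
    y = g[~f]
    if len(x) == 0 or len(y) == 0:
        raise DegenerateLabelsError("both classes are needed for the U test")
    has_ties = len(np.unique(g)) < len(g)
    method = (
        "exact"
        if (len(x) * len(y) <= _EXACT_MW_MAX_PRODUCT and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def analyze_roc(gprs: Sequence[float], fails: Sequence[bool]) -> ROCResult:
    """ROC curve plus AUC, optimal threshold and Mann-Whitney p-value."""
    roc = roc_curve(gprs, fails)
    roc.auc = auc(roc)
    roc.opth = optimal_threshold(roc)
    roc.p_value = auc_significance(gprs, fails)
    return roc


# ---------------------------------------------------------------------------
# Spearman permutation correlation
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("constant input vector")
    return float(xc @ yc) / denom


def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    The observed coefficient is the Pearson correlation of mid-ranks; the
    null population is built by random shuffles of one rank vector
    (``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``).  For ``n <= 7``
    all ``n!`` permutations are enumerated and the p-value is exact.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = _pearson(rx, ry)
    tol = 1e-12
    if len(x) <= _EXACT_PERM_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(len(x))):
            r = _pearson(rx, ry[list(perm)])
            count += abs(r) >= abs(r_obs) - tol
            total += 1
        return CorrelationResult(r_s=r_obs, p_perm=count / total,
                                 n_perm=total, seed=None, exact=True)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ rxc
    denom = np.sqrt(float(rxc @ rxc) * np.einsum("ij,ij->i", pc, pc))
    r_perm = num / denom
    count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - tol))
    return CorrelationResult(
        r_s=r_obs, p_perm=(1 + count) / (n_perm + 1), n_perm=n_perm,
        seed=seed, exact=False,
    )


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def run_roc_study(
    records: Sequence[QARecord],
    criteria_labels: Sequence[str] | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """One ROC analysis per (mode, criteria, level).

    Rows whose ground-truth labels are degenerate (all pass or all fail)
    are reported with ``defined = False`` and NaN statistics rather than
    dropped.
    """
    if not records:
        raise ValidationError("no records")
    if criteria_labels is None:
        criteria_labels = list(records[0].gpr_by_criteria)
    rows = []
    modes = sorted({rec.mode for rec in records})
    for mode in modes:
        recs = [r for r in records if r.mode == mode]
        for crit in criteria_labels:
            gprs = np.array([r.gpr_by_criteria[crit] for r in recs])
            for level in levels:
                fails = np.array(
                    [label_ground_truth(r, level).label == "fail" for r in recs]
                )
                row = {
                    "mode": mode, "criteria": crit, "level_percent": level,
                    "n_pass": int((~fails).sum()), "n_fail": int(fails.sum()),
                }
                try:
                    roc = analyze_roc(gprs, fails)
                    row.update(auc=roc.auc, opth=roc.opth,
                               p_value=roc.p_value, defined=True)
                except DegenerateLabelsError:
                    row.update(auc=np.nan, opth=np.nan, p_value=np.nan,
                               defined=False)
                rows.append(row)
    return pd.DataFrame(rows)


def fraction_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-mode percentage of defined ROC rows with p < alpha."""
    def frac(sub: pd.DataFrame) -> float:
        defined = sub[sub["defined"]]
        if defined.empty:
            return float("nan")
        return 100.0 * float((defined["p_value"] < alpha).mean())

    return table.groupby("mode").apply(frac, include_groups=False)


class ROCStudy:
    """GPR-vs-absolute-dose classification study (model object).

    Parameters
    ----------
    records : QA records, one per analysed unit.
    criteria_labels : which gamma criteria to analyse (default: every key
        of the first record).
    levels : ground-truth agreement levels in percent (default 1-5).
    """

    def __init__(
        self,
        records: Sequence[QARecord],
        criteria_labels: Sequence[str] | None = None,
        levels: Sequence[float] = DEFAULT_LEVELS,
    ) -> None:
        self.records = list(records)
        if not self.records:
            raise ValidationError("no records")
        self.criteria_labels = (
            list(criteria_labels)
            if criteria_labels is not None
            else list(self.records[0].gpr_by_criteria)
        )
        self.levels = list(levels)
        if not all(0 < lv < 100 for lv in self.levels):
            raise ValidationError("levels must lie in (0, 100)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ROCStudy":
        """Build from a long table with columns unit_id, mode, criteria,
        gpr, d_calc, d_meas (one row per unit x criteria)."""
        required = {"unit_id", "mode", "criteria", "gpr", "d_calc", "d_meas"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"records table missing columns {sorted(missing)}")
        records = []
        for (unit, mode), sub in df.groupby(["unit_id", "mode"], sort=False):
            records.append(
                QARecord(
                    unit_id=str(unit), mode=str(mode),
                    gpr_by_criteria=dict(zip(sub["criteria"], sub["gpr"])),
                    d_calc=float(sub["d_calc"].iloc[0]),
                    d_meas=float(sub["d_meas"].iloc[0]),
                )
            )
        return cls(records, **kwargs)

    def fit(self) -> "ROCStudyResults":
        table = run_roc_study(self.records, self.criteria_labels, self.levels)
        return ROCStudyResults(self, table)


class ROCStudyResults:
    """Fitted ROC study: the (mode x criteria x level) results table."""

    def __init__(self, model: ROCStudy, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    def roc(self, mode: str, criteria: str, level: float) -> ROCResult:
        """Recover the full ROC curve behind one table row."""
        recs = [r for r in self.model.records if r.mode == mode]
        gprs = [r.gpr_by_criteria[criteria] for r in recs]
        fails = [label_ground_truth(r, level).label == "fail" for r in recs]
        return analyze_roc(gprs, fails)

    @property
    def percent_significant(self) -> pd.Series:
        return fraction_significant(self.table)

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["ROC study of gamma passing rates vs isocenter dose agreement",
                 "=" * 62]
        for mode, sub in self.table.groupby("mode"):
            n_units = len([r for r in self.model.records if r.mode == mode])
            defined = sub[sub["defined"]]
            lines.append(f"mode: {mode}  (units: {n_units}, rows: {len(sub)})")
            if not defined.empty:
                sig = 100.0 * float((defined["p_value"] < alpha).mean())
                best = defined.loc[defined["auc"].idxmax()]
                lines.append(
                    f"  significant AUCs (p<{alpha:g}): {sig:.0f}%   best AUC "
                    f"{best['auc']:.3f} ({best['criteria']} at GT "
                    f"{best['level_percent']:g}%, OPTh {best['opth']:.1f}%)"
                )
            with pd.option_context("display.width", 100):
                lines.append(
                    sub.to_string(
                        index=False,
                        float_format=lambda v: f"{v:.4g}",
                        columns=["criteria", "level_percent", "n_pass",
                                 "n_fail", "auc", "opth", "p_value", "defined"],
                    )
                )
        return "\n".join(lines)

    def plot_roc(self, mode: str, level: float, ax=None):
        """Plot the six (or configured) ROC curves for one mode and level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for crit in self.model.criteria_labels:
            roc = self.roc(mode, crit, level)
            ax.step(
                roc.one_minus_specificity, roc.sensitivity, where="post",
                label=f"{crit} (AUC {roc.auc:.3f}, OPTh {roc.opth:.1f}%)",
            )
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{mode}, GT level {level:g}%")
        ax.legend(fontsize=7)
        return ax
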
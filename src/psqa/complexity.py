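"""MLC aperture-complexity metrics and plan quality indices.

For one control point (CP) with leaf-pair widths :math:`w_i` and pair
openings (gaps) :math:`g_i`, the aperture area, perimeter and equivalent
field size are

.. math::

    A_{CP} = \\sum_{i\\,\\mathrm{open}} w_i g_i, \\qquad
    EFS_{CP} = 4 A_{CP} / P_{CP},

with :math:`P_{CP}` the exact rectilinear perimeter of the union of the
open-pair rectangles.  Per plan (or per arc), the mean equivalent field
size and mean square-root aperture area are

.. math::

    MEFS = \\frac{1}{N}\\sum_{CP} EFS_{CP}, \\qquad
    MSRA = \\frac{1}{N}\\sum_{CP} \\sqrt{A_{CP}},

averaged over the :math:`N` control points with an open aperture.  A pair
counts as open when its gap exceeds ``gap_tol`` (default 0.5 mm): smaller
gaps are leaf-gap leakage positions, not apertures.

The quality indices follow the stereotactic conventions: homogeneity index
``HI = (D2% - D98%)/D50%`` and (inverse-Paddick) conformity index
``CI = V_PTV * V_PIV / V_overlap^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .dose_io import ControlPoint, ControlPointSequence, PlanSummary
from .exceptions import ClosedApertureError, ValidationError

__all__ = [
    "GAP_TOL_DEFAULT",
    "ApertureMetrics",
    "QualityIndices",
    "cp_area",
    "cp_perimeter",
    "cp_efs",
    "aperture_metrics",
    "homogeneity_index",
    "conformity_index",
    "quality_indices",
    "round_half_up",
]

GAP_TOL_DEFAULT = 0.5  # mm


@dataclass
class ApertureMetrics:
    """Per-CP aperture geometry and the per-plan/arc complexity means."""

    per_cp: list[tuple[float, float, float]]  # (area mm^2, perimeter mm, EFS mm)
    mefs: float  # mm
    msra: float  # mm
    n_cp_used: int


@dataclass
class QualityIndices:
    hi: float
    ci: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _open_mask(cp: ControlPoint, gap_tol: float) -> np.ndarray:
    return cp.gaps > gap_tol


def cp_area(cp: ControlPoint, gap_tol: float = GAP_TOL_DEFAULT) -> float:
    """Aperture area (mm^2): sum of width x gap over open leaf pairs."""
    mask = _open_mask(cp, gap_tol)
    return float(np.sum(cp.leaf_widths[mask] * cp.gaps[mask]))


def cp_perimeter(cp: ControlPoint, gap_tol: float = GAP_TOL_DEFAULT) -> float:
    """Rectilinear perimeter (mm) of the union of open-pair rectangles.

    Each open pair contributes its two leaf-tip edges (2 x width); the
    horizontal edges at the interface between vertically adjacent pairs are
    ``|da| + |db|`` when the two openings overlap in the leaf-travel
    direction and the two full openings when they are disjoint.  Boundary
    pairs (closed or absent neighbours) expose their full opening.  For a
    single-region aperture this equals the geometric polygon perimeter.
    """
    mask = _open_mask(cp, gap_tol)
    a = cp.bank_a_positions
    b = cp.bank_b_positions
    per = 2.0 * float(np.sum(cp.leaf_widths[mask]))
    n = cp.n_pairs
    for i in range(n + 1):  # interfaces between rows i-1 and i (incl. borders)
        lo_open = i - 1 >= 0 and mask[i - 1]
        hi_open = i < n and mask[i]
        if lo_open and hi_open:
            overlap = min(b[i - 1], b[i]) - max(a[i - 1], a[i])
            if overlap > 0:
                per += abs(a[i - 1] - a[i]) + abs(b[i - 1] - b[i])
            else:
                per += (b[i - 1] - a[i - 1]) + (b[i] - a[i])
        elif lo_open:
            per += b[i - 1] - a[i - 1]
        elif hi_open:
            per += b[i] - a[i]
    return float(per)


def cp_efs(cp: ControlPoint, gap_tol: float = GAP_TOL_DEFAULT) -> float:
    """Equivalent field size 4A/P (mm); raises on a closed aperture."""
    area = cp_area(cp, gap_tol)
    if area <= 0:
        raise ClosedApertureError("closed aperture: EFS undefined")
    return 4.0 * area / cp_perimeter(cp, gap_tol)


def aperture_metrics(seq: ControlPointSequence,
                     gap_tol: float = GAP_TOL_DEFAULT) -> ApertureMetrics:
    """MEFS and MSRA over the open control points of a plan or arc.

    The means are unweighted (no monitor-unit weighting); fully closed
    control points are excluded and ``n_cp_used`` reports how many remain.
    """
    per_cp: list[tuple[float, float, float]] = []
    efs_values: list[float] = []
    sqrt_areas: list[float] = []
    for cp in seq:
        area = cp_area(cp, gap_tol)
        if area <= 0:
            continue
        perimeter = cp_perimeter(cp, gap_tol)
        efs = 4.0 * area / perimeter
        per_cp.append((area, perimeter, efs))
        efs_values.append(efs)
        sqrt_areas.append(np.sqrt(area))
    if not per_cp:
        raise ClosedApertureError("all control points are closed")
    return ApertureMetrics(
        per_cp=per_cp,
        mefs=float(np.mean(efs_values)),
        msra=float(np.mean(sqrt_areas)),
        n_cp_used=len(per_cp),
    )


def homogeneity_index(s: PlanSummary, ndigits: int | None = None) -> float:
    """HI = (D2 - D98)/D50; optionally rounded for table regression."""
    if not s.d50 > 0:
        raise ValidationError("D50 must be > 0 for the homogeneity index")
    hi = (s.d2 - s.d98) / s.d50
    return round_half_up(hi, ndigits) if ndigits is not None else hi


def conformity_index(s: PlanSummary, ndigits: int | None = None) -> float:
    """CI = V_PTV * V_PIV / V_overlap^2 (inverse Paddick)."""
    if not s.v_overlap > 0:
        raise ValidationError("overlap volume must be > 0 for the conformity index")
    ci = (s.v_ptv * s.v_piv) / s.v_overlap**2
    return round_half_up(ci, ndigits) if ndigits is not None else ci


def quality_indices(s: PlanSummary, ndigits: int | None = None) -> QualityIndices:
    return QualityIndices(
        hi=homogeneity_index(s, ndigits), ci=conformity_index(s, ndigits)
    )
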
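"""Seeded generators for every input the QA pipeline consumes.

The generators emulate the structure a repeated-QA classification study
assumes: each simulated unit (plan or arc) carries a latent delivery-error
magnitude ``e`` that simultaneously (a) degrades the gamma passing rate —
through a rigid spatial shift and a global dose-scale error applied when
the detector "measures" the delivered distribution — and (b) perturbs the
absolute isocenter dose, with a tunable coupling strength ``kappa``.

Coupling model
--------------
``e`` is half-normal.  The isocenter deviation magnitude is drawn through
a Gaussian copula: a standard-normal score ``w = sqrt(kappa) * g(e) +
sqrt(1-kappa) * eta`` (``g`` maps ``e`` to its standard-normal score,
``eta`` independent noise) is mapped to the half-normal quantile scale and
multiplied by ``delta_sd_percent``.  ``kappa = 1`` with zero noise gives
``|delta| = delta_sd_percent * e`` exactly (a deterministic monotone
link); ``kappa = 0`` gives an independent half-normal deviation.  The sign
of the deviation is an independent fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classification import QARecord
from .dose_io import ControlPoint, ControlPointSequence, DoseGrid, MeasurementSet
from .exceptions import OutOfBoundsError, ValidationError
from .gamma import STANDARD_CRITERIA, GammaCriteria, GammaEngine, gamma_passing_rate
from .complexity import aperture_metrics

__all__ = [
    "FieldModel",
    "DetectorLayout",
    "CohortSpec",
    "planar_layout",
    "cylindrical_layout",
    "simulate_field",
    "simulate_measurement",
    "simulate_plan",
    "simulate_cohort",
]


@dataclass(frozen=True)
class FieldModel:
    """Analytic SBRT-like field: flat core with logistic penumbra.

    The profile along each axis is ``1 / (1 + exp((|x| - size/2) / k))``
    with ``k`` set so that ``penumbra_mm`` is the 80%-20% distance; the
    dose at the geometric field edge is therefore half the maximum.
    """

    size_mm: float = 30.0
    penumbra_mm: float = 5.0
    dose_max_gy: float = 10.0
    grid_spacing_mm: float = 1.0
    margin_mm: float = 20.0

    def __post_init__(self) -> None:
        if not self.size_mm > 0:
            raise ValidationError("field size must be > 0")
        if self.penumbra_mm >= self.size_mm / 2:
            raise ValidationError("penumbra must be smaller than half the field")


@dataclass(frozen=True)
class DetectorLayout:
    positions: tuple  # ((x, y), ...) mm, hashable for reuse
    geometry_tag: str = "planar"

    @property
    def points(self) -> np.ndarray:
        return np.array(self.positions, dtype=float)


def planar_layout(pitch_mm: float = 2.5, half_extent_mm: float = 20.0
                  ) -> DetectorLayout:
    """Square planar diode grid (high-resolution, SRS-array-like)."""
    axis = np.arange(-half_extent_mm, half_extent_mm + pitch_mm / 2, pitch_mm)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    pos = tuple(zip(xx.ravel().tolist(), yy.ravel().tolist()))
    return DetectorLayout(positions=pos, geometry_tag="planar")


def cylindrical_layout(pitch_mm: float = 10.0, half_extent_mm: float = 25.0
                       ) -> DetectorLayout:
    """Helical diode array unwrapped to its 2D (arc-length x axial) manifold."""
    axis = np.arange(-half_extent_mm, half_extent_mm + pitch_mm / 2, pitch_mm)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    pos = tuple(zip(xx.ravel().tolist(), yy.ravel().tolist()))
    return DetectorLayout(positions=pos, geometry_tag="cylinder_unwrapped")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated QA cohort.

    ``coupling`` is the fraction of the isocenter-deviation variance (on
    the Gaussian-score scale) explained by the delivery-error magnitude.
    ``delta_sd_percent`` sets the marginal half-normal scale of the
    isocenter deviation.
    """

    n_units: int = 20
    mode: str = "cumulative"  # cumulative | field_by_field
    shift_sd: float = 1.0  # mm per unit error magnitude
    scale_sd: float = 0.02  # fractional dose-scale error per unit magnitude
    noise_sd: float = 0.01  # multiplicative detector noise
    coupling: float = 0.8
    delta_sd_percent: float = 2.5
    seed: int = 0
    detector: str = "planar"  # planar | cylinder_unwrapped
    field_model: FieldModel = field(default_factory=FieldModel)
    criteria: tuple[GammaCriteria, ...] = STANDARD_CRITERIA
    # gamma search preset for cohort-scale runs: coarse grid, no refinement
    step_divisor: int = 5
    refine: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValidationError("n_units must be >= 2")
        if min(self.shift_sd, self.scale_sd, self.noise_sd) < 0:
            raise ValidationError("error standard deviations must be >= 0")
        if not 0 <= self.coupling <= 1:
            raise ValidationError("coupling must lie in [0, 1]")
        if self.detector not in ("planar", "cylinder_unwrapped"):
            raise ValidationError("unknown detector preset")


def simulate_field(spec: FieldModel, seed: int | None = None) -> DoseGrid:
    """Analytic 2D dose grid (deterministic; ``seed`` kept for interface
    symmetry with the stochastic generators)."""
    half = spec.size_mm / 2 + spec.margin_mm
    axis = np.arange(-half, half + spec.grid_spacing_mm / 2, spec.grid_spacing_mm)
    k = spec.penumbra_mm / (2 * np.log(4.0))

    def profile(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((np.abs(x) - spec.size_mm / 2) / k))

    values = spec.dose_max_gy * profile(axis)[:, None] * profile(axis)[None, :]
    return DoseGrid(
        origin=np.array([axis[0], axis[0]]),
        spacing=np.array([spec.grid_spacing_mm] * 2),
        values=values,
        frame_label="synthetic field",
    )


def simulate_measurement(
    truth: DoseGrid,
    layout: DetectorLayout,
    shift: np.ndarray,
    scale: float,
    noise_sd: float,
    seed: int | np.random.Generator | None = 0,
) -> MeasurementSet:
    """Detector sampling of the delivered distribution.

    The delivered dose is the truth grid rigidly shifted by ``shift`` and
    scaled by ``1 + scale``; each diode reading carries independent
    multiplicative Gaussian noise of standard deviation ``noise_sd``, and
    the isocenter reading is sampled the same way with its own noise draw.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pts = layout.points
    shift = np.asarray(shift, dtype=float)
    sampled = truth.sample(pts - shift[None, :])
    if np.any(np.isnan(sampled)):
        raise OutOfBoundsError("detector points fall outside the shifted grid")
    eps = rng.normal(0.0, noise_sd, size=len(pts)) if noise_sd > 0 else 0.0
    doses = (1.0 + scale) * sampled * (1.0 + eps)
    iso = truth.sample(-shift[None, :])[0]
    if np.isnan(iso):
        raise OutOfBoundsError("isocenter falls outside the shifted grid")
    eps_iso = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    iso_dose = (1.0 + scale) * iso * (1.0 + eps_iso)
    return MeasurementSet(
        positions=pts,
        doses=np.clip(doses, 0.0, None),
        geometry_tag=layout.geometry_tag,
        isocenter_dose=float(max(iso_dose, 0.0)),
    )


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = min(width, len(x))  # np.convolve 'same' needs kernel <= signal
    if width <= 1 or len(x) < 3:
        return x
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    return np.convolve(x, kernel, mode="same")


def simulate_plan(
    n_cp: int,
    n_pairs: int,
    widths: float | np.ndarray,
    target_efs: float,
    seed: int = 0,
    gap_tol: float = 0.5,
) -> ControlPointSequence:
    """Smooth random leaf trajectories with a prescribed mean aperture size.

    Leaf-pair centers and openings follow smoothed random walks over the
    control points; the bank positions are then rescaled iteratively until
    the realized MEFS lies within 10% of ``target_efs`` (an infeasible
    target raises).
    """
    if n_cp < 1 or n_pairs < 1:
        raise ValidationError("need n_cp >= 1 and n_pairs >= 1")
    if not target_efs > 0:
        raise ValidationError("target_efs must be > 0")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (n_pairs,)).copy()
    rng = np.random.default_rng(seed)
    # envelope keeps central pairs open wider, like a tumour-conformal arc
    row = np.linspace(-1, 1, n_pairs)
    envelope = np.clip(np.cos(row * np.pi / 2) + 0.15, 0.1, None)
    cps = []
    for _ in range(n_cp):
        centers = _smooth(rng.normal(0.0, 0.3 * target_efs, n_pairs), 5)
        gaps = envelope * target_efs * np.abs(
            _smooth(rng.normal(1.0, 0.3, n_pairs), 5)
        )
        gaps = np.clip(gaps, 0.0, None)
        cps.append((centers, gaps))

    def build(scale: float) -> ControlPointSequence:
        return ControlPointSequence(
            control_points=[
                ControlPoint(
                    leaf_widths=widths,
                    bank_a_positions=scale * (c - g / 2),
                    bank_b_positions=scale * (c + g / 2),
                )
                for c, g in cps
            ],
            plan_id=f"synthetic-{seed}",
        )

    # EFS is monotone in the position scale but saturates at a shape-dependent
    # ceiling (fixed leaf-bank height); stop when converged or stalled.
    scale = 1.0
    prev_mefs = None
    for _ in range(40):
        seq = build(scale)
        mefs = aperture_metrics(seq, gap_tol=gap_tol).mefs
        if abs(mefs - target_efs) <= 0.01 * target_efs:
            return seq
        if prev_mefs is not None and abs(mefs - prev_mefs) < 1e-3 * target_efs:
            break  # saturated: no further progress possible
        prev_mefs = mefs
        scale *= np.clip(target_efs / mefs, 0.5, 2.0)
    if abs(mefs - target_efs) > 0.10 * target_efs:
        raise ValidationError(
            f"target EFS {target_efs:g} mm infeasible for this geometry "
            f"(reached {mefs:g} mm)"
        )
    return seq


def _layout_for(spec: CohortSpec) -> DetectorLayout:
    half = spec.field_model.size_mm / 2 + min(spec.field_model.margin_mm / 2, 10.0)
    if spec.detector == "planar":
        return planar_layout(pitch_mm=2.5, half_extent_mm=half)
    return cylindrical_layout(pitch_mm=10.0, half_extent_mm=half)


def simulate_cohort(
    spec: CohortSpec,
    measurement_sink: list | None = None,
) -> tuple[list[QARecord], pd.DataFrame]:
    """Simulate one QA cohort; returns records and the hidden truth table.

    Per unit: a half-normal error magnitude ``e`` drives a rigid shift
    (random direction, magnitude ``shift_sd * e``) and a dose-scale error
    (random sign, magnitude ``scale_sd * e``); the measured distribution is
    the detector sampling of the shifted/scaled truth; GPRs are computed
    for every criterion in ``spec.criteria``; the isocenter deviation is
    drawn from the copula coupling model.  Unit-level randomness is derived
    from per-unit child seeds, so cohorts that differ only in detector
    share the same error realizations (two devices measuring one delivery).

    When ``measurement_sink`` is a list, the per-unit
    :class:`~psqa.dose_io.MeasurementSet` objects are appended to it as
    ``(unit_id, measurement)`` pairs (for writing simulated raw data).
    """
    truth = simulate_field(spec.field_model)
    layout = _layout_for(spec)
    engine = GammaEngine(
        truth,
        layout.points,
        step_divisor=spec.step_divisor,
        refine=spec.refine,
    )
    d_calc = float(truth.sample(np.zeros((1, 2)))[0])
    sqrt_k = np.sqrt(spec.coupling)
    sqrt_1mk = np.sqrt(1.0 - spec.coupling)
    records: list[QARecord] = []
    truth_rows = []
    for i in range(spec.n_units):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, i])
        )
        e = abs(rng.normal())
        theta = rng.uniform(0.0, 2 * np.pi)
        shift = spec.shift_sd * e * np.array([np.cos(theta), np.sin(theta)])
        scale = spec.scale_sd * e * rng.choice([-1.0, 1.0])
        eta = rng.normal()
        sign = rng.choice([-1.0, 1.0])
        # copula: half-normal e -> N(0,1) score, mix with noise, back-map
        g_e = norm.ppf(np.clip(2 * norm.cdf(e) - 1, 1e-15, 1 - 1e-15))
        w = sqrt_k * g_e + sqrt_1mk * eta
        q = np.clip(norm.cdf(w), 1e-15, 1 - 1e-15)
        abs_delta = spec.delta_sd_percent * norm.ppf((1 + q) / 2)
        delta = float(sign * abs_delta)
        meas = simulate_measurement(
            truth, layout, shift, scale, spec.noise_sd, seed=rng
        )
        if measurement_sink is not None:
            measurement_sink.append((f"unit{i:03d}", meas))
        gprs = {}
        for crit in spec.criteria:
            res = gamma_passing_rate(meas, truth, crit, engine=engine)
            gprs[crit.label] = res.gpr_percent
        d_meas = d_calc * (1.0 + delta / 100.0)
        records.append(
            QARecord(
                unit_id=f"unit{i:03d}",
                mode=spec.mode,
                gpr_by_criteria=gprs,
                d_calc=d_calc,
                d_meas=d_meas,
            )
        )
        truth_rows.append(
            {
                "unit_id": f"unit{i:03d}", "e": e,
                "shift_x": shift[0], "shift_y": shift[1],
                "scale": scale, "delta_percent": delta,
                "d_calc": d_calc, "d_meas": d_meas,
            }
        )
    return records, pd.DataFrame(truth_rows)
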
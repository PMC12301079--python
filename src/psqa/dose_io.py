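"""Data model and readers/writers for dose grids, detector measurements,
MLC control points and plan dose/volume summaries.

Conventions
-----------
Coordinates are millimetres in a right-handed frame with the isocenter at
the origin; dose is in Gy.  Grids are node-registered: ``origin`` is the
*center* of the first voxel and sample ``(i, j[, k])`` sits at
``origin + spacing * (i, j[, k])``, with ``values`` indexed in the same
axis order (row-major).

File dialects (all plain text):

* grid-json: ``{"origin": [...], "spacing": [...], "shape": [...],
  "values": [...]}`` with values flattened row-major.
* grid-text: ``# origin:``/``# spacing:``/``# shape:`` header lines followed
  by whitespace-separated values.
* measurements: comma-separated ``x,y[,z],dose`` lines, ``#`` comments; an
  optional ``# isocenter_dose: <Gy>`` directive carries the absolute point
  measurement.
* control points: ``{"leaf_widths": [...], "control_points":
  [{"bank_a": [...], "bank_b": [...]}, ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .exceptions import FormatError, ValidationError

__all__ = [
    "DoseGrid",
    "MeasurementSet",
    "ControlPoint",
    "ControlPointSequence",
    "PlanSummary",
    "read_dose_grid",
    "write_dose_grid",
    "read_measurements",
    "write_measurements",
    "read_control_points",
    "write_control_points",
    "read_plan_summaries",
    "load_reference_cohort",
]

_GAP_CLAMP_TOL = 1e-6  # mm; |negative gap| below this is clamped to closed


@dataclass
class DoseGrid:
    """A calculated dose distribution on a regular 2D or 3D grid."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        nd = self.values.ndim
        if nd not in (2, 3):
            raise ValidationError(f"dose grid must be 2D or 3D, got {nd}D values")
        if self.origin.shape != (nd,) or self.spacing.shape != (nd,):
            raise ValidationError(
                "origin/spacing length must match grid dimensionality"
            )
        if not np.all(self.spacing > 0):
            raise ValidationError("grid spacing must be > 0 on every axis")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be >= 0")
        if any(n < 2 for n in self.values.shape):
            raise ValidationError("grid needs at least 2 samples per axis")
        self._interp: RegularGridInterpolator | None = None

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def axes(self) -> list[np.ndarray]:
        return [
            self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
            for d in range(self.ndim)
        ]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corner coordinates of the sampled region."""
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.values.shape) - 1)
        return lo, hi

    def interpolator(self) -> RegularGridInterpolator:
        """Multilinear interpolator; NaN outside the sampled region."""
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.axes, self.values, method="linear",
                bounds_error=False, fill_value=np.nan,
            )
        return self._interp

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Interpolate dose at ``points`` with shape (..., ndim)."""
        return self.interpolator()(np.asarray(points, dtype=float))


@dataclass
class MeasurementSet:
    """Detector point doses with coordinates (the reference distribution)."""

    positions: np.ndarray  # (n, 2) or (n, 3), mm
    doses: np.ndarray  # (n,), Gy
    geometry_tag: str = "planar"  # planar | cylinder_unwrapped
    isocenter_dose: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.doses = np.asarray(self.doses, dtype=float)
        if self.positions.shape[0] != self.doses.shape[0]:
            raise ValidationError("positions and doses must have equal length")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise ValidationError("measured doses must be finite and >= 0")
        # positions unique within 1e-6 mm
        rounded = np.round(self.positions / 1e-6).astype(np.int64)
        if len({tuple(r) for r in rounded}) != len(rounded):
            raise ValidationError("duplicate measurement positions")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class ControlPoint:
    """One MLC aperture snapshot: per-pair leaf widths and bank positions.

    The gap of pair *i* is ``bank_b[i] - bank_a[i]``; small negative gaps
    (overtravel within 1e-6 mm) are clamped closed, larger ones rejected.
    """

    leaf_widths: np.ndarray  # mm per leaf pair
    bank_a_positions: np.ndarray  # mm
    bank_b_positions: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.leaf_widths = np.asarray(self.leaf_widths, dtype=float)
        self.bank_a_positions = np.asarray(self.bank_a_positions, dtype=float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, dtype=float)
        if not (
            self.leaf_widths.shape
            == self.bank_a_positions.shape
            == self.bank_b_positions.shape
        ):
            raise ValidationError("leaf arrays must have equal length")
        if not np.all(self.leaf_widths > 0):
            raise ValidationError("leaf widths must be > 0")
        gap = self.bank_b_positions - self.bank_a_positions
        if np.any(gap < -_GAP_CLAMP_TOL):
            raise ValidationError("bank_b must not sit below bank_a")
        clamp = gap < 0
        if np.any(clamp):
            self.bank_b_positions = np.where(
                clamp, self.bank_a_positions, self.bank_b_positions
            )

    @property
    def gaps(self) -> np.ndarray:
        return self.bank_b_positions - self.bank_a_positions

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_widths)


@dataclass
class ControlPointSequence:
    """Per-control-point MLC positions for one plan or one arc."""

    control_points: list[ControlPoint]
    plan_id: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if len(self.control_points) < 1:
            raise ValidationError("a control-point sequence needs >= 1 CP")

    def __len__(self) -> int:
        return len(self.control_points)

    def __iter__(self):
        return iter(self.control_points)


@dataclass
class PlanSummary:
    """Per-plan dose/volume summary (doses in Gy, volumes in cm^3).

    ``d2 >= d98`` is *not* enforced: clinical summary tables can violate it
    when the dose-volume metrics are reported on different structures.
    """

    d2: float
    d50: float
    d98: float
    v_ptv: float
    v_piv: float
    v_overlap: float
    prescription_dose: float = float("nan")
    n_fractions: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("v_ptv", "v_piv", "v_overlap"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.v_overlap > min(self.v_ptv, self.v_piv) * (1 + 1e-9):
            raise ValidationError("v_overlap cannot exceed min(v_ptv, v_piv)")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _grid_from_dict(obj: dict) -> DoseGrid:
    for key in ("origin", "spacing", "shape", "values"):
        if key not in obj:
            raise FormatError(f"grid header missing field '{key}'")
    shape = tuple(int(n) for n in obj["shape"])
    values = np.asarray(obj["values"], dtype=float)
    if values.size != int(np.prod(shape)):
        raise FormatError("field 'values' length does not match 'shape'")
    return DoseGrid(
        origin=np.asarray(obj["origin"], dtype=float),
        spacing=np.asarray(obj["spacing"], dtype=float),
        values=values.reshape(shape),
        frame_label=str(obj.get("frame_label", "")),
    )


def read_dose_grid(path: str | Path, format_tag: str = "grid-json") -> DoseGrid:
    """Read a :class:`DoseGrid` from the grid-json or grid-text dialect."""
    path = Path(path)
    text = path.read_text()
    if format_tag == "grid-json":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed grid JSON: {exc}") from exc
        return _grid_from_dict(obj)
    if format_tag == "grid-text":
        header: dict[str, list[float]] = {}
        body: list[float] = []
        frame_label = ""
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    continue
                key, _, rhs = line.lstrip("#").partition(":")
                key = key.strip()
                if key == "frame_label":
                    frame_label = rhs.strip()
                elif key in ("origin", "spacing", "shape"):
                    try:
                        header[key] = [float(tok) for tok in rhs.split()]
                    except ValueError as exc:
                        raise FormatError(
                            f"non-numeric entry in header field '{key}'"
                        ) from exc
                continue
            try:
                body.extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise FormatError(f"non-numeric dose value in line {line!r}") from exc
        obj = dict(header, values=body, frame_label=frame_label)
        return _grid_from_dict(obj)
    raise FormatError(f"unknown grid format tag '{format_tag}'")


def write_dose_grid(grid: DoseGrid, path: str | Path,
                    format_tag: str = "grid-json") -> None:
    """Write a grid; the JSON dialect round-trips byte-identically."""
    path = Path(path)
    if format_tag == "grid-json":
        obj = {
            "origin": list(grid.origin),
            "spacing": list(grid.spacing),
            "shape": list(grid.values.shape),
            "values": [float(v) for v in grid.values.ravel()],
            "frame_label": grid.frame_label,
        }
        path.write_text(json.dumps(obj, sort_keys=True, separators=(",", ":"))
                        + "\n")
        return
    if format_tag == "grid-text":
        lines = [
            "# origin: " + " ".join(repr(float(v)) for v in grid.origin),
            "# spacing: " + " ".join(repr(float(v)) for v in grid.spacing),
            "# shape: " + " ".join(str(int(n)) for n in grid.values.shape),
        ]
        if grid.frame_label:
            lines.append("# frame_label: " + grid.frame_label)
        for row in grid.values.reshape(grid.values.shape[0], -1):
            lines.append(" ".join(repr(float(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")
        return
    raise FormatError(f"unknown grid format tag '{format_tag}'")


def read_measurements(path: str | Path) -> MeasurementSet:
    """Read a delimited point-dose file: ``x,y[,z],dose`` per line."""
    positions: list[list[float]] = []
    doses: list[float] = []
    isocenter_dose: float | None = None
    geometry_tag = "planar"
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, rhs = line.lstrip("#").partition(":")
            key = key.strip()
            if key == "isocenter_dose":
                try:
                    isocenter_dose = float(rhs)
                except ValueError as exc:
                    raise FormatError("non-numeric isocenter_dose header") from exc
            elif key == "geometry":
                geometry_tag = rhs.strip()
            continue
        tokens = [tok for tok in line.replace(",", " ").split() if tok]
        if len(tokens) not in (3, 4):
            raise FormatError(
                f"line {lineno}: expected x,y[,z],dose — got {len(tokens)} fields"
            )
        try:
            nums = [float(tok) for tok in tokens]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric field") from exc
        positions.append(nums[:-1])
        doses.append(nums[-1])
    if not doses:
        raise FormatError("empty measurement file (no data lines)")
    dims = {len(p) for p in positions}
    if len(dims) != 1:
        raise FormatError("mixed 2D/3D coordinates in measurement file")
    try:
        return MeasurementSet(
            positions=np.array(positions), doses=np.array(doses),
            geometry_tag=geometry_tag, isocenter_dose=isocenter_dose,
        )
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_measurements(ms: MeasurementSet, path: str | Path) -> None:
    lines = [f"# geometry: {ms.geometry_tag}"]
    if ms.isocenter_dose is not None:
        lines.append(f"# isocenter_dose: {ms.isocenter_dose!r}")
    for pos, dose in zip(ms.positions, ms.doses):
        lines.append(",".join(repr(float(v)) for v in pos) + "," + repr(float(dose)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_control_points(path: str | Path) -> ControlPointSequence:
    """Read a control-point JSON file (DICOM-RT-like bank sequences)."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed control-point JSON: {exc}") from exc
    if "leaf_widths" not in obj:
        raise FormatError("control-point file missing field 'leaf_widths'")
    if "control_points" not in obj or not obj["control_points"]:
        raise FormatError("control-point file missing field 'control_points'")
    widths = np.asarray(obj["leaf_widths"], dtype=float)
    cps = []
    for i, cp in enumerate(obj["control_points"]):
        for key in ("bank_a", "bank_b"):
            if key not in cp:
                raise FormatError(f"control point {i} missing field '{key}'")
            if len(cp[key]) != len(widths):
                raise FormatError(
                    f"control point {i}: '{key}' length {len(cp[key])} does not "
                    f"match leaf_widths length {len(widths)}"
                )
        try:
            cps.append(ControlPoint(widths, np.asarray(cp["bank_a"], float),
                                    np.asarray(cp["bank_b"], float)))
        except ValidationError as exc:
            raise FormatError(f"control point {i}: {exc}") from exc
    return ControlPointSequence(
        control_points=cps,
        plan_id=str(obj.get("plan_id", "")),
        field_id=str(obj.get("field_id", "")),
    )


def write_control_points(seq: ControlPointSequence, path: str | Path) -> None:
    obj = {
        "plan_id": seq.plan_id,
        "field_id": seq.field_id,
        "leaf_widths": [float(v) for v in seq.control_points[0].leaf_widths],
        "control_points": [
            {
                "bank_a": [float(v) for v in cp.bank_a_positions],
                "bank_b": [float(v) for v in cp.bank_b_positions],
            }
            for cp in seq.control_points
        ],
    }
    Path(path).write_text(json.dumps(obj, sort_keys=True, separators=(",", ":"))
                          + "\n")


_SUMMARY_COLUMNS = ["d2", "d50", "d98", "v_ptv", "v_piv", "v_overlap"]


def read_plan_summaries(path: str | Path) -> list[PlanSummary]:
    """Read a CSV of plan dose/volume summaries into :class:`PlanSummary` rows."""
    df = pd.read_csv(path)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plan summary CSV missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        meta = {
            c: row[c]
            for c in df.columns
            if c not in _SUMMARY_COLUMNS + ["prescription_dose", "n_fractions"]
        }
        out.append(
            PlanSummary(
                d2=float(row["d2"]), d50=float(row["d50"]), d98=float(row["d98"]),
                v_ptv=float(row["v_ptv"]), v_piv=float(row["v_piv"]),
                v_overlap=float(row["v_overlap"]),
                prescription_dose=float(row.get("prescription_dose", np.nan)),
                n_fractions=int(row.get("n_fractions", 0)),
                metadata=meta,
            )
        )
    return out


def load_reference_cohort() -> pd.DataFrame:
    """Published 20-plan SBRT reference cohort used for index regression tests.

    Columns include the PTV dose-volume metrics (``d98``, ``d50``, ``d2``, Gy),
    the PTV/prescription-isodose volumes (cm^3) and the published two-decimal
    homogeneity (``hi_published``) and conformity (``ci_published``) indices.
    """
    here = Path(__file__).parent / "data" / "plan_summaries.csv"
    return pd.read_csv(here)
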
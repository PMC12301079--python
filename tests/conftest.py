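import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from psqa import (
    ControlPoint,
    ControlPointSequence,
    DoseGrid,
    FieldModel,
    MeasurementSet,
    planar_layout,
    simulate_field,
    simulate_measurement,
)


@pytest.fixture
def square_cp():
    """12 pairs of 5 mm width, all gaps 60 mm: a 60 x 60 mm square field."""
    n = 12
    return ControlPoint(
        leaf_widths=np.full(n, 5.0),
        bank_a_positions=np.full(n, -30.0),
        bank_b_positions=np.full(n, 30.0),
    )


@pytest.fixture
def rect_cp():
    """10 pairs of 5 mm width, gaps 100 mm: a 100 x 50 mm rectangle."""
    n = 10
    return ControlPoint(
        leaf_widths=np.full(n, 5.0),
        bank_a_positions=np.full(n, -50.0),
        bank_b_positions=np.full(n, 50.0),
    )


@pytest.fixture
def small_field():
    """30 mm analytic field on a 1 mm grid."""
    return simulate_field(FieldModel(size_mm=30.0, penumbra_mm=5.0,
                                     dose_max_gy=10.0))


@pytest.fixture
def exact_measurement(small_field):
    """Detector sampling of the field with no error at all."""
    return simulate_measurement(
        small_field, planar_layout(5.0, 15.0), np.zeros(2), 0.0, 0.0, seed=0
    )


def random_single_region_cp(rng, n_pairs=None):
    """Random one-region aperture: contiguous open rows whose openings
    overlap pairwise, so the union is a single rectilinear polygon."""
    n = n_pairs or rng.integers(2, 9)
    widths = rng.uniform(2.0, 10.0, n)
    a = np.empty(n)
    b = np.empty(n)
    a[0] = rng.uniform(-40, 0)
    b[0] = a[0] + rng.uniform(5, 40)
    for i in range(1, n):
        # keep an overlap with the previous open interval
        lo = a[i - 1] - 15
        hi = b[i - 1] - 1.0
        a[i] = rng.uniform(lo, hi)
        b[i] = rng.uniform(max(a[i] + 1.0, a[i - 1] + 1.0), b[i - 1] + 15)
    return ControlPoint(widths, a, b)
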
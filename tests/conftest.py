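import numpy as np
import pytest

from vmatqa.mlc import ApertureShape, MlcGeometry


@pytest.fixture
def geom10():
    """Ten 5 mm leaf pairs spanning y in [-25, 25]."""
    return MlcGeometry(np.arange(-25.0, 26.0, 5.0))


@pytest.fixture
def rect_shape(geom10):
    """100 x 50 mm rectangle: every pair fully open to x in [-50, 50]."""
    return ApertureShape(
        left=np.full(10, -50.0),
        right=np.full(10, 50.0),
        jaws=(-60.0, 60.0, -30.0, 30.0),
        geometry=geom10,
    )


def random_staircase(rng, n_pairs=12, band=5.0, grid=0.5, p_closed=0.25):
    """Random lattice-aligned staircase aperture.

    All coordinates are multiples of ``grid`` so a rasterization at a pixel
    dividing ``grid`` has no partially covered pixels.  Open gaps are at
    least 2 mm, keeping well clear of the default 0.5 mm closed-gap rule.
    """
    geometry = MlcGeometry(np.arange(0.0, band * n_pairs + 1e-9, band))
    left = np.zeros(n_pairs)
    right = np.zeros(n_pairs)
    for j in range(n_pairs):
        if rng.random() < p_closed:
            continue  # parked: left == right == 0 -> closed
        lo = rng.integers(-40, 30) * grid
        hi = lo + rng.integers(4, 80) * grid  # gap >= 2 mm
        left[j], right[j] = lo, hi
    jaws = (
        rng.integers(-50, -40) * grid,
        rng.integers(40, 50) * grid,
        0.0,
        band * n_pairs,
    )
    return ApertureShape(left=left, right=right, jaws=jaws, geometry=geometry)
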
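import numpy as np
import pytest

from grainshape.efd import ContourSequence
from grainshape.simulate import grain_outline


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def grain_contour():
    """A generic asymmetric grain outline (nonzero taper, so the
    half-period standardization tie-break is well separated)."""
    return grain_outline(aspect=2.3, taper=0.2, roundness=2.2, n_points=500)


@pytest.fixture
def make_grain():
    def _make(aspect=2.3, taper=0.2, roundness=2.2, n_points=500):
        return grain_outline(aspect, taper, roundness, n_points=n_points)

    return _make


def transform_contour(contour, scale=1.0, angle=0.0, shift=0, translate=(0.0, 0.0)):
    """Apply scaling, rotation, cyclic start shift and translation."""
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    pts = scale * contour.points @ rot.T + np.asarray(translate)
    return ContourSequence(np.roll(pts, shift, axis=0))
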
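import numpy as np
import pandas as pd
import pytest

from sporescope import simulate
from sporescope.morphometry import CalibrationScale, _region_from_slice


@pytest.fixture(scope="session")
def scale():
    return CalibrationScale()  # 15.8097 px/µm


@pytest.fixture(scope="session")
def spore_field():
    """A small rendered spore field with ground truth (12 sagittal, 3 oblique)."""
    spec = simulate.SporeFieldSpec(n_sagittal=12, n_oblique=3, seed=11)
    return simulate.synth_micrograph(spec)


@pytest.fixture()
def make_region():
    """Build a LabeledRegion straight from a boolean mask."""

    def _make(mask: np.ndarray):
        return _region_from_slice(np.asarray(mask, dtype=bool), 1, mask.shape)

    return _make


@pytest.fixture(scope="session")
def nested_table():
    """Nested-design trait table with individual-level structure."""
    spec = simulate.MorphSimSpec(seed=21)
    table, truth = simulate.synth_morphtable(spec)
    return table, truth


@pytest.fixture()
def ellipse_mask_factory():
    """Rasterize a filled ellipse with given semi-axes and rotation."""

    def _make(shape, cy, cx, a, b, theta=0.0):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    return _make
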
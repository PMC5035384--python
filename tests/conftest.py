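import numpy as np
import pytest

from morphsel.io import LandmarkSet, SliderTable
from morphsel.simulate import consensus_outline, default_truth, gen_specimens


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def triangle_set():
    """Three triangles: rotated/scaled/translated copies of one shape."""
    base = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.5]])
    configs = []
    for theta, scale, shift in [(0.0, 1.0, (0, 0)), (0.7, 2.0, (5, -3)), (-1.2, 0.5, (-1, 4))]:
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        configs.append(base @ rot.T * scale + np.array(shift))
    return LandmarkSet(coords=np.array(configs), specimen_ids=["a", "b", "c"])


@pytest.fixture
def outline_truth():
    """Small, fast truth: fewer landmarks, modest noise."""
    return default_truth(n_mating=60, n_fertilization=60)


@pytest.fixture
def outline_specimens(outline_truth):
    return gen_specimens(outline_truth, n=40, seed=11)


@pytest.fixture
def outline_sliders(outline_truth):
    from morphsel.simulate import _outline_sliders

    return _outline_sliders(outline_truth)


@pytest.fixture
def consensus29():
    return consensus_outline(29)
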
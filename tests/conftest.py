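import numpy as np
import pytest

from nodulecad import (
    PhantomSpec,
    RoiVolume,
    feature_table,
    make_benchmark,
    make_roi,
    normalize_minmax,
    split_feature_table,
)


@pytest.fixture(scope="session")
def ball_roi():
    """Digitized ball, radius 12, constant intensity."""
    return make_roi(PhantomSpec(shape="ball", size=(12,), grid=(30, 30, 30)))


@pytest.fixture(scope="session")
def cube_roi():
    """Solid cube, side 40 (large enough that lattice effects are small)."""
    mask = np.zeros((44, 44, 44), bool)
    mask[2:42, 2:42, 2:42] = True
    return RoiVolume(np.ones((44, 44, 44)), mask, id="cube")


@pytest.fixture()
def constant_roi():
    """Ball mask inside a globally constant intensity field (value 7)."""
    mask = np.zeros((24, 24, 24), bool)
    z, y, x = np.indices((24, 24, 24)) - 11.5
    mask[z**2 + y**2 + x**2 <= 64] = True
    return RoiVolume(np.full((24, 24, 24), 7.0), mask, id="const")


@pytest.fixture(scope="session")
def separable_features():
    """Feature table of the default separable 70+70 phantom benchmark."""
    rois = make_benchmark(70, 70, seed=0, difficulty="separable")
    table = feature_table(rois)
    feats, labels = split_feature_table(table)
    return normalize_minmax(feats), labels, feats


@pytest.fixture(scope="session")
def noisy_features():
    """Feature table of the default noisy 70+70 phantom benchmark."""
    rois = make_benchmark(70, 70, seed=0, difficulty="noisy")
    table = feature_table(rois)
    feats, labels = split_feature_table(table)
    return normalize_minmax(feats), labels, feats
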
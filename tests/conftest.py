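import numpy as np
import pytest

from imquant.grid import ImageVolume, LabelMask
from imquant.phantoms import PhantomSpec, make_geometric_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def noisy_sphere():
    """12 mm sphere on a 1 mm grid with mild noise, plus its ground truth."""
    vol, mask, truth = make_geometric_phantom(
        PhantomSpec(shape=(40, 40, 40), radius_mm=12.0, foreground=200.0,
                    noise_sd=5.0, seed=7))
    return vol, mask, truth


@pytest.fixture
def small_random_pair(rng):
    """A small random volume + full ROI for texture tests."""
    data = rng.normal(50.0, 10.0, (6, 6, 6))
    vol = ImageVolume(data)
    mask = LabelMask(np.ones((6, 6, 6), dtype=np.int16))
    return vol, mask


def random_roi_volume(seed: int, shape=(6, 6, 6), p_roi=0.8, n_levels=6):
    """Random integer-valued volume with a random ROI (texture oracle input)."""
    r = np.random.default_rng(seed)
    data = r.integers(0, n_levels, size=shape).astype(float)
    roi = r.random(shape) < p_roi
    if not roi.any():
        roi[tuple(s // 2 for s in shape)] = True
    return ImageVolume(data), LabelMask(roi.astype(np.int16))
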
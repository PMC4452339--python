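import numpy as np
import pytest
from scipy import ndimage as ndi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def blob_mask(seed: int, shape=(72, 72), density=0.88, min_size=20) -> np.ndarray:
    """Random smooth blob mask: thresholded filtered noise, small objects
    dropped so every component has a genuine interior."""
    gen = np.random.default_rng(seed)
    field = ndi.gaussian_filter(gen.normal(size=shape), 4.0)
    mask = field > np.quantile(field, density)
    labeled, n = ndi.label(mask, structure=np.ones((3, 3), int))
    out = np.zeros(shape, bool)
    for comp in range(1, n + 1):
        sel = labeled == comp
        if sel.sum() >= min_size:
            out |= sel
    return out


def count_components(mask: np.ndarray) -> int:
    _, n = ndi.label(mask, structure=np.ones((3, 3), int))
    return int(n)
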
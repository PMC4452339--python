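"""Gray-threshold soft-tissue extraction and Gaussian pre-smoothing."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidParameterError
from .image import BinaryMask, Image2D, as_array, spacing_of

__all__ = ["extract_soft_tissue", "gaussian_smooth", "DEFAULT_GRAY_THRESHOLD"]

#: Default soft-tissue threshold on the 8-bit intensity scale.
DEFAULT_GRAY_THRESHOLD = 130.0

_TRUNCATE = 4.0  # kernel support in sigmas


def extract_soft_tissue(image, threshold: float = DEFAULT_GRAY_THRESHOLD) -> BinaryMask:
    """Binarize: mask is 1 where intensity >= ``threshold``, else 0.

    Vessels, airways and nodules are brighter than lung parenchyma, so a
    single gray threshold isolates the soft tissue.  The boundary value is
    assigned to the foreground.  16-bit integer inputs are rescaled to the
    8-bit range before comparison so the default threshold keeps its meaning.
    """
    data = as_array(image)
    raw = image.data if isinstance(image, (Image2D, BinaryMask)) else np.asarray(image)
    if not np.isfinite(threshold):
        raise InvalidParameterError(f"threshold must be finite, got {threshold}")
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        info = np.iinfo(np.asarray(raw).dtype)
        if not (info.min <= threshold <= info.max):
            raise InvalidParameterError(
                f"threshold {threshold} outside representable range [{info.min}, {info.max}]"
            )
    if np.issubdtype(np.asarray(raw).dtype, np.unsignedinteger) and np.asarray(raw).dtype.itemsize > 1:
        data = data * (255.0 / np.iinfo(np.asarray(raw).dtype).max)
    elif threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    return BinaryMask(data >= threshold, spacing_of(image))


def gaussian_smooth(image, sigma: float):
    """Convolve with a normalized 2D Gaussian kernel (truncated at 4 sigma,
    reflective boundaries).  ``sigma = 0`` is the identity."""
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    data = as_array(image)
    if sigma > 0:
        data = ndi.gaussian_filter(data, sigma, mode="reflect", truncate=_TRUNCATE)
    else:
        data = data.copy()
    if isinstance(image, Image2D):
        return Image2D(data, image.spacing_mm)
    return data
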
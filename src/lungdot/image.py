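"""Core raster types shared by every stage of the pipeline.

Coordinate convention (used everywhere in lungdot): images are indexed
``(row, col)``, 0-based, with pixel centers at integer coordinates.  When a
line is written ``alpha*x + beta*y + gamma = 0``, ``x`` is the column and
``y`` is the row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SPACING_MM = 0.6


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale image with isotropic physical pixel spacing."""

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"Image2D requires a non-empty 2D array, got shape {arr.shape}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask with the same grid and spacing as its source image."""

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("BinaryMask values must be 0 or 1")
            arr = arr.astype(bool)
        if arr.ndim != 2:
            raise ValueError(f"BinaryMask requires a 2D array, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def as_array(image) -> np.ndarray:
    """Unwrap an :class:`Image2D`/:class:`BinaryMask` or pass through an ndarray."""
    if isinstance(image, (Image2D, BinaryMask)):
        return image.data
    return np.asarray(image, dtype=np.float64)


def spacing_of(image, default: float = DEFAULT_SPACING_MM) -> float:
    if isinstance(image, (Image2D, BinaryMask)):
        return image.spacing_mm
    return default
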
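"""Synthetic test-image generators.

Every structure is built from two analytic models on the pixel grid:

* a *dot* ``d(x, y) = A * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))`` and
* a *line* ``l(x, y) = A * exp(-u^2 / (2 sigma^2))`` where ``u`` is the
  perpendicular distance to a finite segment (capped ends, so vessel ends
  exist and can produce blob-like responses).

Elements are composited by addition, so phantoms are linear in their
elements; intensities therefore lie in ``[0, sum of amplitudes]``.
Rendering is deterministic; optional additive noise is reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import InvalidParameterError
from .image import DEFAULT_SPACING_MM, Image2D

__all__ = [
    "PhantomSpec",
    "render_dot",
    "render_line",
    "render_spec",
    "make_dotline_panel",
    "make_vessel_phantom",
    "make_attached_nodule_phantom",
    "DOTLINE_PANEL_SHAPE",
    "DOTLINE_DOT_SIGMAS",
]


@dataclass(frozen=True)
class DotSpec:
    center: tuple[float, float]  # (row, col)
    sigma: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class LineSpec:
    p_start: tuple[float, float]  # (row, col)
    p_end: tuple[float, float]
    sigma: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a phantom scene.

    Invariants: all element centers lie inside the grid; sigmas are strictly
    positive; identical (spec, seed) pairs render bit-identical images.
    """

    shape: tuple[int, int]
    spacing_mm: float = DEFAULT_SPACING_MM
    elements: tuple[Any, ...] = field(default_factory=tuple)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nrow, ncol = self.shape
        if nrow <= 0 or ncol <= 0:
            raise InvalidParameterError(f"empty grid shape {self.shape}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for el in self.elements:
            if el.sigma <= 0:
                raise InvalidParameterError(f"element sigma must be > 0, got {el.sigma}")
            pts = [el.center] if isinstance(el, DotSpec) else [el.p_start, el.p_end]
            for r, c in pts:
                if not (0 <= r < nrow and 0 <= c < ncol):
                    raise InvalidParameterError(
                        f"element point ({r}, {c}) outside grid {self.shape}"
                    )


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    return rows, cols


def _dot_field(shape, center, sigma, amplitude) -> np.ndarray:
    rows, cols = _grid(shape)
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def _segment_distance(shape, p_start, p_end) -> np.ndarray:
    """Per-pixel Euclidean distance to the finite segment p_start--p_end."""
    rows, cols = _grid(shape)
    a = np.asarray(p_start, dtype=np.float64)
    d = np.asarray(p_end, dtype=np.float64) - a
    seg_len2 = float(d @ d)
    t = ((rows - a[0]) * d[0] + (cols - a[1]) * d[1]) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dr = rows - (a[0] + t * d[0])
    dc = cols - (a[1] + t * d[1])
    return np.hypot(dr, dc)


def _line_field(shape, p_start, p_end, sigma, amplitude) -> np.ndarray:
    u = _segment_distance(shape, p_start, p_end)
    return amplitude * np.exp(-(u**2) / (2.0 * sigma**2))


def render_dot(
    center: tuple[float, float],
    sigma: float,
    shape: tuple[int, int],
    amplitude: float = 1.0,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> Image2D:
    """Render a single Gaussian dot on an otherwise empty grid.

    The value at pixel (row, col) is
    ``amplitude * exp(-((row-cr)^2 + (col-cc)^2) / (2 sigma^2))``.
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    return Image2D(_dot_field(shape, center, sigma, amplitude), spacing_mm)


def render_line(
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    sigma: float,
    shape: tuple[int, int],
    amplitude: float = 1.0,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> Image2D:
    """Render a Gaussian-profile line segment (capped ends)."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    if tuple(p_start) == tuple(p_end):
        raise InvalidParameterError("line endpoints must be distinct")
    return Image2D(_line_field(shape, p_start, p_end, sigma, amplitude), spacing_mm)


def render_spec(spec: PhantomSpec) -> Image2D:
    """Render a :class:`PhantomSpec` by additive composition of its elements."""
    out = np.zeros(spec.shape, dtype=np.float64)
    for el in spec.elements:
        if isinstance(el, DotSpec):
            out += _dot_field(spec.shape, el.center, el.sigma, el.amplitude)
        elif isinstance(el, LineSpec):
            out += _line_field(spec.shape, el.p_start, el.p_end, el.sigma, el.amplitude)
        else:  # pragma: no cover
            raise InvalidParameterError(f"unknown element type {type(el).__name__}")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        np.clip(out, 0.0, None, out=out)
    return Image2D(out, spec.spacing_mm)


DOTLINE_PANEL_SHAPE = (300, 460)
DOTLINE_DOT_SIGMAS = (2.0, 4.0, 6.0, 8.0, 10.0)
_DOTLINE_DOT_CENTERS = ((75.0, 45.0), (75.0, 115.0), (75.0, 195.0), (75.0, 290.0), (75.0, 400.0))
_DOTLINE_LINES = (
    ((205.0, 40.0), (205.0, 160.0), 2.0),
    ((240.0, 200.0), (185.0, 320.0), 3.0),
    ((175.0, 360.0), (262.0, 430.0), 2.0),
)


def dotline_panel_spec(seed: int = 0, noise_sd: float = 0.0, amplitude: float = 1.0) -> PhantomSpec:
    """The five-dot / three-line panel layout as an editable spec."""
    elements: list[Any] = [
        DotSpec(center, sigma, amplitude)
        for center, sigma in zip(_DOTLINE_DOT_CENTERS, DOTLINE_DOT_SIGMAS)
    ]
    elements += [LineSpec(p0, p1, s, amplitude) for p0, p1, s in _DOTLINE_LINES]
    return PhantomSpec(
        shape=DOTLINE_PANEL_SHAPE,
        spacing_mm=1.0,
        elements=tuple(elements),
        noise_sd=noise_sd,
        seed=seed,
    )


def make_dotline_panel(seed: int = 0, noise_sd: float = 0.0, amplitude: float = 1.0) -> Image2D:
    """Render the dots-and-lines panel: five dots with sigma 2, 4, 6, 8, 10 px
    and three line structures, none touching the border."""
    return render_spec(dotline_panel_spec(seed=seed, noise_sd=noise_sd, amplitude=amplitude))


_VESSEL_KINDS = ("single", "Y", "X")


def vessel_segments(
    kind: str, shape: tuple[int, int] = (192, 192), margin: float = 30.0
) -> tuple[tuple[tuple[float, float], tuple[float, float]], ...]:
    """Centerline segments (as (row, col) endpoint pairs) for a vessel model."""
    if kind not in _VESSEL_KINDS:
        raise InvalidParameterError(f"unknown vessel kind {kind!r}; expected one of {_VESSEL_KINDS}")
    nrow, ncol = shape
    cr, cc = (nrow - 1) / 2.0, (ncol - 1) / 2.0
    if kind == "single":
        return (((cr, margin), (cr, ncol - 1 - margin)),)
    if kind == "Y":
        junction = (cr + 0.15 * nrow, cc)
        return (
            (junction, (margin, cc - 0.22 * ncol)),
            (junction, (margin, cc + 0.22 * ncol)),
            (junction, (nrow - 1 - margin, cc)),
        )
    return (
        ((margin, margin), (nrow - 1 - margin, ncol - 1 - margin)),
        ((margin, ncol - 1 - margin), (nrow - 1 - margin, margin)),
    )


def make_vessel_phantom(
    kind: str,
    shape: tuple[int, int] = (192, 192),
    sigma: float = 2.5,
    amplitude: float = 255.0,
    spacing_mm: float = DEFAULT_SPACING_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Image2D:
    """Render a vessel model: ``single`` (one segment), ``Y`` (three segments
    meeting at a junction) or ``X`` (two crossing segments)."""
    segs = vessel_segments(kind, shape)
    elements = tuple(LineSpec(p0, p1, sigma, amplitude) for p0, p1 in segs)
    spec = PhantomSpec(shape, spacing_mm, elements, noise_sd=noise_sd, seed=seed)
    return render_spec(spec)


def make_attached_nodule_phantom(
    offset_px: float,
    nodule_sigma: float = 5.0,
    shape: tuple[int, int] = (160, 160),
    vessel_sigma: float = 1.5,
    amplitude: float = 255.0,
    spacing_mm: float = DEFAULT_SPACING_MM,
    along_px: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Image2D, dict]:
    """A horizontal vessel with a Gaussian nodule adhering near one end.

    The nodule center sits ``along_px`` beyond the vessel tip along the axis
    (default 1.5 nodule sigmas, so the nodule hangs off the end but still
    overlaps the vessel) and ``offset_px`` perpendicular to it.  Returns the
    image plus a ground truth record with the nodule center/sigma and the
    vessel axis for parameter-recovery tests.
    """
    if nodule_sigma <= 0 or vessel_sigma <= 0:
        raise InvalidParameterError("sigmas must be > 0")
    if along_px is None:
        along_px = 1.5 * nodule_sigma
    nrow, ncol = shape
    # integer axis row: keeps the thresholded vessel symmetric about a pixel
    # row, so its skeleton does not carry a half-pixel offset
    cr = float(round((nrow - 1) / 2.0))
    p_start = (cr, 20.0)
    p_end = (cr, ncol - 50.0)
    center = (cr - offset_px, p_end[1] + along_px)
    if not (
        -3 * nodule_sigma < center[0] < nrow - 1 + 3 * nodule_sigma
        and -3 * nodule_sigma < center[1] < ncol - 1 + 3 * nodule_sigma
    ):
        raise InvalidParameterError(f"nodule center {center} lies fully off the grid {shape}")
    # adhesion requires the two thresholdable blobs to touch
    gap = float(np.hypot(offset_px, along_px)) - 2.0 * (nodule_sigma + vessel_sigma)
    if gap > 0:
        raise InvalidParameterError(
            f"offset {offset_px} px too large for adhesion with nodule_sigma={nodule_sigma}"
        )
    spec = PhantomSpec(
        shape,
        spacing_mm,
        (
            LineSpec(p_start, p_end, vessel_sigma, amplitude),
            DotSpec(center, nodule_sigma, amplitude),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )
    truth = {
        "nodule_center": center,
        "nodule_sigma": nodule_sigma,
        "vessel_axis": (p_start, p_end),
        "offset_px": float(offset_px),
        "offset_mm": float(offset_px) * spacing_mm,
        "spacing_mm": spacing_mm,
    }
    return render_spec(spec), truth
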
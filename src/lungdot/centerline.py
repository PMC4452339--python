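"""Binary thinning, spur pruning, gap bridging and local line fitting.

The thinning operator is the two-subiteration scheme driven by two
neighborhood quantities around a candidate pixel p1 (8-neighborhood in the
cyclic order p2..p9 = N, NE, E, SE, S, SW, W, NW):

* ``N(p1)`` — the number of nonzero neighbors, and
* ``T(p1)`` — the number of 0-to-1 transitions scanning p2, p3, ..., p9
  cyclically back to p2.

A border pixel is deleted in subiteration 1 when 2 <= N(p1) <= 6,
T(p1) == 1, p2*p4*p6 == 0 and p4*p6*p8 == 0; subiteration 2 swaps the last
two conditions for p2*p4*p8 == 0 and p2*p6*p8 == 0.  Deletion within a
subiteration is simultaneous (flag then delete), and the loop stops when a
full two-subiteration pass removes nothing — which makes the operator
idempotent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .errors import InsufficientSupportError, InvalidParameterError, VerticalLineError
from .image import BinaryMask, as_array, spacing_of

__all__ = [
    "Skeleton",
    "LineFit",
    "neighbor_count",
    "transition_count",
    "thin",
    "prune_spurs",
    "fill_gaps",
    "fit_line_local",
    "fit_deviation",
]

# offsets of p2..p9 relative to p1, in cyclic order N, NE, E, SE, S, SW, W, NW
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)

_EIGHT = np.ones((3, 3), dtype=int)
_NB_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)


def neighbor_count(nb: Sequence[int]) -> int:
    """N(p1): number of nonzero entries among the 8 neighbors p2..p9."""
    nb = tuple(nb)
    if len(nb) != 8 or any(v not in (0, 1) for v in nb):
        raise InvalidParameterError("neighborhood must be 8 binary values (p2..p9)")
    return int(sum(nb))


def transition_count(nb: Sequence[int]) -> int:
    """T(p1): number of 0->1 transitions scanning p2,p3,...,p9 and cyclically
    back to p2."""
    nb = tuple(nb)
    if len(nb) != 8 or any(v not in (0, 1) for v in nb):
        raise InvalidParameterError("neighborhood must be 8 binary values (p2..p9)")
    return sum(1 for i in range(8) if nb[i] == 0 and nb[(i + 1) % 8] == 1)


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide centerline of a binary region."""

    mask: np.ndarray  # bool
    spacing_mm: float = 0.6

    @property
    def pixels(self) -> np.ndarray:
        """(n, 2) array of skeleton pixel coordinates (row, col)."""
        return np.column_stack(np.nonzero(self.mask))

    def _neighbor_counts(self) -> np.ndarray:
        return ndi.convolve(self.mask.astype(int), _NB_KERNEL, mode="constant")

    @property
    def endpoints(self) -> np.ndarray:
        """Skeleton pixels with exactly one skeleton neighbor."""
        counts = self._neighbor_counts()
        return np.column_stack(np.nonzero(self.mask & (counts == 1)))

    @property
    def branch_points(self) -> np.ndarray:
        """Skeleton pixels with three or more skeleton neighbors."""
        counts = self._neighbor_counts()
        return np.column_stack(np.nonzero(self.mask & (counts >= 3)))

    def branch_point_clusters(self) -> int:
        """Number of 8-connected clusters of branch pixels (a thick junction
        can thin to a couple of adjacent branch pixels)."""
        bp = np.zeros_like(self.mask)
        pts = self.branch_points
        bp[pts[:, 0], pts[:, 1]] = True
        _, n = ndi.label(bp, structure=_EIGHT)
        return int(n)


def _neighbor_planes(img: np.ndarray) -> list[np.ndarray]:
    """The eight shifted copies of a 1-px zero-padded image, aligned to p1."""
    padded = np.pad(img, 1)
    planes = []
    for dr, dc in NEIGHBOR_OFFSETS:
        planes.append(padded[1 + dr : 1 + dr + img.shape[0], 1 + dc : 1 + dc + img.shape[1]])
    return planes


def _thin_pass(img: np.ndarray, step: int) -> int:
    p = _neighbor_planes(img)
    n = sum(p)
    t = sum((p[i] == 0) & (p[(i + 1) % 8] == 1) for i in range(8))
    p2, p4, p6, p8 = p[0], p[2], p[4], p[6]
    if step == 1:
        cond_cd = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
    else:
        cond_cd = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
    kill = (img == 1) & (n >= 2) & (n <= 6) & (t == 1) & cond_cd
    img[kill] = 0
    return int(kill.sum())


def thin(mask) -> Skeleton:
    """Thin a binary region to its one-pixel-wide, connectivity-preserving
    centerline (skeleton).

    The raw two-subiteration rules can fully erode certain small regions
    (2x2 blocks and some even-sided rounded blobs) — excessive corrosion the
    scheme is explicitly supposed to avoid.  Any source component left with
    no skeleton pixel is therefore re-seeded with its innermost pixel (the
    distance-transform maximum), keeping the component count invariant.
    """
    spacing = spacing_of(mask)
    src = as_array(mask).astype(bool)
    img = src.astype(np.uint8)
    while True:
        removed = _thin_pass(img, 1)
        removed += _thin_pass(img, 2)
        if removed == 0:
            break
    out = img.astype(bool)
    labeled, n = ndi.label(src, structure=_EIGHT)
    survivors = set(np.unique(labeled[out])) - {0}
    for comp in range(1, n + 1):
        if comp in survivors:
            continue
        sel = labeled == comp
        dist = ndi.distance_transform_edt(sel)
        out[np.unravel_index(int(dist.argmax()), out.shape)] = True
    return Skeleton(out, spacing)


def _trace_length(mask: np.ndarray, start: tuple[int, int], max_steps: int) -> int:
    """Walk from an endpoint along the skeleton; stop at a junction (>= 3
    neighbors), a dead end, or after ``max_steps`` steps.  Returns the number
    of steps taken (capped at max_steps)."""
    nrow, ncol = mask.shape

    def nbrs(pt):
        r, c = pt
        out = []
        for dr, dc in NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and mask[rr, cc]:
                out.append((rr, cc))
        return out

    prev = None
    cur = start
    steps = 0
    while steps < max_steps:
        neighbors = [q for q in nbrs(cur) if q != prev]
        if prev is not None:
            # drop neighbors adjacent to prev that are just diagonal shortcuts
            neighbors = [q for q in neighbors if q != prev]
        if len(nbrs(cur)) >= 3 and cur != start:
            return steps  # reached a junction: branch ends here
        if not neighbors:
            return steps
        prev, cur = cur, neighbors[0]
        steps += 1
    return steps


def prune_spurs(skeleton: Skeleton, iterations: int, protect_factor: float = 5.0) -> Skeleton:
    """Iteratively delete skeleton endpoints (burrs).

    Per iteration every current endpoint is removed unless the branch it
    terminates is longer than ``protect_factor * iterations`` pixels — that
    keeps genuine vessel ends from eroding while short spurs vanish.
    ``iterations = 0`` is the identity.
    """
    if iterations < 0:
        raise InvalidParameterError(f"iterations must be >= 0, got {iterations}")
    mask = skeleton.mask.copy()
    protect_len = int(np.ceil(protect_factor * iterations)) if iterations else 0
    for _ in range(iterations):
        counts = ndi.convolve(mask.astype(int), _NB_KERNEL, mode="constant")
        ends = np.column_stack(np.nonzero(mask & (counts == 1)))
        removed = 0
        for r, c in ends:
            if _trace_length(mask, (int(r), int(c)), protect_len + 1) <= protect_len:
                mask[r, c] = False
                removed += 1
        if removed == 0:
            break
    return Skeleton(mask, skeleton.spacing_mm)


def _equivalent_diameter(area: int) -> float:
    return 2.0 * float(np.sqrt(area / np.pi))


def fill_gaps(mask, removed_regions: Iterable[np.ndarray], max_gap_px: float | None = None):
    """Bridge mask components separated by removed suspect regions.

    ``removed_regions`` are (n, 2) pixel-coordinate arrays of the footprints
    deleted from the mask.  When a footprint separates two or more
    components that each lie within ``max_gap_px`` of it (default: twice the
    footprint's equivalent diameter), straight 1-px bridges are drawn from
    each component's nearest pixel through the footprint's center, so the
    repaired vessel passes through the removed area (a crossing stays a
    crossing).  Components farther apart than the reach are left alone.
    Never increases the component count.
    """
    spacing = spacing_of(mask)
    out = as_array(mask).astype(bool)
    regions = [np.asarray(r) for r in removed_regions if len(r)]
    if not regions:
        return BinaryMask(out.copy(), spacing)
    out = out.copy()
    for region in regions:
        gap = max_gap_px if max_gap_px is not None else 2.0 * _equivalent_diameter(len(region))
        labeled, n = ndi.label(out, structure=_EIGHT)
        if n < 2:
            continue
        centroid = region.mean(axis=0)
        reach = gap + np.linalg.norm(region - centroid, axis=1).max() + 1.0
        anchors: list[np.ndarray] = []
        for comp in range(1, n + 1):
            pts = np.column_stack(np.nonzero(labeled == comp))
            close = pts[np.linalg.norm(pts - centroid, axis=1) <= reach]
            if not len(close):
                continue
            d = np.linalg.norm(close[:, None, :] - region[None, :, :], axis=2)
            if float(d.min()) <= gap:
                anchors.append(close[int(np.unravel_index(d.argmin(), d.shape)[0])])
        if len(anchors) < 2:
            continue
        hub = np.rint(centroid).astype(int)
        for pt in anchors:
            rr, cc = draw_line(int(pt[0]), int(pt[1]), int(hub[0]), int(hub[1]))
            out[rr, cc] = True
    return BinaryMask(out, spacing)


@dataclass(frozen=True)
class LineFit:
    """Total-least-squares line ``alpha*x + beta*y + gamma = 0`` with
    ``alpha**2 + beta**2 == 1`` (x = column, y = row)."""

    alpha: float
    beta: float
    gamma: float

    _TOL = 1e-12

    @property
    def slope(self) -> float:
        """-alpha/beta (the dy/dx slope of the line)."""
        if abs(self.beta) < self._TOL:
            raise VerticalLineError("vertical line: slope -alpha/beta is undefined")
        return -self.alpha / self.beta

    @property
    def intercept(self) -> float:
        """-gamma/beta (the y value at x = 0)."""
        if abs(self.beta) < self._TOL:
            raise VerticalLineError("vertical line: intercept -gamma/beta is undefined")
        return -self.gamma / self.beta

    def distance(self, point: tuple[float, float]) -> float:
        """Perpendicular distance from a (row, col) point to the line."""
        y, x = point
        return abs(self.alpha * x + self.beta * y + self.gamma)


def fit_line_local(skeleton: Skeleton, anchor_point: tuple[float, float], window: int = 15) -> LineFit:
    """Fit a TLS line to the ``window`` skeleton pixels nearest the anchor.

    The line is the principal axis of the selected pixels' scatter; its
    normal gives (alpha, beta) directly.
    """
    pts = skeleton.pixels
    if len(pts) < 2:
        raise InsufficientSupportError(f"need >= 2 skeleton pixels, have {len(pts)}")
    anchor = np.asarray(anchor_point, dtype=float)
    order = np.argsort(np.linalg.norm(pts - anchor, axis=1), kind="stable")
    sel = pts[order[: max(2, int(window))]].astype(float)
    x = sel[:, 1]
    y = sel[:, 0]
    xm, ym = x.mean(), y.mean()
    cov = np.cov(np.stack([x - xm, y - ym]), bias=True)
    evals, evecs = np.linalg.eigh(cov)
    alpha, beta = evecs[:, 0]  # eigenvector of the smaller eigenvalue = normal
    if beta < 0 or (beta == 0 and alpha < 0):
        alpha, beta = -alpha, -beta
    gamma = -(alpha * xm + beta * ym)
    return LineFit(float(alpha), float(beta), float(gamma))


def fit_deviation(fits: Sequence[LineFit]) -> tuple[float, float]:
    """Spread (population SD) of -alpha/beta and -gamma/beta over replicate
    fits — small values mean a stable centerline extraction."""
    if len(fits) < 2:
        raise InsufficientSupportError("need >= 2 replicate fits")
    slopes = np.array([f.slope for f in fits])  # raises VerticalLineError if beta == 0
    intercepts = np.array([f.intercept for f in fits])
    return float(np.std(slopes)), float(np.std(intercepts))
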
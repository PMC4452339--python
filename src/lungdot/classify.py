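"""Suspect-to-skeleton distances, the 1.5 mm decision rules, and the full
detection pipeline.

Two distances are measured for every suspect region:

* ``d1`` — perpendicular distance (mm) from the suspect's response-weighted
  centroid to the line fitted through the skeleton pixels nearest it, and
* ``d2`` — minimum distance (mm) from the centroid to any skeleton pixel.

With threshold t (default 1.5 mm): ``d1 > t`` means the centroid sits off
the vessel axis — an attached nodule; ``d1 <= t`` with ``d2 > t`` means the
centroid lies on the (extrapolated) axis but beyond the skeleton — a vessel
end; both small means a vessel intersection or end.  Equality goes to the
vessel classes (conservative: fewer nodule calls).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .centerline import Skeleton, fill_gaps, fit_line_local, prune_spurs, thin
from .config import PipelineConfig
from .dotfilter import SuspectRegion, extract_suspects, multiscale_dot_filter, sigma_schedule
from .errors import InsufficientSupportError, InvalidParameterError, NoSkeletonError
from .image import BinaryMask, Image2D, as_array, spacing_of
from .preprocess import extract_soft_tissue, gaussian_smooth

__all__ = [
    "LABEL_NODULE",
    "LABEL_VESSEL_END",
    "LABEL_INTERSECTION",
    "NoduleDecision",
    "DetectionReport",
    "suspect_distances",
    "decide",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

LABEL_NODULE = "attached_nodule"
LABEL_VESSEL_END = "vessel_end"
LABEL_INTERSECTION = "vessel_intersection_or_end"


@dataclass(frozen=True)
class NoduleDecision:
    """Classification record for one suspect region."""

    suspect: SuspectRegion
    d1_mm: float
    d2_mm: float
    label: str

    def to_record(self) -> dict:
        rec = self.suspect.to_record()
        rec.update(d1_mm=float(self.d1_mm), d2_mm=float(self.d2_mm), label=self.label)
        return rec


@dataclass
class DetectionReport:
    decisions: list[NoduleDecision]
    suspects: list[SuspectRegion]
    unclassifiable: list[SuspectRegion] = field(default_factory=list)
    config: PipelineConfig | None = None
    intermediates: dict = field(default_factory=dict)

    def labels(self) -> list[str]:
        return [d.label for d in self.decisions]

    def count(self, label: str) -> int:
        return sum(1 for d in self.decisions if d.label == label)


def suspect_distances(
    suspect: SuspectRegion,
    skeleton: Skeleton,
    spacing_mm: float,
    window: int = 15,
) -> tuple[float, float]:
    """(d1_mm, d2_mm) for one suspect against a skeleton.

    The local line is fitted at the skeleton pixel nearest the centroid.
    """
    pts = skeleton.pixels
    if len(pts) == 0:
        raise NoSkeletonError("skeleton is empty; suspect is unclassifiable")
    centroid = np.asarray(suspect.centroid, dtype=float)
    dists = np.linalg.norm(pts - centroid, axis=1)
    nearest = pts[int(dists.argmin())]
    d2_mm = float(dists.min()) * spacing_mm
    fit = fit_line_local(skeleton, tuple(nearest), window=window)
    d1_mm = fit.distance(tuple(centroid)) * spacing_mm
    return d1_mm, d2_mm


def decide(d1_mm: float, d2_mm: float, threshold_mm: float = 1.5) -> str:
    """Apply the distance rules: d1 > t -> attached nodule; d1 <= t and
    d2 > t -> vessel end; both <= t -> vessel intersection or end."""
    if threshold_mm <= 0:
        raise InvalidParameterError(f"threshold_mm must be > 0, got {threshold_mm}")
    if d1_mm < 0 or d2_mm < 0:
        raise InvalidParameterError("distances must be non-negative")
    if d1_mm > threshold_mm:
        return LABEL_NODULE
    if d2_mm > threshold_mm:
        return LABEL_VESSEL_END
    return LABEL_INTERSECTION


def _removal_footprint(
    suspect: SuspectRegion, shape: tuple[int, int], factor: float
) -> np.ndarray:
    """Pixels to delete from the tissue mask for one suspect: its response
    footprint dilated by a disk of radius ``factor * best_sigma_px``."""
    fp = np.zeros(shape, dtype=bool)
    fp[suspect.coords[:, 0], suspect.coords[:, 1]] = True
    radius = max(1, int(round(factor * max(suspect.best_sigma_px, 1.0))))
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    disk = yy * yy + xx * xx <= radius * radius
    return ndi.binary_dilation(fp, structure=disk)


def run_pipeline(image, config: PipelineConfig | None = None) -> DetectionReport:
    """Run the full detection chain on one image.

    Stages: soft-tissue thresholding -> Gaussian pre-smoothing -> multiscale
    dot filter -> suspect extraction -> suspect removal from the tissue mask
    -> gap filling -> thinning -> spur pruning -> per-suspect d1/d2 and the
    distance decision.
    """
    cfg = config or PipelineConfig()
    spacing = cfg.spacing_mm or spacing_of(image)
    if not spacing or spacing <= 0:
        raise InvalidParameterError("pixel spacing (mm) is required and must be > 0")
    data = as_array(image)
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.perf_counter()

    _stage("threshold")
    tissue = extract_soft_tissue(Image2D(data, spacing), cfg.threshold)
    if not tissue.data.any():
        warnings.warn("tissue mask is empty; nothing to detect", stacklevel=2)
        return DetectionReport([], [], config=cfg, intermediates={"tissue_mask": tissue})

    _stage("smooth")
    smoothed = gaussian_smooth(data, cfg.presmooth_sigma)

    _stage("dotfilter")
    schedule = sigma_schedule(cfg.r0_mm, cfg.r1_mm, cfg.n_scales)
    response, scale_map, stack = multiscale_dot_filter(
        smoothed, schedule.sigmas_px(spacing), normalize_scale=cfg.scale_norm,
        return_stack=True,
    )

    _stage("suspects")
    suspects = extract_suspects(
        response, cfg.rel_threshold, cfg.min_area_px, scale_map,
        scale_responses=stack, core_frac=cfg.core_frac,
    )
    # keep only suspects whose centroid falls on tissue
    suspects = [
        s
        for s in suspects
        if tissue.data[int(round(s.centroid[0])), int(round(s.centroid[1]))]
    ]
    logger.info("suspect regions on tissue: %d", len(suspects))

    _stage("remove+fill")
    vessel_mask = tissue.data.copy()
    removed = []
    for s in suspects:
        fp = _removal_footprint(s, vessel_mask.shape, cfg.removal_factor)
        removed.append(np.column_stack(np.nonzero(fp & tissue.data)))
        vessel_mask[fp] = False
    filled = fill_gaps(BinaryMask(vessel_mask, spacing), removed, None)

    _stage("skeleton")
    skeleton = prune_spurs(thin(filled), cfg.prune_iterations)

    _stage("classify")
    decisions: list[NoduleDecision] = []
    unclassifiable: list[SuspectRegion] = []
    for s in suspects:
        try:
            d1, d2 = suspect_distances(s, skeleton, spacing, window=cfg.window)
        except (NoSkeletonError, InsufficientSupportError) as exc:
            logger.warning("suspect %d unclassifiable: %s", s.label, exc)
            unclassifiable.append(s)
            continue
        decisions.append(NoduleDecision(s, d1, d2, decide(d1, d2, cfg.d_threshold_mm)))

    now = time.perf_counter()
    stages = list(timings)
    for a, b in zip(stages, stages[1:] + [None]):
        t0 = timings[a]
        t1 = timings[b] if b else now
        logger.info("stage %-12s %6.1f ms", a, (t1 - t0) * 1e3)

    return DetectionReport(
        decisions,
        suspects,
        unclassifiable=unclassifiable,
        config=cfg,
        intermediates={
            "tissue_mask": tissue,
            "response": response,
            "scale_map": scale_map,
            "vessel_mask": filled,
            "skeleton": skeleton,
        },
    )
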
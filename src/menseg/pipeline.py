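"""End-to-end orchestration: histogram → FCM → growing → KB rules → morphology.

`run_pipeline` is deterministic given (inputs, config): the only random
element is the FCM membership initialisation, driven by ``config.seed``.
The KB cascade is the main failure surface, so every rule decision is
collected in a :class:`~menseg.knowledge.KBTrace` and per-stage candidate
counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np
import yaml

from .histogram_fcm import ImagePair, build_intensity_histogram, fcm_cluster, defuzzify
from .region_growing import CandidateRegion, largest_connected_component, grow_region
from .knowledge import (
    KBTrace,
    LateralityResult,
    bounding_box_filter,
    laterality_analysis,
    side_filter,
    solidity_filter,
    area_filter,
    merge_selected,
)
from .morphology import refine_mask
from .metrics import SegMetrics, confusion, pm_cr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SegmentationResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; CLI flags override the YAML config file."""

    clusters: int = 32          # FCM cluster count (over-segmentation)
    fuzzifier: float = 2.0      # FCM exponent m
    eps: float = 1e-5           # FCM |dJ| stopping tolerance
    max_iter: int = 300
    seed: int = 0
    region_growing: bool = True
    k_sd: float = 2.0           # growth acceptance half-width, in seed SDs
    connectivity: int = 8
    restrict_growth: bool = False  # limit growth to the cluster's own pixels
    brain_threshold: int = 0    # brain mask: T1 or T2 strictly above this
    bbox_combine: str = "and"
    noise_floor: int = 50       # laterality histogram noise cutoff
    laterality_threshold: float = 0.95
    morph_radius: int = 1
    morph_element: str = "square"  # 3x3 square opening leaves solid convex masks intact

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class SegmentationResult:
    """Output bundle of one pipeline run.

    ``status`` is ``"success"`` or ``"no-tumor-found"`` (the KB cascade
    eliminated every candidate, the pipeline's documented failure mode on
    edematous cases).
    """

    status: str
    final_mask: Optional[np.ndarray]
    preliminary_mask: Optional[np.ndarray]
    candidates: list[CandidateRegion]
    laterality: Optional[LateralityResult]
    trace: KBTrace
    cluster_masks: list[np.ndarray] = field(default_factory=list)
    metrics: Optional[SegMetrics] = None
    stage_counts: dict[str, int] = field(default_factory=dict)


def _make_candidates(
    masks: list[np.ndarray], pair: ImagePair, config: PipelineConfig
) -> list[CandidateRegion]:
    candidates = []
    for cid, mask in enumerate(masks):
        if not mask.any():
            continue
        seed = largest_connected_component(mask, connectivity=config.connectivity)
        if config.region_growing:
            cand = grow_region(
                seed,
                pair,
                connectivity=config.connectivity,
                k_sd=config.k_sd,
                cluster_id=cid,
                restrict_to=mask if config.restrict_growth else None,
            )
        else:
            t1 = pair.t1.astype(float)
            t2 = pair.t2.astype(float)
            cand = CandidateRegion(
                cluster_id=cid,
                seed_mask=seed,
                grown_mask=mask,
                t1_mean=float(t1[seed].mean()),
                t2_mean=float(t2[seed].mean()),
                t1_sd=float(t1[seed].std()),
                t2_sd=float(t2[seed].std()),
            )
        candidates.append(cand)
    return candidates


def run_pipeline(
    pair: ImagePair,
    config: PipelineConfig | None = None,
    gt_mask: np.ndarray | None = None,
    manual_ids: list[int] | None = None,
) -> SegmentationResult:
    """Segment the tumor in a co-registered T1/T2 pair.

    With `manual_ids` (semi-supervised mode) the operator's cluster ids
    replace the automatic solidity/area selection; rules (a) and (b) still
    apply.  If `gt_mask` is given, PM/CR are computed on the final mask.
    """
    config = config or PipelineConfig()
    trace = KBTrace()
    counts: dict[str, int] = {}

    hist = build_intensity_histogram(pair)
    partition = fcm_cluster(
        hist,
        c=config.clusters,
        m=config.fuzzifier,
        eps=config.eps,
        max_iter=config.max_iter,
        seed=config.seed,
    )
    cluster_masks = list(defuzzify(partition, hist, pair))
    candidates = _make_candidates(cluster_masks, pair, config)
    counts["clusters"] = len(cluster_masks)
    counts["candidates"] = len(candidates)

    brain_mask = (pair.t1 > config.brain_threshold) | (pair.t2 > config.brain_threshold)
    surviving = bounding_box_filter(candidates, brain_mask, trace, combine=config.bbox_combine)
    counts["after_bounding_box"] = len(surviving)

    laterality = laterality_analysis(
        pair.t2, noise_floor=config.noise_floor, threshold=config.laterality_threshold
    )
    midline_col = (pair.shape[1] - 1) / 2.0
    surviving = side_filter(surviving, laterality, midline_col, trace)
    counts["after_laterality"] = len(surviving)

    if manual_ids is not None:
        selected = surviving
    else:
        selected = solidity_filter(surviving, trace)
        counts["after_solidity"] = len(selected)
        selected = area_filter(selected, trace)
        counts["after_area"] = len(selected)
    logger.info("KB cascade candidate counts: %s", counts)

    if not selected and manual_ids is None:
        return SegmentationResult(
            status="no-tumor-found",
            final_mask=None,
            preliminary_mask=None,
            candidates=candidates,
            laterality=laterality,
            trace=trace,
            cluster_masks=cluster_masks,
            stage_counts=counts,
        )

    preliminary = merge_selected(selected, manual_ids=manual_ids)
    try:
        final = refine_mask(preliminary, radius=config.morph_radius, element=config.morph_element)
    except ValueError:
        logger.warning("morphological erosion annihilated the mask; falling back to radius 0")
        final = refine_mask(preliminary, radius=0)

    metrics = None
    if gt_mask is not None:
        metrics = pm_cr(confusion(final, gt_mask))
    return SegmentationResult(
        status="success",
        final_mask=final,
        preliminary_mask=preliminary,
        candidates=candidates,
        laterality=laterality,
        trace=trace,
        cluster_masks=cluster_masks,
        metrics=metrics,
        stage_counts=counts,
    )
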
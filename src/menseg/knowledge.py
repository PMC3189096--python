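"""Knowledge-based selection of tumor-containing candidate regions.

Four rules, applied in order, whittle the grown candidates down to the
group(s) that contain tumor, with no training data:

(a) bounding box - a candidate whose tight box is taller than half the
    brain box AND wider than half the brain box is normal tissue/background;
(b) laterality - meningioma is bright on T2, so the left- and right-half
    T2 histograms decorrelate when the tumor is lateral; candidates mostly
    on the non-tumor side are dropped (midline verdicts drop nothing);
(c) solidity - tumors are compact; a 2-way agglomerative split on solidity
    keeps the high-solidity group;
(d) area - a 2-way split on area drops small residual noise.

Survivors are OR-merged into one preliminary tumor mask.  A semi-supervised
variant lets the operator pick candidate ids instead of rules (c)+(d).
Every decision is recorded in a :class:`KBTrace` for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .region_growing import CandidateRegion

__all__ = [
    "LateralityResult",
    "KBTrace",
    "bounding_box_filter",
    "laterality_analysis",
    "side_filter",
    "solidity",
    "hierarchical_split",
    "solidity_filter",
    "area_filter",
    "merge_selected",
]


@dataclass(frozen=True)
class LateralityResult:
    """Verdict of the modified symmetrical-histogram analysis.

    ``correlation`` is Pearson's r between the left- and right-half T2
    histograms (bins >= the noise floor); ``reference_bin`` is the intensity
    where |left - right| is maximal (None for midline verdicts).
    """

    verdict: str  # "left" | "right" | "midline"
    correlation: float
    reference_bin: int | None


@dataclass
class KBTrace:
    """Per-candidate audit log of the KB cascade (one row per rule applied)."""

    records: list[dict] = field(default_factory=list)

    def log(self, cluster_id: int, rule: str, kept: bool, **features) -> None:
        self.records.append({"cluster_id": cluster_id, "rule": rule, "kept": kept, **features})

    def terminal_status(self) -> dict[int, bool]:
        """Final kept/eliminated status per candidate id."""
        status: dict[int, bool] = {}
        for rec in self.records:
            cid = rec["cluster_id"]
            if status.get(cid, True):  # once eliminated, stays eliminated
                status[cid] = rec["kept"]
        return status

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _bbox(mask: np.ndarray) -> tuple[int, int]:
    """(height, width) of the tight bounding box of a non-empty mask."""
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)


def bounding_box_filter(
    candidates: list[CandidateRegion],
    brain_mask: np.ndarray,
    trace: KBTrace | None = None,
    combine: str = "and",
) -> list[CandidateRegion]:
    """Rule (a): drop candidates whose box exceeds half the brain box.

    With ``combine="and"`` (default) a candidate is eliminated only when its
    box is taller than half the brain-box height AND wider than half the
    width; ``combine="or"`` eliminates on either excess (sensitivity
    analysis).
    """
    if combine not in ("and", "or"):
        raise ValueError(f"combine must be 'and' or 'or', got {combine!r}")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    bh, bw = _bbox(brain_mask)
    survivors = []
    for cand in candidates:
        h, w = _bbox(cand.grown_mask)
        too_tall, too_wide = h > bh / 2.0, w > bw / 2.0
        drop = (too_tall and too_wide) if combine == "and" else (too_tall or too_wide)
        if trace is not None:
            trace.log(cand.cluster_id, "bounding_box", not drop, box_h=h, box_w=w, brain_h=bh, brain_w=bw)
        if not drop:
            survivors.append(cand)
    return survivors


def _half_histograms(t2: np.ndarray, noise_floor: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left/right half T2 histograms over bins >= noise_floor, plus the bin values."""
    w = t2.shape[1]
    half = w // 2
    left, right = t2[:, :half], t2[:, w - half :]
    bins = np.arange(noise_floor, 256)
    left_h = np.bincount(left.ravel(), minlength=256)[noise_floor:]
    right_h = np.bincount(right.ravel(), minlength=256)[noise_floor:]
    return left_h.astype(np.int64), right_h.astype(np.int64), bins


def laterality_analysis(
    t2: np.ndarray,
    noise_floor: int = 50,
    threshold: float = 0.95,
) -> LateralityResult:
    """Rule (b) stage 1: locate the tumor hemisphere from T2 half-histograms.

    Pixels below `noise_floor` are discarded as noise.  If the Pearson
    correlation of the two half-histograms exceeds `threshold` the halves
    are symmetric and the tumor may sit at the midline; otherwise the side
    with the higher count at the maximal |left - right| bin (the reference
    point) is called as the tumor side.

    Assumes a well-centered slice (midline = central column); with an odd
    width the central column belongs to neither half.
    """
    t2 = np.asarray(t2)
    left_h, right_h, bins = _half_histograms(t2, noise_floor)
    if left_h.sum() == 0 and right_h.sum() == 0:
        raise ValueError(f"no pixels at or above the noise floor {noise_floor}")
    if np.array_equal(left_h, right_h):
        r = 1.0  # exact mirror symmetry
    elif left_h.std() == 0 or right_h.std() == 0:
        r = 0.0  # a flat histogram carries no shape to correlate
    else:
        r = float(np.corrcoef(left_h, right_h)[0, 1])
    if r > threshold:
        return LateralityResult(verdict="midline", correlation=r, reference_bin=None)
    diff = np.abs(left_h - right_h)
    ref = int(np.argmax(diff))
    verdict = "left" if left_h[ref] > right_h[ref] else "right"
    return LateralityResult(verdict=verdict, correlation=r, reference_bin=int(bins[ref]))


def side_filter(
    candidates: list[CandidateRegion],
    laterality: LateralityResult,
    midline_column: float,
    trace: KBTrace | None = None,
) -> list[CandidateRegion]:
    """Rule (b) stage 2: drop candidates mostly on the non-tumor side.

    A candidate is eliminated iff strictly more than half of its pixels lie
    strictly on the opposite hemisphere.  Midline verdicts keep everything.
    """
    survivors = []
    for cand in candidates:
        if laterality.verdict == "midline":
            if trace is not None:
                trace.log(cand.cluster_id, "laterality", True, verdict="midline", off_side_fraction=0.0)
            survivors.append(cand)
            continue
        cols = np.nonzero(cand.grown_mask)[1]
        if laterality.verdict == "left":
            off = cols > midline_column
        else:
            off = cols < midline_column
        frac = float(off.mean()) if cols.size else 0.0
        drop = frac > 0.5
        if trace is not None:
            trace.log(cand.cluster_id, "laterality", not drop, verdict=laterality.verdict, off_side_fraction=frac)
        if not drop:
            survivors.append(cand)
    return survivors


def _hull_pixel_area(points: np.ndarray) -> int:
    """Number of pixel centers inside (or on) the convex hull of `points`.

    Degenerate (collinear) point sets fall back to counting the integer
    points on the extremal segment.
    """
    try:
        hull = ConvexHull(points)
    except QhullError:
        # all points collinear: pixels on the segment between the extremes
        p = points[np.lexsort((points[:, 1], points[:, 0]))]
        a, b = p[0], p[-1]
        d = b - a
        if d[0] == 0 and d[1] == 0:
            return 1
        g = gcd(int(abs(d[0])), int(abs(d[1])))
        return g + 1
    rmin, cmin = points.min(axis=0)
    rmax, cmax = points.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    pts = np.stack([rr.ravel(), cc.ravel(), np.ones(rr.size)], axis=1)
    # inside iff every hull facet's signed distance <= 0 (with fp slack)
    inside = (pts @ hull.equations.T <= 1e-9).all(axis=1)
    return int(inside.sum())


def solidity(mask: np.ndarray) -> float:
    """Region area divided by the pixel area of its convex hull; in (0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute solidity of an empty mask")
    points = np.argwhere(mask).astype(np.float64)
    return float(mask.sum()) / _hull_pixel_area(points)


def hierarchical_split(values: list[float], keep: str = "higher") -> list[int]:
    """Split 1-D `values` into 2 groups by agglomerative clustering; keep one.

    Singleton clusters merge bottom-up under average linkage (mean absolute
    difference between cluster members) until two clusters remain; the
    indices of the cluster with the higher (or lower) mean are returned.
    With a single value it is trivially kept; if the two final cluster means
    tie, the cluster containing the lowest original index wins.
    """
    if keep not in ("higher", "lower"):
        raise ValueError(f"keep must be 'higher' or 'lower', got {keep!r}")
    vals = [float(v) for v in values]
    if len(vals) == 0:
        raise ValueError("cannot split an empty value list")
    if len(vals) == 1:
        return [0]
    clusters: list[list[int]] = [[i] for i in range(len(vals))]
    while len(clusters) > 2:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([abs(vals[i] - vals[j]) for i in clusters[a] for j in clusters[b]])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    means = [float(np.mean([vals[i] for i in cl])) for cl in clusters]
    if means[0] == means[1]:
        chosen = clusters[0] if min(clusters[0]) < min(clusters[1]) else clusters[1]
    elif keep == "higher":
        chosen = clusters[int(np.argmax(means))]
    else:
        chosen = clusters[int(np.argmin(means))]
    return sorted(chosen)


def _split_filter(
    candidates: list[CandidateRegion],
    values: list[float],
    rule: str,
    trace: KBTrace | None,
) -> list[CandidateRegion]:
    if not candidates:
        return []
    if len(candidates) == 1 or len(set(values)) == 1:
        # no meaningful 2-split: fail open and keep everything
        for cand, v in zip(candidates, values):
            if trace is not None:
                trace.log(cand.cluster_id, rule, True, **{rule: v})
        return list(candidates)
    kept = set(hierarchical_split(values, keep="higher"))
    survivors = []
    for idx, (cand, v) in enumerate(zip(candidates, values)):
        if trace is not None:
            trace.log(cand.cluster_id, rule, idx in kept, **{rule: v})
        if idx in kept:
            survivors.append(cand)
    return survivors


def solidity_filter(
    candidates: list[CandidateRegion], trace: KBTrace | None = None
) -> list[CandidateRegion]:
    """Rule (c): keep the high-solidity group of candidates."""
    return _split_filter(candidates, [solidity(c.grown_mask) for c in candidates], "solidity", trace)


def area_filter(
    candidates: list[CandidateRegion], trace: KBTrace | None = None
) -> list[CandidateRegion]:
    """Rule (d): keep the large-area group of candidates."""
    return _split_filter(candidates, [float(c.area) for c in candidates], "area", trace)


def merge_selected(
    candidates: list[CandidateRegion],
    manual_ids: list[int] | None = None,
) -> np.ndarray:
    """OR-merge surviving candidate masks into one preliminary tumor mask.

    In semi-supervised mode `manual_ids` names the cluster ids to merge
    (replacing the automatic solidity/area selection); unknown ids raise.
    Raises ``ValueError`` when nothing is selected.
    """
    if manual_ids is not None:
        by_id = {c.cluster_id: c for c in candidates}
        unknown = [i for i in manual_ids if i not in by_id]
        if unknown:
            raise ValueError(f"unknown candidate ids: {unknown}; have {sorted(by_id)}")
        chosen = [by_id[i] for i in manual_ids]
    else:
        chosen = list(candidates)
    if not chosen:
        raise ValueError("no candidates selected: nothing to merge")
    merged = np.zeros_like(chosen[0].grown_mask, dtype=bool)
    for cand in chosen:
        merged |= cand.grown_mask
    return merged
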
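"""Seeded region growing for post-clustering binary fragments.

Defuzzified cluster masks are typically noisy and fragmented.  Each mask is
seeded from its largest connected component; the seed's T1/T2 mean and SD
are computed once and FROZEN, and any pixel adjacent to the growing region
whose T1 AND T2 intensities both lie within ``mean ± k_sd * SD`` of those
frozen seed statistics is merged, until no qualifying neighbor remains.

Because the acceptance predicate is a fixed per-pixel test, the grown
region equals the connected component - through eligible or seed pixels -
containing the seed, which is what the implementation computes in one
labeling pass instead of an explicit breadth-first loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .histogram_fcm import ImagePair

__all__ = ["CandidateRegion", "largest_connected_component", "grow_region"]

_STRUCTS = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class CandidateRegion:
    """One grown candidate: seed mask, grown mask and frozen seed statistics."""

    cluster_id: int
    seed_mask: np.ndarray
    grown_mask: np.ndarray
    t1_mean: float
    t2_mean: float
    t1_sd: float
    t2_sd: float

    @property
    def area(self) -> int:
        return int(self.grown_mask.sum())


def _check_connectivity(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return _STRUCTS[connectivity]


def largest_connected_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Return the single largest connected component of a non-empty binary mask.

    Ties break to the component whose label scipy assigns first (raster
    order).  Raises ``ValueError`` on an empty mask so callers can drop the
    cluster.
    """
    struct = _check_connectivity(connectivity)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty: cluster has no pixels")
    labels, n = ndimage.label(mask, structure=struct)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    return labels == (int(np.argmax(sizes)) + 1)


def grow_region(
    seed_mask: np.ndarray,
    pair: ImagePair,
    connectivity: int = 8,
    k_sd: float = 2.0,
    cluster_id: int = -1,
    restrict_to: np.ndarray | None = None,
) -> CandidateRegion:
    """Grow `seed_mask` over `pair` by the frozen mean ± `k_sd`·SD criterion.

    Both channels must be in range (conjunction).  A single-pixel seed has
    SD 0, so only pixels exactly matching the seed intensities can merge.
    `restrict_to` optionally limits growth candidates to a mask (e.g. the
    cluster's own defuzzified pixels); by default any image pixel may merge.
    """
    struct = _check_connectivity(connectivity)
    seed = np.asarray(seed_mask, dtype=bool)
    if not seed.any():
        raise ValueError("seed mask is empty")
    if seed.shape != pair.shape:
        raise ValueError(f"seed shape {seed.shape} != image shape {pair.shape}")

    t1 = pair.t1.astype(np.float64)
    t2 = pair.t2.astype(np.float64)
    t1_mean, t1_sd = float(t1[seed].mean()), float(t1[seed].std())
    t2_mean, t2_sd = float(t2[seed].mean()), float(t2[seed].std())

    eligible = (
        (np.abs(t1 - t1_mean) <= k_sd * t1_sd)
        & (np.abs(t2 - t2_mean) <= k_sd * t2_sd)
    )
    if restrict_to is not None:
        eligible &= np.asarray(restrict_to, dtype=bool)
    # BFS from the seed over eligible pixels == connected components of
    # (eligible | seed) that intersect the seed.
    labels, _ = ndimage.label(eligible | seed, structure=struct)
    seed_labels = np.unique(labels[seed])
    grown = np.isin(labels, seed_labels[seed_labels > 0])
    return CandidateRegion(
        cluster_id=cluster_id,
        seed_mask=seed,
        grown_mask=grown,
        t1_mean=t1_mean,
        t2_mean=t2_mean,
        t1_sd=t1_sd,
        t2_sd=t2_sd,
    )
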
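"""Joint T1/T2 intensity histogram and fuzzy c-means clustering over its bins.

Each pixel of a co-registered 8-bit T1/T2 pair is a point
``x_k = (t1_k, t2_k)`` in the 256x256 intensity plane.  The pair is reduced
to a joint histogram (bin counts), and fuzzy c-means (FCM) is run over the
*occupied bins*, weighting each bin by its pixel count.  This minimises the
same objective as per-pixel FCM

    J = sum_k sum_i u_ik^m ||x_k - v_i||^2

because pixels sharing a bin share coordinates, hence memberships - but at
the cost of the number of occupied bins (<= 65536) instead of the number of
pixels.  Defuzzification assigns every bin (hence every pixel) to its
maximal-membership cluster, producing ``c`` disjoint binary masks.

The cluster count ``c`` defaults to 32: deliberate over-segmentation so the
tumor separates into its own group(s), to be re-assembled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImagePair",
    "Histogram2D",
    "FuzzyPartition",
    "ClusterMaskSet",
    "build_intensity_histogram",
    "fcm_cluster",
    "defuzzify",
    "initial_memberships",
]

N_LEVELS = 256  # 8-bit intensity range


@dataclass(frozen=True)
class ImagePair:
    """A co-registered pair of 2D 8-bit grayscale slices (T1- and T2-weighted)."""

    t1: np.ndarray
    t2: np.ndarray

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1)
        t2 = np.asarray(self.t2)
        if t1.ndim != 2 or t2.ndim != 2:
            raise ValueError("t1 and t2 must be 2D arrays")
        if t1.shape != t2.shape:
            raise ValueError(
                f"T1 and T2 must be co-registered to the same grid; "
                f"got shapes {t1.shape} and {t2.shape}"
            )
        for name, arr in (("t1", t1), ("t2", t2)):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(f"{name} values outside the 8-bit range [0, 255]")
        object.__setattr__(self, "t1", t1.astype(np.uint8))
        object.__setattr__(self, "t2", t2.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1.shape

    @property
    def n_pixels(self) -> int:
        return int(self.t1.size)


@dataclass(frozen=True)
class Histogram2D:
    """256x256 joint (T1, T2) bin counts; ``counts[a, b]`` = pixels with T1=a, T2=b."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"counts must be {N_LEVELS}x{N_LEVELS}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        """Total pixel count."""
        return int(self.counts.sum())

    def occupied_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates (k, 2) of occupied bins and their counts (k,)."""
        t1_idx, t2_idx = np.nonzero(self.counts)
        coords = np.stack([t1_idx, t2_idx], axis=1).astype(np.float64)
        return coords, self.counts[t1_idx, t2_idx].astype(np.float64)


@dataclass
class FuzzyPartition:
    """Converged FCM state over the occupied histogram bins.

    ``memberships[i, k]`` is the grade of occupied bin ``k`` in cluster ``i``;
    columns sum to 1.  ``centers`` are (c, 2) points in the (T1, T2) plane.
    ``objective_trace`` records J after each iteration and is non-increasing.
    """

    c: int
    m: float
    memberships: np.ndarray
    centers: np.ndarray
    bin_coords: np.ndarray
    bin_counts: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    eps: float = 1e-5
    n_iter: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class ClusterMaskSet:
    """The ``c`` disjoint binary masks produced by defuzzification."""

    masks: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.masks[i]


def build_intensity_histogram(pair: ImagePair) -> Histogram2D:
    """Count pixels of `pair` into the 256x256 joint (T1, T2) intensity histogram."""
    flat = pair.t1.astype(np.int64).ravel() * N_LEVELS + pair.t2.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=N_LEVELS * N_LEVELS).reshape(N_LEVELS, N_LEVELS)
    return Histogram2D(counts=counts)


def initial_memberships(n_points: int, c: int, seed: int | None) -> np.ndarray:
    """Random membership matrix (c, n_points), columns normalised to sum to 1.

    Exposed so that an independent per-pixel FCM can be started from the
    identical fuzzy state for equivalence checks.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(c, n_points))
    return u / u.sum(axis=0, keepdims=True)


def _fcm_iterate(
    coords: np.ndarray,
    weights: np.ndarray,
    u: np.ndarray,
    m: float,
    eps: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    """Alternate the FCM center/membership updates until |dJ| <= eps.

    `weights` multiplies each point's contribution; with unit weights this is
    classical per-point FCM.
    """
    trace: list[float] = []
    centers = np.empty((u.shape[0], coords.shape[1]))
    prev_j = None
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m * weights  # (c, k)
        centers = (um @ coords) / um.sum(axis=1, keepdims=True)
        # squared distances bin->center, (c, k)
        d2 = ((coords[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
        # membership update: u_ik = 1 / sum_j (d_ik/d_jk)^(1/(m-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            zero_cols = ~np.isfinite(inv).all(axis=0)
            u = inv / inv.sum(axis=0, keepdims=True)
        if zero_cols.any():
            # a point coincides with >=1 center: full membership there, split on ties
            for k in np.nonzero(zero_cols)[0]:
                hits = d2[:, k] == 0.0
                u[:, k] = hits / hits.sum()
        j = float((u**m * weights * d2).sum())
        trace.append(j)
        if prev_j is not None and abs(prev_j - j) <= eps:
            break
        prev_j = j
    return centers, u, trace, it


def fcm_cluster(
    hist: Histogram2D,
    c: int = 32,
    m: float = 2.0,
    eps: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
) -> FuzzyPartition:
    """Partition the occupied bins of `hist` into `c` fuzzy clusters.

    Runs count-weighted FCM: the objective equals per-pixel FCM on the image
    the histogram came from.  Memberships start uniform-random (seeded) and
    the loop stops when the objective changes by at most `eps`, or after
    `max_iter` iterations.

    Raises ``ValueError`` if ``c < 1``, ``m <= 1`` or the histogram has fewer
    occupied bins than clusters.
    """
    if c < 1:
        raise ValueError(f"cluster count must be >= 1, got {c}")
    if m <= 1.0:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    coords, weights = hist.occupied_bins()
    k = coords.shape[0]
    if k < c:
        raise ValueError(f"histogram has {k} occupied bins, fewer than c={c} clusters")
    u0 = initial_memberships(k, c, seed)
    centers, u, trace, n_iter = _fcm_iterate(coords, weights, u0, m, eps, max_iter)
    return FuzzyPartition(
        c=c,
        m=m,
        memberships=u,
        centers=centers,
        bin_coords=coords,
        bin_counts=weights,
        objective_trace=trace,
        eps=eps,
        n_iter=n_iter,
        seed=seed,
    )


def defuzzify(partition: FuzzyPartition, hist: Histogram2D, pair: ImagePair) -> ClusterMaskSet:
    """Assign each pixel to its bin's maximal-membership cluster.

    Ties break to the lowest cluster index (``argmax`` convention).  Returns
    ``c`` binary masks that are pairwise disjoint and cover the image; clusters
    that win no bin yield empty masks, which downstream filters discard.
    """
    label_of_bin = np.argmax(partition.memberships, axis=0)  # (k,)
    lut = np.full((N_LEVELS, N_LEVELS), -1, dtype=np.int32)
    coords = partition.bin_coords.astype(np.intp)
    lut[coords[:, 0], coords[:, 1]] = label_of_bin
    pixel_labels = lut[pair.t1.astype(np.intp), pair.t2.astype(np.intp)]
    if (pixel_labels < 0).any():
        raise ValueError("image contains intensities absent from the clustered histogram")
    masks = [pixel_labels == i for i in range(partition.c)]
    return ClusterMaskSet(masks=masks)
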
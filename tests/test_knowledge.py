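"""Knowledge-based candidate selection rules and their oracles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from menseg.knowledge import (
    KBTrace,
    LateralityResult,
    area_filter,
    bounding_box_filter,
    hierarchical_split,
    laterality_analysis,
    merge_selected,
    side_filter,
    solidity,
    solidity_filter,
)
from menseg.phantom import PhantomSpec, generate_phantom
from menseg.region_growing import CandidateRegion


def make_candidate(mask, cluster_id=0):
    mask = np.asarray(mask, dtype=bool)
    return CandidateRegion(
        cluster_id=cluster_id, seed_mask=mask, grown_mask=mask,
        t1_mean=0.0, t2_mean=0.0, t1_sd=0.0, t2_sd=0.0,
    )


def box_candidate(shape, r, c, h, w, cluster_id=0):
    mask = np.zeros(shape, dtype=bool)
    mask[r : r + h, c : c + w] = True
    return make_candidate(mask, cluster_id)


class TestBoundingBox:
    brain = np.zeros((120, 120), dtype=bool)
    brain[10:110, 10:110] = True  # 100x100 brain box

    def test_full_brain_box_eliminated(self):
        cand = box_candidate((120, 120), 10, 10, 100, 100)
        assert bounding_box_filter([cand], self.brain) == []

    def test_single_pixel_kept(self):
        cand = box_candidate((120, 120), 50, 50, 1, 1)
        assert len(bounding_box_filter([cand], self.brain)) == 1

    @pytest.mark.parametrize(
        "h,w,kept_and,kept_or",
        [(60, 40, True, False), (40, 60, True, False), (60, 60, False, False), (40, 40, True, True)],
    )
    def test_and_or_variants(self, h, w, kept_and, kept_or):
        cand = box_candidate((120, 120), 12, 12, h, w)
        assert bool(bounding_box_filter([cand], self.brain, combine="and")) is kept_and
        assert bool(bounding_box_filter([cand], self.brain, combine="or")) is kept_or

    def test_empty_candidate_list_passes_through(self):
        assert bounding_box_filter([], self.brain) == []

    def test_empty_brain_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            bounding_box_filter([], np.zeros((5, 5), dtype=bool))


class TestLaterality:
    def test_mirror_symmetric_is_midline_with_unit_correlation(self):
        img = np.tile(np.r_[np.arange(128), np.arange(128)[::-1]], (64, 1)).astype(np.uint8)
        res = laterality_analysis(img)
        assert res.correlation == 1.0
        assert res.verdict == "midline"

    def test_bright_blob_left(self):
        # mirror-symmetric graded background, T2-bright mass in the left half
        img = np.tile(
            np.r_[np.linspace(60, 180, 32), np.linspace(180, 60, 32)], (64, 1)
        ).astype(np.uint8)
        img[18:34, 4:20] = 220
        res = laterality_analysis(img)
        assert res.verdict == "left"
        assert res.reference_bin == 220

    def test_phantom_right_tumor_detected_right(self):
        pair, _ = generate_phantom(PhantomSpec(tumor_position="right", noise_sd=5.0, seed=3))
        assert laterality_analysis(pair.t2).verdict == "right"

    def test_reflection_swaps_verdict(self):
        pair, _ = generate_phantom(PhantomSpec(tumor_position="left", noise_sd=5.0, seed=4))
        res = laterality_analysis(pair.t2)
        flipped = laterality_analysis(pair.t2[:, ::-1])
        assert res.verdict == "left" and flipped.verdict == "right"

    def test_all_below_noise_floor_raises(self):
        with pytest.raises(ValueError, match="noise floor"):
            laterality_analysis(np.full((32, 32), 10, dtype=np.uint8))


class TestSideFilter:
    midline = LateralityResult(verdict="left", correlation=0.5, reference_bin=200)

    def test_midline_keeps_all(self):
        cands = [box_candidate((40, 40), 5, 5, 10, 10), box_candidate((40, 40), 5, 25, 10, 10)]
        res = LateralityResult(verdict="midline", correlation=0.99, reference_bin=None)
        assert len(side_filter(cands, res, 19.5)) == 2

    def test_opposite_side_eliminated(self):
        cand = box_candidate((40, 40), 5, 30, 8, 8)  # entirely right
        assert side_filter([cand], self.midline, 19.5) == []

    def test_straddling_majority_side_kept(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 13:23] = True  # cols 13..22: 7 left of 19.5, 3 right
        assert len(side_filter([make_candidate(mask)], self.midline, 19.5)) == 1


def brute_force_hull_pixels(points):
    """Exhaustive point-in-hull test via half-plane (cross-product) checks."""
    from itertools import combinations

    pts = [tuple(p) for p in points]
    # hull edges: pairs where all points lie on one side
    def inside(q):
        # q is inside hull iff for every directed edge of the hull boundary it
        # is on the correct side; equivalently q is a convex combination -
        # here: q fails if there is a separating line through two points
        for a, b in combinations(pts, 2):
            ab = (b[0] - a[0], b[1] - a[1])
            side = None
            sep = True
            cross_q = ab[0] * (q[1] - a[1]) - ab[1] * (q[0] - a[0])
            for p in pts:
                cr = ab[0] * (p[1] - a[1]) - ab[1] * (p[0] - a[0])
                if cr > 1e-9:
                    if side == -1:
                        sep = False
                        break
                    side = 1
                elif cr < -1e-9:
                    if side == 1:
                        sep = False
                        break
                    side = -1
            if not sep or side is None:
                continue
            if side * cross_q < -1e-9:
                return False
        return True

    rmin = min(p[0] for p in pts)
    rmax = max(p[0] for p in pts)
    cmin = min(p[1] for p in pts)
    cmax = max(p[1] for p in pts)
    return sum(
        inside((r, c)) for r in range(int(rmin), int(rmax) + 1) for c in range(int(cmin), int(cmax) + 1)
    )


class TestSolidity:
    def test_filled_rectangle_is_one(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:12, 4:15] = True
        assert solidity(mask) == 1.0

    def test_l_shape_matches_hull_oracle(self):
        mask = np.zeros((13, 13), dtype=bool)
        mask[0:5, 0:5] = True
        mask[4:9, 4:9] = True
        pts = np.argwhere(mask)
        expected = mask.sum() / brute_force_hull_pixels(pts)
        assert solidity(mask) == pytest.approx(expected)

    def test_disk_is_nearly_solid(self):
        rr, cc = np.mgrid[0:50, 0:50]
        mask = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2
        assert solidity(mask) >= 0.95

    def test_random_masks_match_hull_oracle(self, rng):
        for _ in range(10):
            mask = np.zeros((12, 12), dtype=bool)
            idx = rng.random((12, 12)) < 0.2
            mask |= idx
            if mask.sum() < 3:
                continue
            expected = mask.sum() / brute_force_hull_pixels(np.argwhere(mask))
            assert solidity(mask) == pytest.approx(expected)

    def test_collinear_mask(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 2:8] = True
        assert solidity(mask) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            solidity(np.zeros((4, 4), dtype=bool))


def scipy_two_split(values):
    """Independent 2-cluster average-linkage split via scipy.hierarchy."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = fcluster(linkage(arr, method="average"), t=2, criterion="maxclust")
    groups = [np.nonzero(labels == g)[0] for g in np.unique(labels)]
    means = [arr[g].mean() for g in groups]
    return sorted(groups[int(np.argmax(means))].tolist())


class TestHierarchicalSplit:
    def test_clear_gap(self):
        assert hierarchical_split([0.9, 0.85, 0.2], keep="higher") == [0, 1]

    def test_tie_prefers_lowest_index_cluster(self):
        assert hierarchical_split([0.5, 0.5], keep="higher") == [0]

    def test_keep_lower(self):
        assert hierarchical_split([10.0, 1.0, 1.2], keep="lower") == [1, 2]

    def test_single_value_trivially_kept(self):
        assert hierarchical_split([0.7]) == [0]

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            values = rng.random(n).tolist()
            assert hierarchical_split(values, keep="higher") == scipy_two_split(values)

    def test_split_contiguous_in_sorted_order(self, rng):
        for _ in range(20):
            values = rng.random(8)
            kept = hierarchical_split(values.tolist(), keep="higher")
            order = np.argsort(values)
            ranks = sorted(np.searchsorted(values[order], values[kept]))
            assert ranks == list(range(len(values) - len(kept), len(values)))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hierarchical_split([])


class TestFeatureFilters:
    def test_low_solidity_candidate_dropped(self):
        c_solid1 = box_candidate((40, 40), 2, 2, 8, 8, cluster_id=0)
        c_solid2 = box_candidate((40, 40), 20, 20, 8, 8, cluster_id=1)
        ragged = np.zeros((40, 40), dtype=bool)
        ragged[2, 20:39:2] = True
        ragged[3, 20:39] = True
        c_ragged = make_candidate(ragged, cluster_id=2)
        kept = solidity_filter([c_solid1, c_solid2, c_ragged])
        assert [c.cluster_id for c in kept] == [0, 1]

    def test_equal_solidities_all_kept(self):
        cands = [box_candidate((30, 30), 2 + 10 * i, 2, 5, 5, cluster_id=i) for i in range(3)]
        assert len(solidity_filter(cands)) == 3

    def test_small_area_dropped(self):
        big1 = box_candidate((120, 120), 0, 0, 70, 72, cluster_id=0)   # 5040 px
        big2 = box_candidate((120, 120), 75, 0, 60, 80, cluster_id=1)  # 4800 px
        small = box_candidate((120, 120), 0, 100, 5, 8, cluster_id=2)  # 40 px
        kept = area_filter([big1, big2, small])
        assert [c.cluster_id for c in kept] == [0, 1]

    def test_single_candidate_kept(self):
        cand = box_candidate((20, 20), 1, 1, 3, 3)
        assert len(area_filter([cand])) == 1 and len(solidity_filter([cand])) == 1


class TestMergeAndTrace:
    def test_single_mask_identity(self):
        cand = box_candidate((20, 20), 2, 2, 5, 5)
        assert np.array_equal(merge_selected([cand]), cand.grown_mask)

    def test_disjoint_areas_add(self):
        a = box_candidate((30, 30), 0, 0, 10, 10, cluster_id=0)
        b = box_candidate((30, 30), 15, 15, 5, 10, cluster_id=1)
        assert merge_selected([a, b]).sum() == 150

    def test_overlap_inclusion_exclusion(self):
        a = box_candidate((30, 30), 0, 0, 10, 10, cluster_id=0)
        b = box_candidate((30, 30), 5, 5, 10, 10, cluster_id=1)
        inter = (a.grown_mask & b.grown_mask).sum()
        assert merge_selected([a, b]).sum() == 100 + 100 - inter

    def test_unknown_manual_id_raises(self):
        cand = box_candidate((20, 20), 2, 2, 5, 5, cluster_id=3)
        with pytest.raises(ValueError, match="unknown"):
            merge_selected([cand], manual_ids=[7])

    def test_manual_selection_overrides(self):
        a = box_candidate((30, 30), 0, 0, 4, 4, cluster_id=1)
        b = box_candidate((30, 30), 10, 10, 4, 4, cluster_id=2)
        assert np.array_equal(merge_selected([a, b], manual_ids=[2]), b.grown_mask)

    def test_trace_terminal_status_unique(self):
        trace = KBTrace()
        cands = [box_candidate((40, 40), 5, 5, 6, 6, cluster_id=i) for i in range(3)]
        brain = np.ones((40, 40), dtype=bool)
        survivors = bounding_box_filter(cands, brain, trace)
        solidity_filter(survivors, trace)
        status = trace.terminal_status()
        assert set(status) == {0, 1, 2}
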
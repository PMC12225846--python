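"""Inter-/intra-rater reliability statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from segqc.metrics import iou
from segqc.phantoms import SimulatedRaterSpec, make_rater_set
from segqc.reliability import (RaterAnnotationSet, agreement_vs_distance,
                               iarr, iarr_all, ierr_matrix, ierr_pair,
                               mean_round_mask, stratify_by_area, union_mask)


def toy_grid():
    """Hand-built 2-rater × 2-image × 3-round grid of 4×4 masks."""
    def m(coords):
        out = np.zeros((4, 4), dtype=np.uint8)
        for y, x in coords:
            out[y, x] = 1
        return out

    grid = np.empty((2, 2, 3), dtype=object)
    # rater 0, image 0: stable 2×2 block with a flickering corner
    grid[0, 0, 0] = m([(0, 0), (0, 1), (1, 0), (1, 1)])
    grid[0, 0, 1] = m([(0, 0), (0, 1), (1, 0)])
    grid[0, 0, 2] = m([(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)])
    # rater 0, image 1: identical rounds
    grid[0, 1, 0] = grid[0, 1, 1] = grid[0, 1, 2] = m([(2, 2), (2, 3)])
    # rater 1, image 0: shifted block
    grid[1, 0, 0] = m([(0, 1), (0, 2), (1, 1), (1, 2)])
    grid[1, 0, 1] = m([(0, 1), (0, 2), (1, 1)])
    grid[1, 0, 2] = m([(0, 1), (0, 2), (1, 1), (1, 2)])
    # rater 1, image 1: disagrees with rater 0 entirely
    grid[1, 1, 0] = grid[1, 1, 1] = m([(0, 0)])
    grid[1, 1, 2] = m([(0, 0), (0, 1)])
    return RaterAnnotationSet(grid)


def brute_ierr(s, i, j):
    """Oracle: union over rounds per rater, IoU per image, mean over images."""
    vals = []
    for k in range(s.n_images):
        ui = np.zeros_like(s.masks[i, k, 0])
        uj = np.zeros_like(s.masks[j, k, 0])
        for r in range(s.n_rounds):
            ui = ui | s.masks[i, k, r]
            uj = uj | s.masks[j, k, r]
        vals.append(iou(ui, uj))
    return float(np.mean(vals))


def brute_iarr(s, i):
    """Oracle: IoU over every round pair, averaged over images then pairs."""
    pair_vals = []
    for r, t in itertools.combinations(range(s.n_rounds), 2):
        pair_vals.append(np.mean([iou(s.masks[i, k, r], s.masks[i, k, t])
                                  for k in range(s.n_images)]))
    return float(np.mean(pair_vals))


class TestMeanRoundMask:
    def test_identical_rounds_return_the_mask(self):
        s = toy_grid()
        assert np.array_equal(mean_round_mask(s, 0, 1), s.masks[0, 1, 0])

    def test_all_ones_and_all_zeros_average_to_half(self):
        grid = np.empty((1, 1, 2), dtype=object)
        grid[0, 0, 0] = np.ones((3, 3), dtype=np.uint8)
        grid[0, 0, 1] = np.zeros((3, 3), dtype=np.uint8)
        s = RaterAnnotationSet(grid)
        assert np.allclose(mean_round_mask(s, 0, 0), 0.5)

    def test_three_round_average_takes_third_values(self):
        s = toy_grid()
        avg = mean_round_mask(s, 0, 0)
        assert set(np.round(np.unique(avg), 6)) <= {0.0, round(1 / 3, 6),
                                                    round(2 / 3, 6), 1.0}

    def test_threshold_equals_union_of_rounds(self):
        s = toy_grid()
        for i in range(2):
            for k in range(2):
                union = s.masks[i, k, 0] | s.masks[i, k, 1] | s.masks[i, k, 2]
                assert np.array_equal(union_mask(s, i, k), union)


class TestIeRR:
    def test_identical_raters_score_one(self):
        grid = np.empty((2, 2, 2), dtype=object)
        base = np.zeros((4, 4), dtype=np.uint8)
        base[1:3, 1:3] = 1
        for i in range(2):
            for k in range(2):
                for r in range(2):
                    grid[i, k, r] = base
        assert ierr_pair(RaterAnnotationSet(grid), 0, 1) == 1.0

    def test_disjoint_raters_score_zero(self):
        grid = np.empty((2, 1, 1), dtype=object)
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        grid[0, 0, 0], grid[1, 0, 0] = a, b
        assert ierr_pair(RaterAnnotationSet(grid), 0, 1) == 0.0

    def test_toy_grid_matches_brute_force_oracle(self):
        s = toy_grid()
        assert ierr_pair(s, 0, 1) == brute_ierr(s, 0, 1)

    def test_same_rater_rejected(self):
        with pytest.raises(ValueError):
            ierr_pair(toy_grid(), 1, 1)

    def test_matrix_symmetric_with_nan_diagonal(self):
        m = ierr_matrix(toy_grid())
        assert np.isnan(m[0, 0]) and np.isnan(m[1, 1])
        assert m[0, 1] == m[1, 0]
        assert 0.0 <= m[0, 1] <= 1.0


class TestIaRR:
    def test_identical_rounds_score_one(self):
        s = toy_grid()
        # rater 0 image 1 identical across rounds, but image 0 flickers:
        # build a single-image set from image 1 only
        grid = s.masks[:1, 1:2, :]
        assert iarr(RaterAnnotationSet(grid), 0) == 1.0

    def test_two_disjoint_rounds_score_zero(self):
        grid = np.empty((1, 1, 2), dtype=object)
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        grid[0, 0, 0], grid[0, 0, 1] = a, b
        assert iarr(RaterAnnotationSet(grid), 0) == 0.0

    def test_toy_grid_matches_brute_force_over_three_round_pairs(self):
        s = toy_grid()
        for i in range(2):
            assert iarr(s, i) == pytest.approx(brute_iarr(s, i), abs=1e-15)

    def test_single_round_rejected(self):
        grid = np.empty((1, 1, 1), dtype=object)
        grid[0, 0, 0] = np.zeros((2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            iarr(RaterAnnotationSet(grid), 0)


class TestStratification:
    def test_single_stratum_equals_global_values(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=3, n_images=6, n_rounds=3,
                                  bias_strength=1, round_noise=0.2)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:6], spec,
                                              np.random.default_rng(0)))
        table = stratify_by_area(s, area_edges=(0,))
        assert len(table) == 1
        assert table.iloc[0]["ierr_mean"] == pytest.approx(
            np.nanmean(ierr_matrix(s)))
        assert table.iloc[0]["iarr_mean"] == pytest.approx(
            iarr_all(s).mean())

    def test_empty_strata_are_absent_not_zero(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=2, n_images=4, n_rounds=2,
                                  bias_strength=0, round_noise=0.1)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:4], spec,
                                              np.random.default_rng(1)))
        table = stratify_by_area(s)  # phantoms all have area >= 20
        assert not ((table["area_lo"] == 0) & (table["area_hi"] == 20)).any()

    def test_noisy_small_areas_less_reliable_than_large(self):
        rng = np.random.default_rng(5)
        grid = np.empty((3, 6, 2), dtype=object)
        for k in range(6):
            small = k < 3
            base = np.zeros((32, 32), dtype=np.uint8)
            if small:
                base[15:18, 15:18] = 1  # 9 px
            else:
                base[4:28, 6:26] = 1    # 480 px
            for i in range(3):
                for r in range(2):
                    m = base.copy()
                    if small:  # jitter the tiny blob by a pixel per rater/round
                        m = np.roll(np.roll(base, rng.integers(-2, 3), 0),
                                    rng.integers(-2, 3), 1)
                    grid[i, k, r] = m
        table = stratify_by_area(RaterAnnotationSet(grid))
        small_row = table[table["area_hi"] == 20].iloc[0]
        large_row = table[np.isinf(table["area_hi"])].iloc[0]
        assert small_row["ierr_mean"] < large_row["ierr_mean"]


class TestAgreementVsDistance:
    def test_identical_masks_agree_everywhere(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=3, n_images=4, n_rounds=2,
                                  bias_strength=0, round_noise=0.0)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:4], spec,
                                              np.random.default_rng(0)))
        for ref in ("center", "edge"):
            prof = agreement_vs_distance(s, 5, ref)
            assert np.allclose(prof[~np.isnan(prof)], 1.0)

    def test_boundary_perturbations_lower_the_rim_rings(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=3, n_images=6, n_rounds=3,
                                  bias_strength=1, round_noise=0.25)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:6], spec,
                                              np.random.default_rng(2)))
        centre = agreement_vs_distance(s, 5, "center")
        assert centre[0] > 0.9
        assert centre[-1] < centre[0]
        edge = agreement_vs_distance(s, 5, "edge")
        assert edge[0] < 1.0

    def test_profile_values_bounded(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=2, n_images=4, n_rounds=2,
                                  bias_strength=1, round_noise=0.3)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:4], spec,
                                              np.random.default_rng(3)))
        prof = agreement_vs_distance(s, 6, "edge")
        valid = prof[~np.isnan(prof)]
        assert ((valid >= 0.0) & (valid <= 1.0)).all()

    def test_unknown_reference_rejected(self, phantom_pairs):
        spec = SimulatedRaterSpec(n_raters=2, n_images=2, n_rounds=2,
                                  bias_strength=0, round_noise=0.0)
        s = RaterAnnotationSet(make_rater_set(phantom_pairs[:2], spec,
                                              np.random.default_rng(0)))
        with pytest.raises(ValueError):
            agreement_vs_distance(s, 5, "corner")
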
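import warnings

import numpy as np
import pytest
from skimage import color as skcolor

from histofuse.cases import CaseProbabilities
from histofuse.patches import (PatchRecord, ReinhardStats, TissueMask,
                               aggregate_patch_votes, balance_by_rotation,
                               color_normalize, extract_patches_grid,
                               extract_patches_random, filter_patches_iforest,
                               reinhard_stats, select_effective_patches,
                               tissue_bounding_boxes, tissue_mask_hsv,
                               tissue_mask_otsu)

PINK = (220, 120, 170)     # saturated enough to count as tissue
WHITE = (255, 255, 255)    # glass background: zero saturation


def tile(h, w, rgb=WHITE):
    t = np.zeros((h, w, 3), dtype=np.uint8)
    t[:] = rgb
    return t


class TestTissueMaskHsv:
    def test_pure_white_glass_gives_empty_mask(self):
        tm = tissue_mask_hsv(tile(64, 64), min_hole=0, min_object=0)
        assert not tm.pixels.any()

    def test_pink_block_detected_exactly(self):
        t = tile(200, 200)
        t[40:140, 60:160] = PINK
        tm = tissue_mask_hsv(t, min_hole=0, min_object=0)
        expected = np.zeros((200, 200), bool)
        expected[40:140, 60:160] = True
        assert (tm.pixels == expected).all()

    def test_fully_in_range_tile_gives_full_mask(self):
        tm = tissue_mask_hsv(tile(32, 32, PINK), min_hole=0, min_object=0)
        assert tm.pixels.all()

    def test_small_holes_filled_and_clumps_removed(self):
        t = tile(100, 100)
        t[10:60, 10:60] = PINK
        t[30:33, 30:33] = WHITE     # 9-px hole
        t[80:83, 80:83] = PINK      # 9-px clump
        tm = tissue_mask_hsv(t, min_hole=16, min_object=16)
        assert tm.pixels[31, 31]          # hole filled
        assert not tm.pixels[81, 81]      # clump removed

    def test_degenerate_thresholds_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            tissue_mask_hsv(tile(8, 8), lo=(0.5, 0.5, 0.5), hi=(0.5, 0.5, 0.5),
                            min_hole=0, min_object=0)

    def test_lo_above_hi_rejected(self):
        with pytest.raises(ValueError):
            tissue_mask_hsv(tile(8, 8), lo=(0.9, 0, 0), hi=(0.1, 1, 1))


class TestTissueMaskOtsu:
    def test_bimodal_image_selects_darker_half(self):
        g = np.full((20, 20), 255.0)
        g[:, :10] = 0.0
        tm = tissue_mask_otsu(g)
        assert tm.pixels[:, :10].all()
        assert not tm.pixels[:, 10:].any()

    def test_inverted_image_gives_complementary_mask(self):
        rng = np.random.default_rng(0)
        g = np.where(rng.random((30, 30)) < 0.5, 40.0, 210.0)
        a = tissue_mask_otsu(g)
        b = tissue_mask_otsu(255.0 - g)
        assert (a.pixels == ~b.pixels).all()

    def test_threshold_matches_exhaustive_variance_search(self):
        """Otsu on a two-Gaussian histogram lands between the modes and
        agrees with a brute-force between-class-variance maximization."""
        rng = np.random.default_rng(1)
        g = np.concatenate([rng.normal(60, 10, 2000),
                            rng.normal(200, 10, 2000)])
        g = np.clip(g, 0, 255).round().reshape(40, 100)
        from skimage.filters import threshold_otsu

        t = threshold_otsu(g)
        assert 60 < t < 200
        # exhaustive search over integer thresholds
        best_t, best_var = None, -1.0
        flat = g.ravel()
        for cand in range(1, 255):
            w0 = (flat < cand).mean()
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            m0, m1 = flat[flat < cand].mean(), flat[flat >= cand].mean()
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_t, best_var = cand, var
        assert abs(t - best_t) <= 2

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            tissue_mask_otsu(np.full((10, 10), 7.0))


class TestBoundingBoxes:
    def test_empty_mask_no_boxes(self):
        assert tissue_bounding_boxes(TissueMask(np.zeros((10, 10), bool))) == []

    def test_two_blocks_exact_extents(self):
        m = np.zeros((20, 30), bool)
        m[2:6, 3:9] = True
        m[12:18, 20:25] = True
        boxes = sorted(tissue_bounding_boxes(TissueMask(m)))
        assert boxes == [(2, 3, 6, 9), (12, 20, 18, 25)]

    def test_full_mask_one_full_box(self):
        boxes = tissue_bounding_boxes(TissueMask(np.ones((10, 12), bool)))
        assert boxes == [(0, 0, 10, 12)]

    def test_scale_applied_to_coordinates(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        boxes = tissue_bounding_boxes(TissueMask(m, scale=32))
        assert boxes == [(32, 32, 96, 96)]


class TestExtractPatchesGrid:
    def test_448_box_yields_four_224_patches(self):
        t = tile(448, 448, PINK)
        patches = extract_patches_grid(t, [(0, 0, 448, 448)], size=224)
        assert len(patches) == 4
        assert {p.origin for p in patches} == {(0, 0), (0, 224), (224, 0),
                                               (224, 224)}

    def test_box_smaller_than_patch_yields_nothing(self):
        t = tile(100, 100, PINK)
        assert extract_patches_grid(t, [(0, 0, 50, 50)], size=64) == []

    def test_patch_pixels_are_bit_exact_crops(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        for p in extract_patches_grid(t, [(0, 0, 64, 64)], size=16, stride=24):
            r, c = p.origin
            assert (p.pixels == t[r:r + 16, c:c + 16]).all()


class TestExtractPatchesRandom:
    def test_twenty_patches_from_all_tissue_tile(self):
        t = tile(600, 600, PINK)
        tm = TissueMask(np.ones((600, 600), bool))
        patches = extract_patches_random(t, tm, size=448, n=20, seed=3)
        assert len(patches) == 20
        for p in patches:
            assert p.pixels.shape == (448, 448, 3)

    def test_single_valid_origin_when_full_coverage_required(self):
        t = tile(40, 40, PINK)
        m = np.zeros((40, 40), bool)
        m[10:26, 10:26] = True
        with pytest.warns(UserWarning, match="valid origins"):
            patches = extract_patches_random(t, TissueMask(m), size=16, n=3,
                                             min_tissue_frac=1.0, seed=0)
        assert {p.origin for p in patches} == {(10, 10)}

    def test_same_seed_reproduces_origins(self):
        t = tile(128, 128, PINK)
        tm = TissueMask(np.ones((128, 128), bool))
        a = extract_patches_random(t, tm, size=32, n=10, seed=7)
        b = extract_patches_random(t, tm, size=32, n=10, seed=7)
        assert [p.origin for p in a] == [p.origin for p in b]

    def test_fewer_valid_origins_than_requested_warns(self):
        t = tile(40, 40, PINK)
        m = np.zeros((40, 40), bool)
        m[0:16, 0:16] = True
        with pytest.warns(UserWarning, match="valid origins"):
            patches = extract_patches_random(t, TissueMask(m), size=16, n=50,
                                             min_tissue_frac=1.0, seed=0)
        assert len(patches) == 1


class TestColorNormalize:
    def _random_patch(self, seed=0):
        rng = np.random.default_rng(seed)
        px = rng.integers(60, 220, (32, 32, 3), dtype=np.uint8)
        return PatchRecord((0, 0), 32, px)

    def test_reinhard_matches_target_means(self):
        src = self._random_patch(1)
        target = reinhard_stats(self._random_patch(2).pixels)
        out = color_normalize(src, "reinhard", target)
        got = skcolor.rgb2lab(out.pixels / 255.0).reshape(-1, 3).mean(0)
        assert np.allclose(got, target.means, atol=1.0)

    def test_reinhard_identity_when_already_at_target(self):
        src = self._random_patch(3)
        target = reinhard_stats(src.pixels)
        out = color_normalize(src, "reinhard", target)
        assert np.abs(out.pixels.astype(int) - src.pixels.astype(int)).max() <= 2

    def test_reinhard_constant_patch_passes_through_with_warning(self):
        p = PatchRecord((0, 0), 8, tile(8, 8, (100, 100, 100)))
        with pytest.warns(UserWarning, match="constant"):
            out = color_normalize(p, "reinhard", ReinhardStats((50, 0, 0), (10, 5, 5)))
        assert (out.pixels == p.pixels).all()

    def test_hist_eq_spreads_two_levels_to_extremes(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:5] = 90
        px[5:] = 150
        out = color_normalize(PatchRecord((0, 0), 10, px), "hist_eq")
        assert set(np.unique(out.pixels)) == {0, 255}

    def test_reinhard_without_target_rejected(self):
        with pytest.raises(ValueError):
            color_normalize(self._random_patch(), "reinhard")


class TestIsolationForestFilter:
    def test_zero_contamination_keeps_all(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        assert filter_patches_iforest(list(X), 0.0) == list(range(30))

    def test_planted_distant_outliers_removed(self):
        """95 isotropic Gaussian points + 5 planted at 10 sigma: the filter
        at contamination 0.05 removes exactly the planted indices."""
        rng = np.random.default_rng(4)
        inliers = rng.normal(size=(95, 8))
        outliers = rng.normal(loc=10.0, size=(5, 8))
        X = np.vstack([inliers, outliers])
        kept = filter_patches_iforest(list(X), 0.05, seed=0)
        assert sorted(set(range(100)) - set(kept)) == [95, 96, 97, 98, 99]

    def test_kept_count_matches_contamination(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 5))
        kept = filter_patches_iforest(list(X), 0.1, seed=1)
        assert abs(len(kept) - int(np.ceil(0.9 * 80))) <= 1

    def test_contamination_half_or_more_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            filter_patches_iforest(list(X), 0.5)


def _patch(label, seed=0, size=16):
    rng = np.random.default_rng(seed)
    return PatchRecord((0, 0), size,
                       rng.integers(0, 256, (size, size, 3), dtype=np.uint8),
                       label=label)


class TestBalanceByRotation:
    def test_already_balanced_unchanged(self):
        patches = [_patch(0, 1), _patch(0, 2), _patch(1, 3), _patch(1, 4)]
        out = balance_by_rotation(patches, seed=0)
        assert len(out) == 4
        assert not any(p.augmented for p in out)

    def test_ten_vs_thirty_equalized_with_twenty_flagged_copies(self):
        patches = [_patch(0, i) for i in range(10)] + \
                  [_patch(1, 100 + i) for i in range(30)]
        out = balance_by_rotation(patches, seed=0)
        counts = {0: 0, 1: 0}
        flagged = 0
        for p in out:
            counts[p.label] += 1
            flagged += p.augmented
        assert counts == {0: 30, 1: 30}
        assert flagged == 20

    def test_originals_always_retained(self):
        patches = [_patch(0, i) for i in range(3)] + [_patch(1, 9)]
        out = balance_by_rotation(patches, seed=1)
        assert out[:4] == patches

    def test_unlabeled_patch_rejected(self):
        with pytest.raises(ValueError):
            balance_by_rotation([_patch(None, 0)])


def _prob_patch(p_oligo, seed=0):
    p = _patch(None, seed, size=4)
    p.probs = CaseProbabilities(p_oligo, 1 - p_oligo)
    return p


class TestSelectEffectivePatches:
    def test_zero_threshold_keeps_all(self):
        patches = [_prob_patch(0.6), _prob_patch(0.3)]
        assert select_effective_patches(patches, 0.0) == patches

    def test_099_threshold_keeps_only_confident(self):
        patches = [_prob_patch(0.995), _prob_patch(0.8), _prob_patch(0.991)]
        kept = select_effective_patches(patches, 0.99)
        assert kept == [patches[0], patches[2]]

    def test_fallback_to_single_most_confident(self):
        patches = [_prob_patch(0.6), _prob_patch(0.8), _prob_patch(0.7)]
        with pytest.warns(UserWarning, match="falling back"):
            kept = select_effective_patches(patches, 0.99)
        assert kept == [patches[1]]

    def test_missing_probs_rejected(self):
        with pytest.raises(ValueError):
            select_effective_patches([_patch(0)], 0.5)


class TestAggregatePatchVotes:
    def test_unanimous_patches(self):
        out = aggregate_patch_votes([_prob_patch(1.0), _prob_patch(1.0)])
        assert (out.p_oligo, out.p_astro) == (1.0, 0.0)

    @pytest.mark.parametrize("mode", ["mean_prob", "majority_frac"])
    def test_opposite_certain_patches_split_evenly(self, mode):
        out = aggregate_patch_votes([_prob_patch(1.0), _prob_patch(0.0)], mode)
        assert out.p_oligo == pytest.approx(0.5)

    def test_majority_ties_split_between_classes(self):
        out = aggregate_patch_votes([_prob_patch(0.5)], "majority_frac")
        assert out.p_oligo == pytest.approx(0.5)

    def test_output_is_a_distribution(self):
        rng = np.random.default_rng(8)
        patches = [_prob_patch(float(rng.uniform()), i) for i in range(9)]
        for mode in ("mean_prob", "majority_frac"):
            out = aggregate_patch_votes(patches, mode)
            assert out.p_oligo >= 0 and out.p_astro >= 0
            assert out.p_oligo + out.p_astro == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patch_votes([])
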
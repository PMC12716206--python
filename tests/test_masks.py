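"""Line-mask generation: exact counts, kept borders, run limits, scar extraction."""

import itertools

import numpy as np
import pytest

import partialscan as ps
from partialscan.errors import InfeasibleMaskError, ParameterError


class TestCounts:
    def test_round_half_up(self):
        assert ps.round_half_up(76.8) == 77
        assert ps.round_half_up(76.5) == 77
        assert ps.round_half_up(76.49) == 76

    @pytest.mark.parametrize("maker", [
        lambda: ps.random_line_mask(256, 0.30, seed=0),
        lambda: ps.random_line_mask(256, 0.30, max_consecutive=5, seed=1),
        lambda: ps.patterned_line_mask(256, 0.30, "fixed_distance"),
        lambda: ps.patterned_line_mask(256, 0.30, "geometric"),
        lambda: ps.patterned_line_mask(256, 0.30, "block", block_length=7),
    ])
    def test_exactly_77_skips_at_p30_m256(self, maker):
        lm = maker()
        assert lm.n_skipped == 77
        assert lm.keep[0] and lm.keep[-1]

    def test_p_zero_is_identity(self):
        lm = ps.random_line_mask(64, 0.0, seed=0)
        assert lm.n_skipped == 0 and lm.keep.all()

    def test_infeasible_fraction(self):
        with pytest.raises(InfeasibleMaskError):
            ps.random_line_mask(10, 0.95, seed=0)

    def test_too_few_lines(self):
        with pytest.raises(ParameterError):
            ps.random_line_mask(3, 0.1, seed=0)


class TestRandomMasks:
    def test_deterministic_per_seed(self):
        a = ps.random_line_mask(100, 0.3, seed=5)
        b = ps.random_line_mask(100, 0.3, seed=5)
        assert np.array_equal(a.keep, b.keep)

    def test_max_consecutive_respected_over_seeds(self):
        for seed in range(300):
            lm = ps.random_line_mask(100, 0.3, max_consecutive=2, seed=seed)
            assert lm.max_run() <= 2

    def test_max_consecutive_infeasible(self):
        # 40 skips with runs <= 1 need 40 separators in 98 interior lines: ok;
        # but at p=0.6 (60 skips) runs<=1 need 119 slots > 98
        with pytest.raises(InfeasibleMaskError):
            ps.random_line_mask(100, 0.6, max_consecutive=1, seed=0)

    def test_interior_coverage_roughly_uniform(self):
        counts = np.zeros(100)
        for seed in range(400):
            lm = ps.random_line_mask(100, 0.3, seed=seed)
            counts[~lm.keep] += 1
        interior = counts[1:-1]
        # sanity (not a strict gate): every interior line gets skipped sometimes
        assert interior.min() > 0
        assert counts[0] == 0 and counts[-1] == 0


class TestPatternedMasks:
    def test_fixed_distance_most_even_placement(self):
        # brute-force oracle: the placement minimizing the variance of gaps
        # between consecutive skips (borders included as virtual skips)
        m, p = 10, 0.2
        k = ps.round_half_up(p * m)
        best, best_var = None, np.inf
        for combo in itertools.combinations(range(1, m - 1), k):
            gaps = np.diff([0, *combo, m - 1])
            v = gaps.var()
            if v < best_var - 1e-12:
                best, best_var = combo, v
        lm = ps.patterned_line_mask(m, p, "fixed_distance")
        assert tuple(lm.skipped_rows) == best

    def test_geometric_gaps_grow(self):
        lm = ps.patterned_line_mask(200, 0.1, "geometric", ratio=1.5)
        gaps = np.diff(lm.skipped_rows)
        assert (np.diff(gaps) >= 0).all()
        assert lm.n_skipped == 20

    def test_block_single_run(self):
        lm = ps.patterned_line_mask(256, 0.30, "block", block_length=77)
        assert lm.n_skipped == 77
        assert lm.max_run() == 77  # one contiguous run

    def test_block_run_length_bound(self):
        lm = ps.patterned_line_mask(256, 0.30, "block", block_length=7)
        assert lm.max_run() == 7


class TestExpandMask:
    def test_broadcast(self):
        lm = ps.LineMask(keep=np.array([True, False, True]), fraction=1 / 3,
                         pattern="random")
        raster = ps.expand_mask(lm, 2)
        assert np.array_equal(raster.values, [[1, 1], [0, 0], [1, 1]])

    def test_zero_fraction_preserved(self):
        lm = ps.random_line_mask(64, 0.25, seed=3)
        raster = ps.expand_mask(lm, 32)
        assert raster.values.mean() == lm.keep.mean()


class TestScarExtraction:
    def test_clean_scene_all_keep(self, small_scene):
        lm = ps.extract_scar_mask(small_scene)
        assert lm.keep.all()

    def test_constant_image_all_keep(self):
        h = ps.HeightMap(values=np.full((16, 16), 2.0))
        assert ps.extract_scar_mask(h).keep.all()

    def test_planted_full_row_scars_recovered(self):
        p = ps.SceneParams(image_size=(64, 64), seed=21)
        h = ps.generate_scene(p)
        scarred, truth = ps.add_scars(
            h, ps.ScarSpec(scar_rows=[10, 50], scar_offset_range=(1.0, 1.0),
                           seed=0))
        lm = ps.extract_scar_mask(scarred)
        assert set(lm.skipped_rows) == {10, 50}

    def test_detection_matches_ground_truth_over_scenes(self):
        hits = fps = total = 0
        for seed in range(10):
            h = ps.generate_scene(ps.SceneParams(seed=seed))
            scarred, truth = ps.add_scars(h, ps.ScarSpec(n_scars=5, seed=seed))
            found = set(ps.extract_scar_mask(scarred).skipped_rows)
            planted = set(truth.skipped_rows)
            hits += len(found & planted)
            fps += len(found - planted)
            total += len(planted)
        assert hits / total >= 0.95
        assert fps / 10 <= 1.0
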
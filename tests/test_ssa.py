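"""SSA detection: rank-sum contrasts, conjunction and corrections,
cluster extraction, SSA index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oddball_fmri import design, glm, simulate, ssa

import oracles


def _beta_maps_from_array(betas, grid):
    return glm.BetaMaps(betas=betas, conditions=design.CONDITIONS,
                        roi_labels=grid.voxel_labels,
                        roi_names=dict(grid.roi_names),
                        coords=grid.voxel_coords, grid_shape=grid.shape)


class TestRankSum:
    @pytest.mark.parametrize("x,y", [
        ([3, 4, 5], [1, 2]),
        ([1, 5, 2, 8], [3, 0, 4]),
        ([10, 2, 7, 1, 9], [3, 8, 4]),
        ([0.5, 1.5, 2.5, 3.5, 4.5, 5.5], [1.0, 2.0]),
    ])
    def test_matches_exhaustive_enumeration(self, x, y):
        expected = oracles.ranksum_p_enumeration(x, y)
        res = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert res.pvalue == pytest.approx(expected, abs=1e-12)

    def test_three_vs_two_example(self):
        # all mass above: only 1 of the 10 assignments is as extreme
        res = stats.mannwhitneyu([3, 4, 5], [1, 2], alternative="greater",
                                 method="exact")
        assert res.pvalue == pytest.approx(0.1)

    def test_symmetric_samples_not_significant(self):
        rng = np.random.default_rng(0)
        grid = simulate.make_roi_grid(
            {"shape": (1, 1, 1), "rois": {"A": ((0, 1), (0, 1), (0, 1))}})
        betas = np.zeros((3, 1, 6, 1))
        base = np.array([1.0, 2.0, 3.0])
        for c in range(6):
            betas[:, 0, c, 0] = base
        maps = _beta_maps_from_array(betas, grid)
        p = ssa.voxelwise_contrast_test(maps, "adaptation")
        assert p[0] >= 0.5

    def test_contrast_uses_run_averaged_betas(self):
        rng = np.random.default_rng(1)
        grid = simulate.make_roi_grid(
            {"shape": (2, 1, 1), "rois": {"A": ((0, 2), (0, 1), (0, 1))}})
        betas = rng.normal(size=(6, 3, 6, 2))
        maps = _beta_maps_from_array(betas, grid)
        p_multi = ssa.voxelwise_contrast_test(maps, "adaptation")
        averaged = betas.mean(axis=1, keepdims=True)
        p_avg = ssa.voxelwise_contrast_test(
            _beta_maps_from_array(averaged, grid), "adaptation")
        np.testing.assert_allclose(p_multi, p_avg)

    def test_too_few_participants_rejected(self):
        grid = simulate.make_roi_grid(
            {"shape": (1, 1, 1), "rois": {"A": ((0, 1), (0, 1), (0, 1))}})
        maps = _beta_maps_from_array(np.zeros((2, 1, 6, 1)), grid)
        with pytest.raises(ValueError, match="participants"):
            ssa.voxelwise_contrast_test(maps, "adaptation")

    def test_unknown_contrast_rejected(self):
        grid = simulate.make_roi_grid(
            {"shape": (1, 1, 1), "rois": {"A": ((0, 1), (0, 1), (0, 1))}})
        maps = _beta_maps_from_array(np.zeros((3, 1, 6, 1)), grid)
        with pytest.raises(ValueError, match="contrast"):
            ssa.voxelwise_contrast_test(maps, "nope")

    def test_adaptation_contrast_weights(self):
        assert ssa.CONTRAST_WEIGHTS["adaptation"] == \
            {"std0": 1.0, "std1": -0.5, "std2": -0.5}
        assert ssa.CONTRAST_WEIGHTS["deviant_detection"] == \
            {"dev4": 1.0, "std1": -0.5, "std2": -0.5}


class TestConjunction:
    def _labels(self, n, k=2):
        labels = np.repeat(np.arange(1, k + 1), n // k)
        return labels, {i: f"R{i}" for i in range(1, k + 1)}

    def test_max_rule(self):
        labels, names = self._labels(2, 1)
        res = ssa.ssa_conjunction(np.array([0.01, 0.2]),
                                  np.array([0.04, 0.1]), labels, names)
        np.testing.assert_allclose(res.p_ssa, [0.04, 0.2])

    def test_bh_step_up_example(self):
        labels, names = self._labels(4, 1)
        p = np.array([0.01, 0.02, 0.03, 0.5])
        res = ssa.ssa_conjunction(p, p, labels, names, alpha=0.05)
        assert res.significant_mask.sum() == 3
        assert not res.significant_mask[3]

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=4, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_definition(self, p_list):
        p = np.array(p_list)
        labels = np.ones(p.size, dtype=int)
        res = ssa.ssa_conjunction(p, p, labels, {1: "R1"}, alpha=0.05)
        expected = oracles.bh_reject_by_definition(p, alpha=0.05)
        assert np.array_equal(res.significant_mask, expected)

    def test_all_ones_empty_mask(self):
        labels, names = self._labels(10, 2)
        p = np.ones(10)
        res = ssa.ssa_conjunction(p, p, labels, names)
        assert not res.significant_mask.any()
        assert all(v == 1.0 for v in res.peak_p.values())

    def test_peak_bonferroni_then_holm(self):
        labels, names = self._labels(10, 2)
        p_a = np.full(10, 0.9)
        p_a[0] = 0.001      # ROI 1 peak
        p_a[5] = 0.004      # ROI 2 peak
        res = ssa.ssa_conjunction(p_a, p_a, labels, names)
        # within-ROI Bonferroni: 0.005 and 0.02; Holm over two ROIs
        expected = oracles.holm_adjust_by_definition([0.005, 0.02])
        assert res.peak_p["R1"] == pytest.approx(expected[0])
        assert res.peak_p["R2"] == pytest.approx(expected[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssa.ssa_conjunction(np.ones(3), np.ones(4), np.ones(3, dtype=int),
                                {1: "R"})


class TestClusters:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0:3, 0, 0] = True
        mask[6:9, 0, 0] = True
        labels = np.ones_like(mask, dtype=int)
        p = np.full(mask.shape, 0.5)
        clusters = ssa.extract_clusters(mask, labels, p, {1: "R"})
        assert sorted(c.size for c in clusters) == [3, 3]

    def test_diagonal_voxels_joined_under_26_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        clusters = ssa.extract_clusters(mask, np.ones_like(mask, dtype=int),
                                        np.ones(mask.shape), {1: "R"})
        assert len(clusters) == 1
        assert clusters[0].size == 2

    def test_peak_is_minimum_p_lowest_linear_index_on_ties(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, :, :] = True
        p = np.ones(mask.shape)
        p[0, 1, 1] = p[0, 2, 2] = 0.001      # tie: first in C order wins
        clusters = ssa.extract_clusters(mask, np.ones_like(mask, dtype=int),
                                        p, {1: "R"})
        assert clusters[0].peak_coord == (0, 1, 1)

    def test_random_mask_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 20, 20)) < 0.05
        labels = np.ones_like(mask, dtype=int)
        clusters = ssa.extract_clusters(mask, labels, np.ones(mask.shape),
                                        {1: "R"})
        oracle = oracles.flood_fill_clusters(mask)
        assert len(clusters) == len(oracle)
        assert sorted(c.size for c in clusters) == \
            sorted(len(c) for c in oracle)

    def test_clusters_confined_to_rois(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:, 0, 0] = True                  # crosses the ROI boundary
        labels = np.zeros_like(mask, dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        clusters = ssa.extract_clusters(mask, labels, np.ones(mask.shape),
                                        {1: "R1", 2: "R2"})
        assert sorted((c.roi, c.size) for c in clusters) == \
            [("R1", 2), ("R2", 2)]


class TestSSAIndex:
    def _maps(self, dev4, std1, std2):
        grid = simulate.make_roi_grid(
            {"shape": (1, 1, 1), "rois": {"A": ((0, 1), (0, 1), (0, 1))}})
        betas = np.zeros((2, 2, 6, 1))
        idx = {c: i for i, c in enumerate(design.CONDITIONS)}
        # two participants x two runs spanning [0, 1] after normalisation
        betas[..., idx["dev4"], 0] = dev4
        betas[..., idx["std1"], 0] = std1
        betas[..., idx["std2"], 0] = std2
        return _beta_maps_from_array(betas, grid)

    def test_equal_conditions_give_zero(self):
        m = self._maps(dev4=[[0, 1], [0, 1]], std1=[[0, 1], [0, 1]],
                       std2=[[0, 1], [0, 1]])
        assert ssa.ssai_map(m).ssai[0] == pytest.approx(0.0)

    def test_pure_deviant_gives_one(self):
        m = self._maps(dev4=[[1, 1], [1, 1]], std1=[[0, 0], [0, 0]],
                       std2=[[0, 0], [0, 0]])
        assert ssa.ssai_map(m).ssai[0] == pytest.approx(1.0)

    def test_direct_formula_example(self):
        # normalised means: dev4 = 0.25, std1 = std2 = 0.5 -> -1/3
        m = self._maps(dev4=[[0.25, 0.25], [0.25, 0.25]],
                       std1=[[0.0, 1.0], [0.0, 1.0]],
                       std2=[[1.0, 0.0], [1.0, 0.0]])
        assert ssa.ssai_map(m).ssai[0] == pytest.approx(-1.0 / 3.0)

    def test_degenerate_voxels_flagged(self):
        m = self._maps(dev4=[[0.5, 0.5], [0.5, 0.5]],
                       std1=[[0.5, 0.5], [0.5, 0.5]],
                       std2=[[0.5, 0.5], [0.5, 0.5]])
        out = ssa.ssai_map(m)
        assert not out.defined[0]
        assert np.isnan(out.ssai[0])

    def test_bounded_on_random_betas(self):
        rng = np.random.default_rng(9)
        grid = simulate.make_roi_grid(
            {"shape": (5, 5, 2), "rois": {"A": ((0, 5), (0, 5), (0, 2))}})
        betas = rng.normal(size=(4, 2, 6, grid.n_labeled))
        out = ssa.ssai_map(_beta_maps_from_array(betas, grid))
        vals = out.ssai[out.defined]
        assert np.all(vals >= -1 - 1e-12) and np.all(vals <= 1 + 1e-12)


class TestDetectionOnSimulatedCohort:
    def test_signal_voxels_recovered_null_voxels_spared(
            self, mixed_cohort_detection):
        """Voxels simulated with h1 or h2 profiles at the default gain and
        tSNR are detected with sensitivity >= 0.8; null-ROI peaks stay
        non-significant."""
        maps = mixed_cohort_detection["maps"]
        contrast = mixed_cohort_detection["detection"]["contrast"]
        config = mixed_cohort_detection["config"]
        signal = np.zeros(maps.n_voxels, dtype=bool)
        for lab, name in maps.roi_names.items():
            if config.roi_profiles[name]["model"] != "null":
                signal |= maps.roi_labels == lab
        assert signal.sum() == 200
        sensitivity = contrast.significant_mask[signal].mean()
        assert sensitivity >= 0.8
        false_rate = contrast.significant_mask[~signal].mean()
        assert false_rate < 0.10
        assert set(contrast.significant_rois) == {"Te1.0L", "Te1.0R"}
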
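"""Group inference: t maps, smoothness estimation, GRF and FDR correction,
cluster extraction."""

import numpy as np
import pytest
from scipy import ndimage, stats

from restpipe.core_io import BrainMask, StatMap
from restpipe.inference import (
    FdrSettings,
    GrfSettings,
    SmoothnessEstimate,
    estimate_smoothness,
    extract_clusters,
    fdr_correct,
    grf_cluster_correct,
    group_residual_maps,
    voxelwise_ttest,
)
from restpipe.preprocess import FWHM_TO_SIGMA
from .conftest import make_grid


def textbook_pooled_t(a, b):
    """Independent oracle: pooled two-sample t from the definition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def maps_from_stack(stack, grid):
    return [StatMap(s, grid, kind="zmap") for s in stack]


def make_mask(shape=(6, 6, 6)):
    grid = make_grid(shape=shape)
    return BrainMask(np.ones(shape, bool), grid), grid


class TestVoxelwiseTtest:
    def test_identical_groups_give_zero(self, rng):
        mask, grid = make_mask()
        stack = rng.standard_normal((3, 6, 6, 6))
        t = voxelwise_ttest(maps_from_stack(stack, grid), maps_from_stack(stack, grid), mask)
        assert np.allclose(t.values, 0.0)
        assert t.df == 4

    def test_small_sample_textbook_value(self):
        mask, grid = make_mask((1, 1, 3))
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1) * np.ones((3, 1, 1, 3))
        b = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1) * np.ones((3, 1, 1, 3))
        t = voxelwise_ttest(maps_from_stack(a, grid), maps_from_stack(b, grid), mask)
        assert t.values[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert t.values[0, 0, 0] == pytest.approx(
            textbook_pooled_t([1, 2, 3], [4, 5, 6]), abs=1e-12
        )

    def test_antisymmetry(self, rng):
        mask, grid = make_mask()
        a = rng.standard_normal((4, 6, 6, 6))
        b = rng.standard_normal((4, 6, 6, 6))
        t_ab = voxelwise_ttest(maps_from_stack(a, grid), maps_from_stack(b, grid), mask)
        t_ba = voxelwise_ttest(maps_from_stack(b, grid), maps_from_stack(a, grid), mask)
        assert np.allclose(t_ab.values, -t_ba.values)

    def test_oracle_on_random_samples(self, rng):
        mask, grid = make_mask((1, 1, 1))
        for _ in range(100):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            a = rng.standard_normal(na)
            b = rng.standard_normal(nb)
            ma = [StatMap(np.full((1, 1, 1), v), grid, kind="zmap") for v in a]
            mb = [StatMap(np.full((1, 1, 1), v), grid, kind="zmap") for v in b]
            t = voxelwise_ttest(ma, mb, mask)
            assert t.values[0, 0, 0] == pytest.approx(textbook_pooled_t(a, b), abs=1e-10)

    def test_welch_matches_scipy(self, rng):
        mask, grid = make_mask((1, 1, 1))
        a = rng.standard_normal(5)
        b = 3.0 * rng.standard_normal(8)
        ma = [StatMap(np.full((1, 1, 1), v), grid, kind="zmap") for v in a]
        mb = [StatMap(np.full((1, 1, 1), v), grid, kind="zmap") for v in b]
        t = voxelwise_ttest(ma, mb, mask, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t.values[0, 0, 0] == pytest.approx(ref.statistic, abs=1e-10)
        assert t.df == int(np.floor(ref.df))

    def test_single_subject_group_rejected(self, rng):
        mask, grid = make_mask()
        a = maps_from_stack(rng.standard_normal((1, 6, 6, 6)), grid)
        b = maps_from_stack(rng.standard_normal((3, 6, 6, 6)), grid)
        with pytest.raises(ValueError):
            voxelwise_ttest(a, b, mask)


class TestSmoothness:
    @staticmethod
    def _smooth_maps(rng, n, shape, fwhm_mm, voxel_mm, grid):
        sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
        return [
            StatMap(
                ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect"),
                grid,
                kind="zmap",
            )
            for _ in range(n)
        ]

    def test_recovers_known_fwhm(self, rng):
        shape = (40, 40, 40)
        grid = make_grid(shape=shape)
        mask = BrainMask(np.ones(shape, bool), grid)
        estimates = []
        for _ in range(10):
            maps = self._smooth_maps(rng, 4, shape, 6.0, 3.0, grid)
            est = estimate_smoothness(maps, mask)
            estimates.append(np.mean(est.fwhm_mm))
        assert np.mean(estimates) == pytest.approx(6.0, rel=0.15)

    def test_white_noise_near_voxel_size(self, rng):
        shape = (30, 30, 30)
        grid = make_grid(shape=shape)
        mask = BrainMask(np.ones(shape, bool), grid)
        maps = [
            StatMap(rng.standard_normal(shape), grid, kind="zmap") for _ in range(6)
        ]
        est = estimate_smoothness(maps, mask)
        assert np.mean(est.fwhm_mm) == pytest.approx(3.0, rel=0.20)

    def test_resels_scale_with_volume(self, rng):
        small = (20, 20, 20)
        large = (20, 20, 40)
        out = {}
        for shape in (small, large):
            grid = make_grid(shape=shape)
            mask = BrainMask(np.ones(shape, bool), grid)
            maps = self._smooth_maps(rng, 6, shape, 6.0, 3.0, grid)
            out[shape] = estimate_smoothness(maps, mask)
        ratio = out[large].resels / out[small].resels
        assert ratio == pytest.approx(2.0, rel=0.15)
        assert np.mean(out[large].fwhm_mm) == pytest.approx(
            np.mean(out[small].fwhm_mm), rel=0.1
        )


class TestGrf:
    SMOOTH = SmoothnessEstimate((6.0, 6.0, 6.0), 500.0)

    def test_subthreshold_map_gives_empty_table(self, rng):
        mask, grid = make_mask((8, 8, 8))
        t = StatMap(0.5 * rng.standard_normal((8, 8, 8)), grid, kind="tmap", df=18)
        table = grf_cluster_correct(t, mask, self.SMOOTH)
        assert len(table) == 0

    def test_massive_effect_survives_with_sign(self, rng):
        mask, grid = make_mask((12, 12, 12))
        values = 0.1 * rng.standard_normal((12, 12, 12))
        values[3:9, 3:9, 3:9] = -12.0  # 216-voxel strong negative block
        t = StatMap(values, grid, kind="tmap", df=18)
        table = grf_cluster_correct(t, mask, self.SMOOTH)
        assert len(table) == 1
        assert table[0].peak_intensity == pytest.approx(-12.0)
        assert table[0].size_voxels == 216

    def test_voxel_p_monotonicity(self, rng):
        # lowering the cluster-forming p never increases the suprathreshold set
        mask, grid = make_mask((10, 10, 10))
        values = 3.0 * rng.standard_normal((10, 10, 10))
        t = StatMap(values, grid, kind="tmap", df=18)
        counts = []
        for voxel_p in (0.01, 0.001, 0.0001):
            t_crit = stats.t.isf(voxel_p / 2, 18)
            counts.append(int((np.abs(values) > t_crit).sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_missing_df_rejected(self, rng):
        mask, grid = make_mask()
        t = StatMap(rng.standard_normal((6, 6, 6)), grid, kind="tmap")
        with pytest.raises(ValueError):
            grf_cluster_correct(t, mask, self.SMOOTH)


def brute_force_bh(p_values, q):
    """Independent oracle: BH step-up rule from the definition."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestFdr:
    def _tmap_from_p(self, p_values, grid, df=18):
        # spaced voxels so each survivor is its own cluster
        values = np.zeros(grid.shape)
        for i, p in enumerate(p_values):
            values[2 * i, 0, 0] = stats.t.isf(p / 2, df)
        return StatMap(values, grid, kind="tmap", df=df)

    def test_all_null_empty(self):
        mask, grid = make_mask((6, 6, 6))
        t = StatMap(np.zeros((6, 6, 6)), grid, kind="tmap", df=18)
        table = fdr_correct(t, mask, FdrSettings(q=0.05, min_extent_voxels=0))
        assert len(table) == 0

    def test_step_up_example_matches_oracle(self):
        p_values = [0.001, 0.002, 0.003, 0.2, 0.9]
        shape = (10, 1, 1)
        grid = make_grid(shape=shape)
        mask_arr = np.zeros(shape, bool)
        mask_arr[[0, 2, 4, 6, 8], 0, 0] = True
        mask = BrainMask(mask_arr, grid)
        t = self._tmap_from_p(p_values, grid)
        table = fdr_correct(t, mask, FdrSettings(q=0.05, min_extent_voxels=0))
        expected = brute_force_bh(p_values, 0.05)
        assert expected.tolist() == [True, True, True, False, False]
        surviving = sorted(c.peak_ijk[0] for c in table)
        assert surviving == [0, 2, 4]

    def test_matches_oracle_on_random_pvectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(3, 200)))
            reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_extent_threshold_drops_49_voxel_blob(self):
        shape = (12, 12, 12)
        grid = make_grid(shape=shape)
        mask = BrainMask(np.ones(shape, bool), grid)
        values = np.zeros(shape)
        blob = np.zeros(shape, bool)
        blob[2:9, 2:9, 5] = True  # 49 voxels
        values[blob] = 30.0
        t = StatMap(values, grid, kind="tmap", df=18)
        dropped = fdr_correct(t, mask, FdrSettings(q=0.05, min_extent_voxels=50))
        kept = fdr_correct(t, mask, FdrSettings(q=0.05, min_extent_voxels=49))
        assert len(dropped) == 0
        assert len(kept) == 1 and kept[0].size_voxels == 49


class TestExtractClusters:
    def test_solid_block_single_cluster(self):
        shape = (8, 8, 8)
        grid = make_grid(shape=shape)
        binary = np.zeros(shape, bool)
        binary[2:5, 2:5, 2:5] = True
        source = StatMap(np.ones(shape), grid, kind="tmap", df=10)
        table = extract_clusters(binary, source)
        assert len(table) == 1
        assert table[0].size_voxels == 27

    def test_corner_touch_connectivity(self):
        shape = (6, 6, 6)
        grid = make_grid(shape=shape)
        binary = np.zeros(shape, bool)
        binary[2, 2, 2] = True
        binary[3, 3, 3] = True  # touch only at a corner
        source = StatMap(np.ones(shape), grid, kind="tmap", df=10)
        assert len(extract_clusters(binary, source, connectivity=26)) == 1
        assert len(extract_clusters(binary, source, connectivity=6)) == 2

    def test_peak_is_max_absolute_value(self):
        shape = (6, 1, 1)
        grid = make_grid(shape=shape)
        binary = np.zeros(shape, bool)
        binary[0:3, 0, 0] = True
        values = np.zeros(shape)
        values[0:3, 0, 0] = [2.0, -5.0, 3.0]
        source = StatMap(values, grid, kind="tmap", df=10)
        table = extract_clusters(binary, source)
        assert table[0].peak_intensity == -5.0
        assert table[0].peak_ijk == (1, 0, 0)
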
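"""Degree centrality (blocked vs brute force), z-scoring, ROI series, seed FC."""

import numpy as np
import pytest

from voxelhub.io import BoldImage, MaskImage
from voxelhub.connectome import (
    DEFAULT_THRESHOLDS,
    RoiSpec,
    compute_dc,
    compute_fc,
    dc_multi_threshold,
    extract_roi_timeseries,
    fisher_z,
    zscore_map,
)

from conftest import make_affine


def bold_from_series(series, affine=None, tr=2.0, shape=None):
    """Pack an (N, t) series matrix into the first N voxels of a grid."""
    series = np.asarray(series, dtype=float)
    n, t = series.shape
    if shape is None:
        side = int(np.ceil(n ** (1 / 3)))
        shape = (side, side, max(side, 2))
    data = np.zeros((*shape, t))
    mask = np.zeros(shape, dtype=bool)
    idx = np.unravel_index(np.arange(n), shape)
    data[idx] = series
    mask[idx] = True
    affine = make_affine(3.0) if affine is None else affine
    return BoldImage(data, affine, tr), MaskImage(mask, affine)


def naive_dc(series, r0, weighted=True):
    """Double-loop all-pairs oracle for weighted degree centrality."""
    n = series.shape[0]
    dc = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r0:
                w = r if weighted else 1.0
                dc[i] += w
                dc[j] += w
    return dc


class TestDegreeCentrality:
    def test_identical_series_give_n_minus_one(self, rng):
        s = rng.standard_normal(40)
        series = np.tile(s, (5, 1))
        b, m = bold_from_series(series)
        for r0 in (0.0, 0.25, 0.9):
            dm = compute_dc(b, m, r0)
            np.testing.assert_allclose(dm.dc[m.data], 4.0, atol=1e-10)

    def test_orthogonal_series_give_zero(self):
        # distinct Fourier harmonics are exactly sample-orthogonal
        t = np.arange(64)
        series = np.array([np.sin(2 * np.pi * k * t / 64) for k in (3, 5, 7, 11)])
        b, m = bold_from_series(series)
        dm = compute_dc(b, m, 0.15)
        np.testing.assert_allclose(dm.dc[m.data], 0.0, atol=1e-10)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_blocked_equals_brute_force(self, rng, weighted):
        series = rng.standard_normal((200, 60))
        b, m = bold_from_series(series)
        # rows land at C-order flat indices 0..n-1, so in-mask order == row order
        for r0 in DEFAULT_THRESHOLDS:
            dm = compute_dc(b, m, r0, weighted=weighted, block_size=37)
            expected = naive_dc(series, r0, weighted)
            np.testing.assert_allclose(dm.dc[m.data], expected, atol=1e-10)

    def test_block_size_does_not_matter(self, rng):
        series = rng.standard_normal((101, 40))
        b, m = bold_from_series(series)
        a = compute_dc(b, m, 0.25, block_size=7).dc
        c = compute_dc(b, m, 0.25, block_size=1000).dc
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        series = rng.standard_normal((80, 50))
        b, m = bold_from_series(series)
        maps = dc_multi_threshold(b, m, DEFAULT_THRESHOLDS)
        for lo, hi in zip(maps, maps[1:]):
            assert (hi.dc <= lo.dc + 1e-12).all()

    def test_r0_zero_sums_all_positive_correlations(self, rng):
        series = rng.standard_normal((30, 40))
        b, m = bold_from_series(series)
        dm = compute_dc(b, m, 0.0)
        R = np.corrcoef(series)
        np.fill_diagonal(R, 0.0)
        expected = np.where(R > 0, R, 0.0).sum(axis=1)
        np.testing.assert_allclose(dm.dc[m.data], expected, atol=1e-10)

    def test_multi_threshold_equals_independent_calls(self, rng):
        series = rng.standard_normal((50, 40))
        b, m = bold_from_series(series)
        multi = dc_multi_threshold(b, m, DEFAULT_THRESHOLDS)
        for dm in multi:
            single = compute_dc(b, m, dm.r0)
            np.testing.assert_allclose(dm.dc, single.dc, atol=1e-12)

    def test_invariant_to_linear_rescaling(self, rng):
        series = rng.standard_normal((40, 30))
        scale = rng.uniform(0.5, 5.0, size=(40, 1))
        shift = rng.normal(size=(40, 1)) * 10
        b1, m = bold_from_series(series)
        b2, _ = bold_from_series(series * scale + shift)
        np.testing.assert_allclose(
            compute_dc(b1, m, 0.25).dc, compute_dc(b2, m, 0.25).dc, atol=1e-9
        )

    def test_weighted_bounds_binarized(self, rng):
        series = rng.standard_normal((60, 45))
        b, m = bold_from_series(series)
        r0 = 0.2
        w = compute_dc(b, m, r0, weighted=True).dc
        k = compute_dc(b, m, r0, weighted=False).dc
        assert (w >= r0 * k - 1e-12).all()
        assert (w <= k).all()  # each surviving r is < 1

    def test_threshold_and_frame_guards(self, rng):
        series = rng.standard_normal((10, 30))
        b, m = bold_from_series(series)
        with pytest.raises(ValueError):
            compute_dc(b, m, 1.0)
        b2, m2 = bold_from_series(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            compute_dc(b2, m2, 0.25)

    def test_zero_variance_voxels_are_dropped(self, rng):
        series = rng.standard_normal((20, 30))
        series[4] = 3.14  # constant voxel
        b, m = bold_from_series(series)
        dm = compute_dc(b, m, 0.25)
        assert dm.mask.n_voxels == 19


class TestZscoreMap:
    def test_mean_zero_sd_one(self, rng, box_mask):
        m = rng.standard_normal((12, 12, 12)) * 4 + 2
        z = zscore_map(m, box_mask)
        vals = z[box_mask.data]
        assert abs(vals.mean()) < 1e-9
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert not z[~box_mask.data].any()

    def test_affine_invariance(self, rng, box_mask):
        m = rng.standard_normal((12, 12, 12))
        np.testing.assert_allclose(
            zscore_map(2.5 * m + 7, box_mask), zscore_map(m, box_mask), atol=1e-9
        )

    def test_hand_computed_three_voxels(self, affine3mm):
        mask = np.zeros((3, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        m = np.zeros((3, 1, 1))
        m[:, 0, 0] = [1.0, 2.0, 3.0]
        z = zscore_map(m, MaskImage(mask, affine3mm))
        # sample SD (ddof=1) of {1,2,3} is exactly 1
        np.testing.assert_allclose(z[:, 0, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_map_is_error(self, box_mask):
        with pytest.raises(ValueError, match="standard deviation"):
            zscore_map(np.ones((12, 12, 12)), box_mask)


class TestRoiTimeseries:
    def test_single_voxel_cluster(self, rng, affine3mm):
        b = BoldImage(rng.standard_normal((8, 8, 8, 20)), affine3mm, 2.0)
        mask = MaskImage(np.ones((8, 8, 8), dtype=bool), affine3mm)
        sel = np.zeros((8, 8, 8), dtype=bool)
        sel[2, 3, 4] = True
        roi = RoiSpec(kind="cluster_mask", mask=MaskImage(sel, affine3mm))
        np.testing.assert_array_equal(
            extract_roi_timeseries(b, roi, mask), b.data[2, 3, 4]
        )

    def test_tiny_sphere_is_one_voxel(self, rng, affine3mm):
        b = BoldImage(rng.standard_normal((8, 8, 8, 20)), affine3mm, 2.0)
        mask = MaskImage(np.ones((8, 8, 8), dtype=bool), affine3mm)
        center = (3 * 4.0, 3 * 4.0, 3 * 4.0)  # world mm of voxel (4,4,4)... not exact
        roi = RoiSpec(kind="sphere", center_mm=(12.0, 12.0, 12.0), radius_mm=1.0)
        np.testing.assert_array_equal(
            extract_roi_timeseries(b, roi, mask), b.data[4, 4, 4]
        )

    def test_matches_brute_force_mean(self, rng, affine3mm):
        b = BoldImage(rng.standard_normal((8, 8, 8, 20)), affine3mm, 2.0)
        mask = MaskImage(np.ones((8, 8, 8), dtype=bool), affine3mm)
        roi = RoiSpec(kind="sphere", center_mm=(12.0, 12.0, 12.0), radius_mm=7.0)
        sel = roi.to_mask(mask)
        assert sel.sum() > 5
        np.testing.assert_allclose(
            extract_roi_timeseries(b, roi, mask),
            b.data[sel].mean(axis=0),
            atol=1e-12,
        )

    def test_empty_intersection_is_error(self, rng, affine3mm, box_mask):
        b = BoldImage(rng.standard_normal((12, 12, 12, 10)), affine3mm, 2.0)
        roi = RoiSpec(kind="sphere", center_mm=(0.0, 0.0, 0.0), radius_mm=1.0)
        with pytest.raises(ValueError, match="intersect"):
            extract_roi_timeseries(b, roi, box_mask)


class TestSeedFc:
    def test_identical_and_anti_identical_voxels(self, rng):
        seed = rng.standard_normal(50)
        series = np.vstack([seed, -seed, rng.standard_normal(50)])
        b, m = bold_from_series(series)
        fc = compute_fc(b, seed, m)
        r = fc.r[m.data][:2]
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[1] == pytest.approx(-1.0, abs=1e-12)
        assert np.isfinite(fc.z).all()

    def test_signal_plus_noise_matches_analytic_r(self, rng):
        t = 10_000
        s = rng.standard_normal(t)
        sigma = 1.5
        voxel = s + sigma * rng.standard_normal(t)
        b, m = bold_from_series(np.vstack([voxel, rng.standard_normal(t)]))
        fc = compute_fc(b, s, m)
        expected = 1.0 / np.sqrt(1.0 + sigma**2)
        observed = fc.r[m.data].max()
        assert observed == pytest.approx(expected, abs=0.02)

    def test_fisher_z_is_odd_and_finite(self, rng):
        r = rng.uniform(-1, 1, size=100)
        np.testing.assert_allclose(fisher_z(-r), -np.asarray(fisher_z(r)), atol=1e-12)
        assert np.isfinite(fisher_z(np.array([-1.0, 1.0]))).all()

    def test_constant_seed_is_error(self, rng):
        b, m = bold_from_series(rng.standard_normal((4, 30)))
        with pytest.raises(ValueError, match="constant seed"):
            compute_fc(b, np.ones(30), m)


class TestHubRecoveryMini:
    def test_in_hub_dc_exceeds_background_at_all_thresholds(self, rng):
        # 60 hub voxels share a latent (loading 0.7), 140 are pure noise
        t = 230
        latent = rng.standard_normal(t)
        n_hub, n_bg = 60, 140
        series = rng.standard_normal((n_hub + n_bg, t))
        series[:n_hub] = 0.7 * latent + 0.6 * rng.standard_normal((n_hub, t))
        b, m = bold_from_series(series)
        for dm in dc_multi_threshold(b, m, DEFAULT_THRESHOLDS):
            vals = dm.dc[m.data]
            assert vals[:n_hub].mean() > vals[n_hub:].mean()
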
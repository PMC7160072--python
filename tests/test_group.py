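"""GLM t-maps, residual smoothness, GRF cluster inference, demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelhub.io import CohortTable, MaskImage
from voxelhub.group import (
    GroupDesign,
    _grf_cluster_p,
    compare_demographics,
    estimate_smoothness,
    extract_cluster_mask,
    gaussianize_t,
    grf_cluster_inference,
    make_group_design,
    one_sample_tmap,
    two_sample_glm,
)
from voxelhub.synth import generate_null_zmaps

from conftest import make_affine


@pytest.fixture
def mask20(affine3mm):
    data = np.zeros((20, 20, 20), dtype=bool)
    data[2:18, 2:18, 2:18] = True
    return MaskImage(data, affine3mm)


def random_maps(rng, n, mask, fwhm_mm=0.0):
    if fwhm_mm:
        return generate_null_zmaps(n, mask, fwhm_mm, rng)
    out = rng.standard_normal((n, *mask.data.shape))
    out[:, ~mask.data] = 0.0
    return out


class TestOneSample:
    def test_constant_positive_maps_give_huge_t(self, rng, box_mask):
        maps = [
            np.where(box_mask.data, 3.0 + 1e-3 * rng.standard_normal(box_mask.data.shape), 0.0)
            for _ in range(10)
        ]
        res = one_sample_tmap(maps, box_mask)
        assert res.df == 9
        assert res.t_map[box_mask.data].min() > 100

    def test_null_calibration_near_nominal(self, rng, mask20):
        n = 20
        maps = random_maps(rng, n, mask20)
        res = one_sample_tmap(list(maps), mask20)
        crit = stats.t.isf(0.005, df=n - 1)
        frac = (np.abs(res.t_map[mask20.data]) > crit).mean()
        # ~1% of null voxels two-tailed; wide binomial band for one draw
        assert 0.004 < frac < 0.02

    def test_two_maps_is_an_error(self, rng, box_mask):
        with pytest.raises(ValueError):
            one_sample_tmap(list(random_maps(rng, 2, box_mask)), box_mask)


class TestTwoSampleGlm:
    def test_equals_pooled_two_sample_t_without_covariates(self, rng, box_mask):
        n1, n2 = 9, 11
        maps = random_maps(rng, n1 + n2, box_mask)
        X = np.column_stack([np.ones(n1 + n2), np.r_[np.ones(n1), np.zeros(n2)]])
        design = GroupDesign(X, ["intercept", "group"], np.array([0.0, 1.0]))
        res = two_sample_glm(list(maps), design, box_mask)
        vals = maps[:, box_mask.data]
        t_ref = stats.ttest_ind(vals[:n1], vals[n1:], axis=0, equal_var=True).statistic
        np.testing.assert_allclose(res.t_map[box_mask.data], t_ref, atol=1e-8)
        assert res.df == n1 + n2 - 2

    def test_collinear_covariate_is_rejected(self, small_cohort):
        df = small_cohort.df.copy()
        df["group_copy"] = (df["group"] == "patient").astype(float)
        cohort = CohortTable(df)
        with pytest.raises(np.linalg.LinAlgError):
            make_group_design(cohort, covariates=("age", "group_copy"))

    def test_covariate_adjustment_removes_a_confound(self, rng, box_mask, small_cohort):
        # inject an age effect only; adjusted group t should be null-ish
        age = small_cohort.df["age"].to_numpy()
        maps = random_maps(rng, len(age), box_mask)
        maps[:, box_mask.data] += 0.5 * (age[:, None] - age.mean())
        design = make_group_design(small_cohort, covariates=("age",))
        res = two_sample_glm(list(maps), design, box_mask)
        frac = (np.abs(res.t_map[box_mask.data]) > stats.t.isf(0.005, res.df)).mean()
        assert frac < 0.05


class TestSmoothness:
    def test_recovers_known_6mm_fwhm(self, rng, mask20):
        maps = generate_null_zmaps(12, mask20, 6.0, rng)
        res = one_sample_tmap(list(maps), mask20)
        sm = estimate_smoothness(res.residuals, mask20)
        assert np.all(np.abs(sm.fwhm_mm - 6.0) / 6.0 < 0.15)

    def test_unsmoothed_noise_floors_at_one_voxel(self, rng, mask20):
        maps = random_maps(rng, 12, mask20)
        res = one_sample_tmap(list(maps), mask20)
        sm = estimate_smoothness(res.residuals, mask20)
        assert np.all(sm.fwhm_vox <= 1.3)
        assert np.all(sm.fwhm_vox >= 1.0)
        assert sm.resels <= mask20.n_voxels

    def test_fwhm_mm_scales_with_voxel_size(self, rng, mask20):
        maps = generate_null_zmaps(10, mask20, 6.0, rng)
        res = one_sample_tmap(list(maps), mask20)
        sm3 = estimate_smoothness(res.residuals, mask20, voxel_sizes_mm=(3, 3, 3))
        sm6 = estimate_smoothness(res.residuals, mask20, voxel_sizes_mm=(6, 6, 6))
        np.testing.assert_allclose(sm6.fwhm_mm, 2 * sm3.fwhm_mm)


class TestGrf:
    def test_gaussianized_threshold_matches_tail_probability(self):
        # the Gaussian cluster-forming threshold u solves Phi(-u) = voxel_p / 2
        for voxel_p in (0.01, 0.001):
            u = stats.norm.isf(voxel_p / 2)
            assert stats.norm.sf(u) == pytest.approx(voxel_p / 2, rel=1e-10)
        # and gaussianize_t maps the t threshold onto u
        t_crit = stats.t.isf(0.005, df=30)
        z = gaussianize_t(np.array([[[t_crit]]]), 30)[0, 0, 0]
        assert z == pytest.approx(stats.norm.isf(0.005), abs=1e-10)
        zneg = gaussianize_t(np.array([[[-t_crit]]]), 30)[0, 0, 0]
        assert zneg == pytest.approx(-z, abs=1e-12)

    def test_cluster_p_monotone_in_extent_and_resels(self):
        u = 2.5758
        ps = [_grf_cluster_p(s, u, 500.0) for s in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        # more resels (rougher field, same extent) -> larger p
        pr = [_grf_cluster_p(2.0, u, R) for R in (100.0, 300.0, 1000.0)]
        assert all(b > a for a, b in zip(pr, pr[1:]))

    def test_injected_effect_recovered_as_single_cluster(self, rng, mask20):
        n1, n2 = 10, 10
        maps = generate_null_zmaps(n1 + n2, mask20, 6.0, rng)
        blob = np.zeros(mask20.data.shape)
        blob[8:13, 8:13, 8:13] = 3.0
        maps[:n1] += blob * mask20.data
        X = np.column_stack([np.ones(n1 + n2), np.r_[np.ones(n1), np.zeros(n2)]])
        design = GroupDesign(X, ["intercept", "group"], np.array([0.0, 1.0]))
        res = two_sample_glm(list(maps), design, mask20)
        table, labels = grf_cluster_inference(res)
        pos = table[table["sign"] > 0]
        assert len(pos) == 1
        assert labels[10, 10, 10] == pos["label"].iloc[0]
        assert pos["peak_t"].iloc[0] > 0

    def test_no_suprathreshold_voxels_gives_empty_table(self, rng, mask20):
        maps = generate_null_zmaps(8, mask20, 6.0, rng) * 1e-3
        maps += np.where(mask20.data, rng.standard_normal(mask20.data.shape) * 1e-3, 0)
        res = one_sample_tmap(list(maps), mask20)
        res.t_map *= 1e-6  # force nothing above threshold
        table, labels = grf_cluster_inference(res)
        assert table.empty and not labels.any()

    def test_cluster_p_one_reports_every_component(self, rng, mask20):
        maps = generate_null_zmaps(12, mask20, 6.0, rng)
        res = one_sample_tmap(list(maps), mask20)
        table, labels = grf_cluster_inference(res, cluster_p=1.0 + 1e-9)
        z = gaussianize_t(res.t_map, res.df)
        z[~mask20.data] = 0
        u = stats.norm.isf(0.005)
        from scipy import ndimage

        total = 0
        for exc in (z > u, -z > u):
            _, n = ndimage.label(exc, structure=np.ones((3, 3, 3), bool))
            total += n
        assert len(table) == total
        assert int(table["n_voxels"].sum()) == int((np.abs(z) > u)[mask20.data].sum())

    def test_cluster_mask_round_trip(self, rng, mask20):
        maps = generate_null_zmaps(12, mask20, 6.0, rng)
        res = one_sample_tmap(list(maps), mask20)
        table, labels = grf_cluster_inference(res, cluster_p=1.0 + 1e-9)
        assert not table.empty
        sizes = {
            int(row["label"]): extract_cluster_mask(labels, int(row["label"]), mask20.affine).n_voxels
            for _, row in table.iterrows()
        }
        assert sizes == dict(zip(table["label"].astype(int), table["n_voxels"].astype(int)))
        with pytest.raises(KeyError):
            extract_cluster_mask(labels, 9999, mask20.affine)


class TestDemographics:
    def _cohort(self, pat, con, var="score"):
        rows = []
        for i, v in enumerate(pat):
            rows.append({"subject_id": f"p{i}", "group": "patient", "age": 60.0 + i,
                         "sex": "M" if i % 4 else "F", "education": 6.0, var: v})
        for i, v in enumerate(con):
            rows.append({"subject_id": f"c{i}", "group": "control", "age": 60.0 + i,
                         "sex": "M" if i % 4 else "F", "education": 6.0, var: v})
        return CohortTable(pd.DataFrame(rows))

    def test_identical_groups_are_nonsignificant(self, rng):
        vals = rng.normal(size=15)
        table = compare_demographics(self._cohort(vals, vals), variables=["score"])
        assert table.loc[table["variable"] == "score", "p"].iloc[0] > 0.9

    def test_strong_separation_is_detected(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)
            tab = compare_demographics(self._cohort(a, b), variables=["score"])
            hits += tab.loc[tab["variable"] == "score", "p"].iloc[0] < 0.001
        assert hits >= 99

    def test_sex_ratio_14_5_vs_15_5_not_significant(self):
        rows = []
        for grp, males, females in (("patient", 14, 5), ("control", 15, 5)):
            for i in range(males + females):
                rows.append({"subject_id": f"{grp}{i}", "group": grp, "age": 60.0,
                             "sex": "M" if i < males else "F", "education": 6.0})
        table = compare_demographics(CohortTable(pd.DataFrame(rows)), variables=[])
        p = table.loc[table["variable"] == "sex", "p"].iloc[0]
        assert p > 0.5

    def test_nonnormal_variable_uses_mannwhitney(self, rng):
        a = rng.exponential(1.0, size=40) ** 3
        b = rng.exponential(1.5, size=40) ** 3
        tab = compare_demographics(self._cohort(a, b), variables=["score"])
        assert tab.loc[tab["variable"] == "score", "test"].iloc[0] == "mannwhitney"
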
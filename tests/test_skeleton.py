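"""Skeletonization, projection, TFCE and permutation inference."""

import numpy as np
import pytest

from fwelim.io import ParameterError
from fwelim.tensor import ScalarMap
from fwelim.skeleton import (SkeletonModel, TfceConfig, difference_values,
                             mask_corrected_by_uncorrected,
                             permutation_group_test, project_subject,
                             skeletonize, tfce)


def gaussian_ridge(shape=(15, 20, 5), crest_x=7, width=2.0, height=0.8):
    x = np.arange(shape[0])[:, None, None]
    return height * np.exp(-0.5 * ((x - crest_x) / width) ** 2) * np.ones(shape)


class TestSkeletonize:
    def test_gaussian_ridge_crest_is_recovered(self):
        fa = gaussian_ridge()
        model = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        assert set(model.skeleton_idx[:, 0]) == {7}
        assert model.n_voxels > 50

    def test_skeletonization_is_deterministic(self):
        fa = gaussian_ridge()
        a = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        b = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        np.testing.assert_array_equal(a.skeleton_idx, b.skeleton_idx)

    def test_flat_plateau_gives_single_width_crest(self):
        fa = np.zeros((10, 12, 1))
        fa[4:6, 2:10, 0] = 0.5        # 2-voxel-thick flat slab along y
        model = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        interior = model.skeleton_idx[(model.skeleton_idx[:, 1] >= 3)
                                      & (model.skeleton_idx[:, 1] <= 8)]
        # the index tie-break keeps exactly the lower-x voxel of each pair
        assert set(interior[:, 0]) == {4}
        cols = {tuple(v[1:]) for v in interior}
        assert len(cols) == len(interior)

    def test_threshold_above_max_errors(self):
        fa = gaussian_ridge()
        with pytest.raises(ParameterError):
            skeletonize(ScalarMap(values=fa, metric="FA"), 1.0)


class TestProjection:
    def test_subject_identical_to_mean_projects_identity(self):
        fa = gaussian_ridge()
        model = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        proj, src, _ = project_subject(ScalarMap(values=fa, metric="FA"), model)
        np.testing.assert_array_equal(src, model.skeleton_idx)
        np.testing.assert_allclose(proj, fa[tuple(model.skeleton_idx.T)])

    def test_laterally_shifted_bundle_projects_its_core(self):
        fa = gaussian_ridge()
        model = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        shifted = np.roll(fa, 1, axis=0)   # subject bundle 1 voxel off
        proj, src, _ = project_subject(ScalarMap(values=shifted, metric="FA"),
                                       model)
        # away from the volume's z boundary (where the zero-padding cliff
        # legitimately dominates the search direction) the source indices
        # moved to the shifted crest and recovered the peak FA
        interior = ((model.skeleton_idx[:, 2] >= 1) & (model.skeleton_idx[:, 2] <= 3)
                    & (model.skeleton_idx[:, 1] >= 1) & (model.skeleton_idx[:, 1] <= 18))
        assert (src[interior, 0] == 8).all()
        np.testing.assert_allclose(proj[interior], 0.8, rtol=1e-12)

    def test_other_maps_reuse_the_fa_projection_indices(self):
        fa = gaussian_ridge()
        model = skeletonize(ScalarMap(values=fa, metric="FA"), 0.2)
        shifted = np.roll(fa, 1, axis=0)
        rng = np.random.default_rng(0)
        md = rng.random(fa.shape)
        proj_fa, src, (proj_md,) = project_subject(
            ScalarMap(values=shifted, metric="FA"), model,
            [ScalarMap(values=md, metric="MD")])
        np.testing.assert_array_equal(proj_md, md[tuple(src.T)])


class TestMaskingAndDifferences:
    def test_corrected_masked_where_uncorrected_is_zero(self):
        u = ScalarMap(values=np.array([[[0.0, 0.5]]]), metric="FA")
        c = ScalarMap(values=np.array([[[0.3, 0.4]]]), metric="FA",
                      correction="fwe_corrected")
        out = mask_corrected_by_uncorrected(c, u)
        assert not out.mask[0, 0, 0]
        assert out.mask[0, 0, 1]

    def test_everywhere_positive_uncorrected_leaves_corrected_unchanged(self):
        u = ScalarMap(values=np.full((2, 2, 1), 0.5), metric="FA")
        c = ScalarMap(values=np.full((2, 2, 1), 0.6), metric="FA")
        out = mask_corrected_by_uncorrected(c, u)
        assert out.mask.all()

    def test_disjoint_masks_warn(self):
        u = ScalarMap(values=np.zeros((2, 2, 1)), metric="FA")
        c = ScalarMap(values=np.ones((2, 2, 1)), metric="FA")
        with pytest.warns(UserWarning):
            out = mask_corrected_by_uncorrected(c, u)
        assert not out.mask.any()

    def test_difference_is_uncorrected_minus_corrected_with_nan_propagation(self):
        u = np.array([1.0, 2.0, np.nan])
        c = np.array([0.5, 2.0, 1.0])
        d = difference_values(u, c)
        np.testing.assert_allclose(d[:2], [0.5, 0.0])
        assert np.isnan(d[2])


class TestTfce:
    def test_all_zero_map_stays_zero(self):
        idx = np.array([[0, i, 0] for i in range(5)])
        out = tfce(np.zeros(5), idx, (1, 5, 1))
        assert (out == 0).all()

    def test_single_voxel_matches_closed_form_integral(self):
        """TFCE of one isolated voxel of height h0 tends to h0^(H+1)/(H+1)."""
        h0 = 2.0
        idx = np.array([[1, 1, 1]])
        out = tfce(np.array([h0]), idx, (3, 3, 3), TfceConfig(n_steps=1000))
        assert out[0] == pytest.approx(h0 ** 3 / 3, rel=0.01)

    def test_uniform_cluster_matches_closed_form(self):
        """k-voxel uniform cluster: TFCE -> k^E h0^(H+1)/(H+1)."""
        k, h0 = 5, 1.5
        idx = np.array([[0, i, 0] for i in range(k)])
        out = tfce(np.full(k, h0), idx, (1, k, 1), TfceConfig(n_steps=1000))
        assert out[0] == pytest.approx(k * h0 ** 3 / 3, rel=0.01)

    def test_tfce_is_monotone_under_scaling(self):
        rng = np.random.default_rng(1)
        idx = np.argwhere(np.ones((4, 4, 2), bool))
        vals = rng.random(len(idx)) * 3
        base = tfce(vals, idx, (4, 4, 2))
        scaled = tfce(1.7 * vals, idx, (4, 4, 2))
        assert (scaled >= base - 1e-12).all()


class TestPermutationInference:
    def _setup(self, n_vox=40):
        idx = np.array([[0, i, 0] for i in range(n_vox)])
        return idx, (1, n_vox, 1)

    def test_identical_groups_are_never_significant(self):
        idx, shape = self._setup()
        rng = np.random.default_rng(2)
        base = rng.standard_normal(len(idx))
        vals = np.tile(base, (12, 1)) + 0.01 * rng.standard_normal((12, len(idx)))
        res = permutation_group_test(vals, np.array(["a"] * 6 + ["b"] * 6),
                                     idx, shape, TfceConfig(n_perm=500), seed=3)
        assert np.nanmin(res.p_corrected_map) > 0.2

    def test_strong_cluster_effect_is_detected(self):
        idx, shape = self._setup()
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((16, len(idx)))
        vals[:8, 10:20] += 2.0      # d = 2 in a 10-voxel cluster
        res = permutation_group_test(vals, np.array(["a"] * 8 + ["b"] * 8),
                                     idx, shape, TfceConfig(n_perm=500), seed=5)
        assert np.nanmin(res.p_corrected_map[10:20]) < 0.05
        assert res.d_map[10:20].mean() > 1.0

    def test_p_values_invariant_to_subject_ordering(self):
        idx, shape = self._setup(20)
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((10, 20))
        vals[:5] += 1.0
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res1 = permutation_group_test(vals, groups, idx, shape,
                                      TfceConfig(n_perm=300), seed=7)
        order = rng.permutation(10)
        res2 = permutation_group_test(vals[order], groups[order], idx, shape,
                                      TfceConfig(n_perm=300), seed=7)
        np.testing.assert_allclose(res1.p_corrected_map, res2.p_corrected_map)

    def test_small_designs_enumerate_exactly(self):
        idx, shape = self._setup(10)
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((7, 10))
        res = permutation_group_test(vals, np.array(["a"] * 4 + ["b"] * 3),
                                     idx, shape, TfceConfig(n_perm=500), seed=9)
        # C(7, 4) = 35 distinct assignments -> exact p on a grid of 1/35
        p = res.p_corrected_map[np.isfinite(res.p_corrected_map)]
        np.testing.assert_allclose(p * 35, np.round(p * 35), atol=1e-9)


@pytest.fixture(scope="module")
def tbss(scheme30):
    """Severe-atrophy cohort, fitted, with its mean-FA skeleton."""
    from fwelim.phantom import (default_cohort_spec, default_phantom_spec,
                                simulate_cohort)
    from fwelim.pipeline import fit_cohort
    subjects = simulate_cohort(
        default_phantom_spec(),
        default_cohort_spec(seed=4077, atrophy_effect={"fornix": 2.0}),
        scheme30)
    fits = fit_cohort(subjects)
    groups = np.array([s.group for s in subjects])
    mean_fa = np.mean([np.where(f.uncorrected["FA"].mask,
                                f.uncorrected["FA"].values, 0)
                       for f in fits], axis=0)
    model = skeletonize(ScalarMap(values=mean_fa, metric="FA"), 0.2)
    return fits, groups, model


class TestCohortSkeletonAnalysis:
    """Severe-atrophy cohort: contamination reaches the bundle crest, so the
    uncorrected skeleton statistics light up while correction collapses the
    effect sizes (the boxed fornix effect of skeleton-based comparisons)."""

    def _run(self, tbss, metric, corrected, direction):
        fits, groups, model = tbss
        rows = []
        for f in fits:
            maps = f.corrected if corrected else f.uncorrected
            _, _, (proj,) = project_subject(f.uncorrected["FA"], model,
                                            [maps[metric]])
            rows.append(proj)
        return permutation_group_test(np.asarray(rows), groups,
                                      model.skeleton_idx, model.shape,
                                      TfceConfig(n_perm=500), seed=5,
                                      direction=direction)

    @pytest.mark.parametrize("metric,direction", [
        ("MD", "b>a"), ("RD", "b>a"), ("FA", "a>b")])
    def test_uncorrected_bundle_significant_and_correction_collapses_d(
            self, tbss, metric, direction):
        fits, groups, model = tbss
        bundle = np.array([i for i, v in enumerate(model.skeleton_idx)
                           if 5 <= v[0] <= 8])
        assert len(bundle) > 0
        res_u = self._run(tbss, metric, corrected=False, direction=direction)
        res_c = self._run(tbss, metric, corrected=True, direction=direction)
        sig_u = np.nan_to_num(res_u.p_corrected_map, nan=1.0) < 0.05
        assert sig_u[bundle].any()
        d_u = np.nanmax(np.abs(res_u.d_map[bundle]))
        d_c = np.nanmax(np.abs(res_c.d_map[bundle]))
        assert d_c < 0.6 * d_u
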
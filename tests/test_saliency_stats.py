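"""Occlusion maps, smoothing, GLM contrast, TFCE and permutation FWER."""

import numpy as np
import pytest
from scipy import ndimage, stats

from neuromae import saliency_stats as ss

GRID = (16, 16, 8)


class _ConstantScorer:
    """P(class) independent of the input: occlusion changes nothing."""

    def predict_proba(self, batch):
        return np.tile([0.7, 0.3], (len(batch), 1))


class _SingleVoxelScorer:
    """P(class 0) depends only on the intensity of one voxel of channel 0."""

    def __init__(self, voxel):
        self.voxel = voxel

    def predict_proba(self, batch):
        v = batch[:, 0, self.voxel[0], self.voxel[1], self.voxel[2]]
        p = 0.5 + 0.4 * v
        return np.stack([p, 1 - p], axis=1)


class TestOcclusionMap:
    def test_constant_model_gives_zero_map(self):
        vol = np.random.default_rng(0).random((3,) + GRID)
        m = ss.occlusion_map(_ConstantScorer(), vol, "A",
                             ss.OcclusionParams(patch_edge=4, stride=2))
        assert m.values.shape == GRID
        assert np.allclose(m.values, 0.0)

    def test_single_voxel_model_localises_to_covering_patches(self):
        vol = np.full((3,) + GRID, 0.8)
        voxel = (8, 8, 4)
        params = ss.OcclusionParams(patch_edge=4, stride=2, fill_value=0.0)
        m = ss.occlusion_map(_SingleVoxelScorer(voxel), vol, "A", params)
        # hiding a patch covering the voxel drops P by 0.4*0.8; elsewhere zero
        assert m.values[voxel] > 0
        covered = np.zeros(GRID, bool)
        e = 4
        for x in range(0, GRID[0] - e + 1):
            for y in range(0, GRID[1] - e + 1):
                for z in range(0, GRID[2] - e + 1):
                    if (x <= voxel[0] < x + e and y <= voxel[1] < y + e
                            and z <= voxel[2] < z + e):
                        covered[x:x + e, y:y + e, z:z + e] = True
        assert np.allclose(m.values[~covered], 0.0)
        assert m.values.max() == m.values[voxel]

    def test_patch_larger_than_grid_rejected(self):
        vol = np.zeros((3,) + GRID)
        with pytest.raises(ValueError, match="larger"):
            ss.occlusion_map(_ConstantScorer(), vol, "A",
                             ss.OcclusionParams(patch_edge=32, stride=8))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        m = np.random.default_rng(1).random(GRID)
        assert np.array_equal(ss.smooth_map(m, 0.0), m)

    def test_constant_map_unchanged(self):
        m = np.full(GRID, 0.3)
        assert np.allclose(ss.smooth_map(m, 4.0), 0.3)

    def test_delta_peak_matches_discrete_kernel_weight(self):
        m = np.zeros((17, 17, 17))
        m[8, 8, 8] = 1.0
        fwhm = 4.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = ss.smooth_map(m, fwhm)
        # oracle: the sampled-and-normalised 1D kernel's central weight, cubed
        r = int(4.0 * sigma + 0.5)
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        k /= k.sum()
        assert out[8, 8, 8] == pytest.approx(k[r] ** 3, abs=1e-6)

    def test_mass_preserved_away_from_boundary(self):
        m = np.zeros((24, 24, 24))
        m[12, 12, 12] = 5.0
        out = ss.smooth_map(m, 4.0)
        assert out.sum() == pytest.approx(5.0, rel=1e-3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            ss.smooth_map(np.zeros(GRID), -1.0)


class TestGlmContrast:
    def test_identical_groups_give_zero(self):
        maps = [np.random.default_rng(2).random(GRID) for _ in range(3)]
        t, zero_var = ss.glm_group_contrast(maps, maps)
        assert np.allclose(t, 0.0)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        a = [rng.random(GRID) for _ in range(4)]
        b = [rng.random(GRID) for _ in range(4)]
        t_ab, _ = ss.glm_group_contrast(a, b)
        t_ba, _ = ss.glm_group_contrast(b, a)
        assert np.allclose(t_ab, -t_ba)

    def test_hand_computed_two_voxel_example(self):
        # 3 vs 3 subjects, 2 "voxels" (embedded in a 3D grid)
        a_vals = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]])
        b_vals = np.array([[2.0, 1.0], [3.0, 2.0], [4.0, 3.0]])

        def embed(rows):
            out = []
            for r in rows:
                g = np.zeros((2, 1, 1))
                g[:, 0, 0] = r
                out.append(g)
            return out

        t, _ = ss.glm_group_contrast(embed(a_vals), embed(b_vals))
        for v in range(2):
            na = nb = 3
            ma, mb = a_vals[:, v].mean(), b_vals[:, v].mean()
            sp = ((a_vals[:, v].var(ddof=1) * 2 + b_vals[:, v].var(ddof=1) * 2)
                  / (na + nb - 2))
            expect = (ma - mb) / np.sqrt(sp * (1 / na + 1 / nb))
            assert t[v, 0, 0] == pytest.approx(expect, abs=1e-10)

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5,) + GRID)
        b = rng.standard_normal((6,) + GRID) + 0.2
        t, _ = ss.glm_group_contrast(a, b)
        ref = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(t, ref, atol=1e-10)

    def test_zero_variance_flagged(self):
        a = [np.zeros(GRID) for _ in range(3)]
        b = [np.zeros(GRID) for _ in range(3)]
        t, zero_var = ss.glm_group_contrast(a, b)
        assert zero_var.all() and (t == 0).all()

    def test_single_map_group_rejected(self):
        m = np.zeros(GRID)
        with pytest.raises(ValueError, match=">= 2"):
            ss.glm_group_contrast([m], [m, m])


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert not ss.tfce(np.zeros(GRID)).any()

    def test_single_voxel_closed_form(self):
        # isolated voxel of height h0 with E=0.5, H=2: integral h^2 dh = h0^3/3
        for h0 in (0.7, 1.0, 2.5):
            m = np.zeros(GRID)
            m[8, 8, 4] = h0
            got = ss.tfce(m, ss.TfceParams(n_steps=1000))[8, 8, 4]
            assert got == pytest.approx(h0 ** 3 / 3, rel=0.01)

    def test_single_voxel_scaling_power(self):
        m = np.zeros(GRID)
        m[8, 8, 4] = 1.0
        p = ss.TfceParams(n_steps=1000)
        base = ss.tfce(m, p)[8, 8, 4]
        for c in (2.0, 3.0):
            assert ss.tfce(c * m, p)[8, 8, 4] / base == pytest.approx(c ** 3, rel=0.01)

    def test_negative_values_enhanced_with_sign(self):
        m = np.zeros(GRID)
        m[4, 4, 4] = 1.0
        m[12, 12, 4] = -1.0
        out = ss.tfce(m, ss.TfceParams(n_steps=200))
        assert out[4, 4, 4] > 0 and out[12, 12, 4] < 0
        assert out[4, 4, 4] == pytest.approx(-out[12, 12, 4], rel=1e-9)

    def test_pointwise_monotone_at_equal_peak(self):
        # map2 >= map1 everywhere with the same maximum (same thresholds):
        # enhanced values can only grow
        rng = np.random.default_rng(5)
        m1 = np.clip(rng.random(GRID) - 0.5, 0, None)
        m1[8, 8, 4] = 1.0
        bump = np.clip(rng.random(GRID) - 0.7, 0, None)
        m2 = np.clip(np.maximum(m1, bump), None, 1.0)
        p = ss.TfceParams(n_steps=100)
        t1, t2 = ss.tfce(m1, p), ss.tfce(m2, p)
        assert (t2 - t1 >= -1e-9).all()

    def test_non_finite_rejected(self):
        m = np.zeros(GRID)
        m[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ss.tfce(m)


class TestPermutationFwer:
    @pytest.fixture()
    def groups(self):
        rng = np.random.default_rng(6)
        a = [ndimage.gaussian_filter(rng.standard_normal(GRID), 2) for _ in range(6)]
        b = [ndimage.gaussian_filter(rng.standard_normal(GRID), 2) for _ in range(6)]
        return a, b

    def test_p_values_within_estimator_bounds(self, groups):
        a, b = groups
        res = ss.permutation_fwer(a, b, n_perm=99, seed=0)
        assert (res.p_map_fwer >= 1 / 100).all()
        assert (res.p_map_fwer <= 1.0).all()
        assert res.sig_mask.shape == GRID

    def test_deterministic_per_seed(self, groups):
        a, b = groups
        r1 = ss.permutation_fwer(a, b, n_perm=99, seed=3)
        r2 = ss.permutation_fwer(a, b, n_perm=99, seed=3)
        assert np.array_equal(r1.p_map_fwer, r2.p_map_fwer)

    def test_invariant_under_common_affine_rescaling(self, groups):
        a, b = groups
        r1 = ss.permutation_fwer(a, b, n_perm=99, seed=1)
        a2 = [3.0 * m + 10.0 for m in a]
        b2 = [3.0 * m + 10.0 for m in b]
        r2 = ss.permutation_fwer(a2, b2, n_perm=99, seed=1)
        # identical up to float round-off flipping a tie by one 1/(n+1) step
        assert np.abs(r1.p_map_fwer - r2.p_map_fwer).max() <= 1 / 100 + 1e-12

    def test_few_relabelings_warn_with_attainable_minimum(self):
        rng = np.random.default_rng(7)
        a = [rng.random(GRID) for _ in range(2)]
        b = [rng.random(GRID) for _ in range(2)]
        with pytest.warns(RuntimeWarning, match="distinct relabelings"):
            ss.permutation_fwer(a, b, n_perm=99, seed=0)

    def test_strong_implanted_effect_detected_in_effect_region(self):
        rng = np.random.default_rng(8)
        effect = np.zeros(GRID)
        effect[6:10, 6:10, 2:6] = 3.0
        a = [ndimage.gaussian_filter(rng.standard_normal(GRID), 1) + effect
             for _ in range(8)]
        b = [ndimage.gaussian_filter(rng.standard_normal(GRID), 1) for _ in range(8)]
        res = ss.permutation_fwer(a, b, n_perm=199, seed=0)
        assert res.sig_mask.any()
        idx = np.argwhere(res.sig_mask)
        centroid = tuple(np.round(idx.mean(axis=0)).astype(int))
        assert effect[centroid] > 0  # centroid inside the implanted region
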
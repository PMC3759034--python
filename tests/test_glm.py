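"""Design assembly, voxelwise fitting with prewhitening, smoothness
estimation, and cluster-level random-field inference."""

import numpy as np
import pytest
from scipy import ndimage

from icarank import (
    Volume4D,
    build_block_regressor,
    build_design,
    canonical_hrf,
    cluster_threshold_grf,
    estimate_smoothness,
    fit_glm,
    predicted_response,
)
from conftest import make_noise_volume


@pytest.fixture(scope="module")
def response56():
    box = build_block_regressor(4, 3, 8, 2.5)
    return predicted_response(box, canonical_hrf(2.5)).values


class TestBuildDesign:
    def test_column_counts(self, response56):
        motion = np.random.default_rng(0).standard_normal((56, 6))
        assert build_design(response56).matrix.shape[1] == 2
        assert build_design(response56, motion).matrix.shape[1] == 8
        assert (
            build_design(response56, motion, motion_derivatives=True).matrix.shape[1]
            == 14
        )

    def test_per_run_intercepts(self, response56):
        x = build_design(np.tile(response56, 3), run_boundaries=[0, 56, 112])
        assert x.matrix.shape[1] == 4
        assert sum(lbl.startswith("intercept") for lbl in x.labels) == 3

    def test_rejects_rank_deficiency_naming_columns(self, response56):
        motion = np.zeros((56, 6))
        motion[:, 0] = response56  # duplicate of the task column
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(response56, motion)


class TestFitGlm:
    def test_noise_free_beta_recovery(self, response56):
        vol = make_noise_volume(shape=(8, 8, 4), t=56)
        vol.data[...] = 100.0 + 3.0 * response56
        design = build_design(response56)
        res = fit_glm(vol, design, prewhiten=False)
        np.testing.assert_allclose(res.beta[vol.brain_mask], 3.0, atol=1e-9)

    def test_orthogonal_confound_leaves_beta_unchanged(self, response56):
        """Cross-checked against an explicit normal-equations oracle."""
        rng = np.random.default_rng(1)
        vol = make_noise_volume(shape=(8, 8, 4), t=56, seed=2)
        vol.data += 100.0 + 2.0 * response56
        base = build_design(response56)
        res0 = fit_glm(vol, base, prewhiten=False)

        # confound orthogonalized against every existing column
        conf = rng.standard_normal(56)
        q, _ = np.linalg.qr(base.matrix)
        conf = conf - q @ (q.T @ conf)
        x_aug = np.column_stack([base.matrix, conf])
        aug = type(base)(matrix=x_aug, labels=base.labels + ["confound"])
        res1 = fit_glm(vol, aug, prewhiten=False)
        np.testing.assert_allclose(
            res1.beta[vol.brain_mask], res0.beta[vol.brain_mask], atol=1e-10
        )

        # normal-equations oracle for the augmented fit
        y = vol.data[vol.brain_mask].T
        beta_oracle = np.linalg.solve(x_aug.T @ x_aug, x_aug.T @ y)[0]
        np.testing.assert_allclose(res1.beta[vol.brain_mask], beta_oracle, atol=1e-9)

    def test_prewhitening_recovers_beta_under_ar1_noise(self, response56):
        rng = np.random.default_rng(3)
        vol = make_noise_volume(shape=(10, 10, 4), t=56, seed=4)
        # AR(1) noise, rho=0.5
        e = rng.standard_normal(vol.data.shape)
        for t in range(1, 56):
            vol.data[..., t] = 0.5 * vol.data[..., t - 1] + e[..., t]
        vol.data += 100.0 + 2.0 * response56
        res = fit_glm(vol, build_design(response56), prewhiten=True)
        assert abs(res.beta[vol.brain_mask].mean() - 2.0) < 0.1

    def test_rejects_nonpositive_dof(self):
        vol = make_noise_volume(shape=(8, 8, 4), t=5)
        task = np.random.default_rng(5).standard_normal(5)
        design = build_design(task, run_boundaries=[0, 1, 2, 3])  # 5 cols, 5 rows
        with pytest.raises(ValueError):
            fit_glm(vol, design)


class TestSmoothness:
    def test_white_noise_fwhm(self):
        """Unsmoothed lattice noise: first-difference variance 2 gives
        FWHM = sqrt(2 ln 2) ~ 1.18 voxels."""
        rng = np.random.default_rng(6)
        resid = rng.standard_normal((32, 32, 32, 20))
        mask = np.ones((32, 32, 32), dtype=bool)
        fwhm, resels = estimate_smoothness(resid, mask)
        expected = np.sqrt(2 * np.log(2))
        for f in fwhm:
            assert abs(f - expected) / expected < 0.2

    def test_recovers_applied_kernel(self):
        rng = np.random.default_rng(7)
        kernel_fwhm = 3.0
        sigma = kernel_fwhm / (2 * np.sqrt(2 * np.log(2)))
        resid = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), sigma)
                for _ in range(12)
            ],
            axis=3,
        )
        mask = np.ones((32, 32, 32), dtype=bool)
        fwhm, _ = estimate_smoothness(resid, mask)
        # intrinsic lattice smoothness adds in quadrature to the kernel
        expected = np.sqrt(kernel_fwhm**2 + 2 * np.log(2))
        for f in fwhm:
            assert abs(f - expected) / expected < 0.15

    def test_resels_proportional_to_mask_volume(self):
        rng = np.random.default_rng(8)
        resid = rng.standard_normal((32, 32, 32, 10))
        small = np.zeros((32, 32, 32), dtype=bool)
        small[:16] = True
        big = np.ones((32, 32, 32), dtype=bool)
        _, r_small = estimate_smoothness(resid, small)
        _, r_big = estimate_smoothness(resid, big)
        assert r_big / r_small == pytest.approx(2.0, rel=0.05)

    def test_rejects_flat_residuals(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.zeros((8, 8, 8, 5)), np.ones((8, 8, 8), bool))


class TestClusterInference:
    def test_subthreshold_map_gives_no_clusters(self):
        zmap = np.ones((16, 16, 8))
        mask = np.ones((16, 16, 8), dtype=bool)
        assert cluster_threshold_grf(zmap, mask, 2.3, 0.05, resels=100.0) == []

    def test_single_blob_one_cluster(self):
        zmap = np.zeros((16, 16, 8))
        zmap[4:7, 4:7, 2:4] = 5.0
        mask = np.ones((16, 16, 8), dtype=bool)
        clusters = cluster_threshold_grf(zmap, mask, 2.3, 0.05, resels=100.0)
        assert len(clusters) == 1
        assert clusters[0].size == 3 * 3 * 2
        assert clusters[0].peak_z == 5.0

    def test_diagonal_voxels_join_with_26_connectivity(self):
        zmap = np.zeros((8, 8, 8))
        zmap[2, 2, 2] = zmap[3, 3, 3] = 4.0
        mask = np.ones((8, 8, 8), dtype=bool)
        clusters = cluster_threshold_grf(zmap, mask, 2.3, 0.05, resels=50.0)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_larger_clusters_get_smaller_p(self):
        mask = np.ones((32, 32, 16), dtype=bool)
        za = np.zeros((32, 32, 16))
        za[2:4, 2:4, 2:4] = 3.0
        zb = np.zeros((32, 32, 16))
        zb[2:10, 2:10, 2:8] = 3.0
        pa = cluster_threshold_grf(za, mask, 2.3, 0.05, 500.0)[0].p_corrected
        pb = cluster_threshold_grf(zb, mask, 2.3, 0.05, 500.0)[0].p_corrected
        assert pb < pa

    def test_no_cluster_threshold_mode_flags_everything(self):
        zmap = np.zeros((8, 8, 8))
        zmap[1, 1, 1] = 2.5
        mask = np.ones((8, 8, 8), dtype=bool)
        clusters = cluster_threshold_grf(
            zmap, mask, 2.3, 0.05, resels=None, no_cluster_threshold=True
        )
        assert len(clusters) == 1 and clusters[0].significant

    def test_rejects_nonpositive_resels(self):
        with pytest.raises(ValueError):
            cluster_threshold_grf(
                np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool), 2.3, 0.05, resels=0.0
            )


def test_smoothing_input_enlarges_true_clusters(small_spec):
    """Pre-smoothing the data grows activation clusters on fixed input."""
    from icarank import simulate_patient
    from icarank.pipeline import task_regressor_for
    from icarank.preprocess import grand_mean_scale, highpass_volume
    from dataclasses import replace

    vol, truth, boundaries = simulate_patient(small_spec)
    _, response = task_regressor_for(small_spec)
    pm = truth.primary_activation_mask

    def mean_true_cluster_size(v):
        vg = highpass_volume(grand_mean_scale(v, 10000.0), 20.0)
        design = build_design(response, truth.motion_params, boundaries)
        res = fit_glm(vg, design)
        clusters = cluster_threshold_grf(
            res.zmap, v.brain_mask, 2.3, 0.05, res.resels
        )
        sizes = [
            c.size for c in clusters if pm[tuple(c.voxels.T)].any()
        ]
        return np.mean(sizes) if sizes else 0.0

    smoothed = replace(
        vol, data=ndimage.gaussian_filter(vol.data, sigma=(1.0, 1.0, 1.0, 0.0))
    )
    assert mean_true_cluster_size(smoothed) > mean_true_cluster_size(vol)
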
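"""Reconstruction algorithms: EM fixed points, likelihood monotonicity,
penalty correctness, regularization behavior, calibration."""

import numpy as np
import pytest

import penpet as pp
from penpet.acquisition import Sinogram
from penpet.recon import (
    BSREMSettings,
    OSEMSettings,
    ReconSystem,
    bsrem_reconstruct,
    calibrate_to_concentration,
    gaussian_postfilter,
    mlem_reconstruct,
    osem_reconstruct,
    rdp_penalty,
)
from penpet.projection import system_matrix

from conftest import SMALL_GEOM, SMALL_GRID


def unit_att(geom, shape):
    return Sinogram(np.ones(shape), geom, "factors", {})


class TestEMFixedPoints:
    def test_single_pixel_em_update_is_counts_over_sensitivity(self):
        """On a one-pixel system, one EM update lands on y/s regardless of init."""
        grid = pp.GridSpec(nx=1, ny=1, n_slices=1, pixel_size=2.0)
        geom = pp.ProjectionGeometry(n_angles=2, n_bins=2, bin_width=2.0)
        data = Sinogram(np.array([[3, 1], [2, 4]], dtype=np.int64)[:, :, None], geom, "sampled", {})
        att = unit_att(geom, data.values.shape)
        res = osem_reconstruct(
            data, att, None,
            OSEMSettings(iterations=1, subsets=1, postfilter_fwhm=0.0, psf_fwhm=0.0),
            grid=grid,
        )
        sys = ReconSystem(data, att, None, 1, 0.0, grid)
        s = sys.sens[0][0, 0, 0]
        assert res.image[0, 0, 0] == pytest.approx(data.total / s, rel=1e-12)

    def test_osem_single_subset_matches_explicit_mlem_oracle(self, small_setup):
        """subsets=1 trajectory equals an independently coded MLEM loop."""
        y = small_setup["y"]
        att = small_setup["att"]
        bg = y.meta["background"]
        scale = y.meta["scale"]
        res = mlem_reconstruct(y, att, None, iterations=3, psf_fwhm=0.0)

        # independent oracle: dense-array MLEM over the raw system matrix
        A = system_matrix(SMALL_GEOM, SMALL_GRID)
        factors = (att.values * scale).reshape(-1, SMALL_GRID.n_slices)
        yv = y.values.reshape(-1, SMALL_GRID.n_slices).astype(float)
        bgv = bg.reshape(-1, SMALL_GRID.n_slices)
        sens = np.asarray(A.T @ factors)
        mask = sens > 1e-12 * sens.max()
        x = np.zeros_like(sens)
        x[mask] = 1.0
        # replicate the package's warm start
        proj = factors * np.asarray(A @ x) + bgv
        net = max(yv.sum() - bgv.sum(), 1.0)
        x[mask] = net / max((proj - bgv).sum(), 1e-12)
        for _ in range(3):
            ybar = factors * np.asarray(A @ x) + bgv
            ratio = yv / np.clip(ybar, 1e-12, None)
            upd = np.asarray(A.T @ (factors * ratio))
            x = np.where(mask, x * upd / np.where(mask, sens, 1.0), 0.0)
        oracle = x.reshape(SMALL_GRID.shape)
        np.testing.assert_allclose(res.image, oracle, rtol=1e-10, atol=1e-12)

    def test_mlem_likelihood_monotone(self, small_setup):
        res = mlem_reconstruct(small_setup["y"], small_setup["att"], None, iterations=8)
        trace = np.array(res.trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9 * np.abs(trace[:-1]))

    def test_bsrem_beta0_equals_subset_em(self, small_setup):
        """With beta=0 and alpha=1 the BSREM update is exactly ordered-subset EM."""
        y, att = small_setup["y"], small_setup["att"]
        em = osem_reconstruct(
            y, att, None, OSEMSettings(iterations=2, subsets=16, postfilter_fwhm=0.0)
        )
        bs = bsrem_reconstruct(
            y, att, None,
            BSREMSettings(beta=0.0, subsets=16, max_iterations=2, alpha0=1.0, eta=0.0,
                          tol=0.0, min_step_ratio=0.0),
        )
        np.testing.assert_allclose(bs.image, em.image, rtol=1e-8, atol=1e-10)


class TestRDP:
    def test_uniform_image_zero_value_zero_gradient(self):
        st = BSREMSettings(beta=2.0)
        v, g = rdp_penalty(np.full((6, 6), 3.7), st)
        assert v == 0.0
        np.testing.assert_array_equal(g, 0.0)

    def test_two_pixel_hand_value(self):
        st = BSREMSettings(beta=1.0, gamma=2.0, epsilon=0.0)
        v, _ = rdp_penalty(np.array([[2.0], [0.0]]), st)
        assert v == pytest.approx(4.0 / 6.0, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(12345)
        st = BSREMSettings(beta=1.7, gamma=2.0, epsilon=0.31)
        x = rng.uniform(0.5, 2.0, (8, 8))
        _, g = rdp_penalty(x, st)
        h = 1e-6
        fd = np.zeros_like(x)
        for i in range(8):
            for j in range(8):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += h
                xm[i, j] -= h
                fd[i, j] = (rdp_penalty(xp, st)[0] - rdp_penalty(xm, st)[0]) / (2 * h)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-5

    def test_scale_invariant_value_scaling(self):
        # RDP value is 1-homogeneous in the image (relative differences)
        st = BSREMSettings(beta=1.0, gamma=2.0, epsilon=0.0)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, (5, 5))
        v1, _ = rdp_penalty(x, st)
        v2, _ = rdp_penalty(10 * x, st)
        assert v2 == pytest.approx(10 * v1, rel=1e-10)


class TestPostfilter:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (16, 16, 3))
        np.testing.assert_array_equal(gaussian_postfilter(img, 0.0, 2.5), img)

    def test_uniform_unchanged(self):
        img = np.full((16, 16, 3), 2.2)
        out = gaussian_postfilter(img, 5.0, 2.5)
        np.testing.assert_allclose(out, img, rtol=1e-12)

    def test_mass_preserving_for_compact_object(self):
        img = np.zeros((64, 64, 1))
        img[28:36, 28:36, 0] = 1.0
        out = gaussian_postfilter(img, 6.0, 2.5)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_postfilter(np.zeros((4, 4, 1)), -1.0, 2.5)


class TestBSREM:
    def test_objective_non_decreasing_overall(self, small_setup):
        res = bsrem_reconstruct(
            small_setup["y"], small_setup["att"], None,
            BSREMSettings(beta=0.1, max_iterations=8),
        )
        assert res.trace[-1] >= res.trace[0]
        assert len(res.trace) == res.iterations_run

    def test_images_non_negative(self, small_setup):
        res = bsrem_reconstruct(
            small_setup["y"], small_setup["att"], None,
            BSREMSettings(beta=0.3, max_iterations=6),
        )
        assert res.image.min() >= 0.0
        osem = osem_reconstruct(small_setup["y"], small_setup["att"], None, OSEMSettings())
        assert osem.image.min() >= 0.0

    def test_stronger_beta_reduces_background_noise(self, small_setup):
        vol = small_setup["vol"]
        region = _central_background(vol)
        covs = []
        for beta in (0.05, 0.5):
            res = bsrem_reconstruct(
                small_setup["y"], small_setup["att"], None,
                BSREMSettings(beta=beta, max_iterations=10),
            )
            vals = res.image[region]
            covs.append(vals.std() / vals.mean())
        assert covs[1] < covs[0]

    def test_beta_to_zero_limit_approaches_subset_em(self, small_setup):
        ref = bsrem_reconstruct(
            small_setup["y"], small_setup["att"], None,
            BSREMSettings(beta=0.0, max_iterations=6),
        ).image
        dists = []
        for beta in (0.4, 0.2, 0.1, 0.05):
            img = bsrem_reconstruct(
                small_setup["y"], small_setup["att"], None,
                BSREMSettings(beta=beta, max_iterations=6),
            ).image
            dists.append(np.linalg.norm(img - ref))
        assert dists == sorted(dists, reverse=True)


def _central_background(vol):
    from scipy.ndimage import binary_erosion

    bg = vol.labels == 1
    er = np.stack(
        [binary_erosion(bg[:, :, k], iterations=6) for k in range(bg.shape[2])], axis=2
    )
    er[:, :, :1] = False
    er[:, :, -1:] = False
    return er


class TestEdgePreservation:
    def test_step_phantom_variance_down_edge_kept(self):
        """RDP at moderate beta denoises both plateaus of a step image while
        moving the between-region mean difference by < 5%."""
        grid = pp.GridSpec(nx=64, ny=64, n_slices=3)
        geom = pp.ProjectionGeometry(n_angles=64, n_bins=64, bin_width=2.5)
        X, _ = grid.meshgrid()
        act = np.zeros(grid.shape)
        act[(X < 0)] = 4.0
        act[(X >= 0)] = 20.0
        # confine to a disk so the object is compact
        X2, Y2 = grid.meshgrid()
        act[(X2**2 + Y2**2) > 70.0**2] = 0.0
        true = pp.forward_project(act, geom, psf_fwhm=4.5, grid=grid)
        att = Sinogram(np.ones_like(true.values), geom, "factors", {})
        mean = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=1200.0))
        y = pp.sample_counts(mean, seed=21)
        lo = ((X2**2 + Y2**2) < 55.0**2) & (X2 < -15.0)
        hi = ((X2**2 + Y2**2) < 55.0**2) & (X2 > 15.0)
        lo3 = np.repeat(lo[:, :, None], 3, axis=2)
        hi3 = np.repeat(hi[:, :, None], 3, axis=2)

        img0 = bsrem_reconstruct(y, att, None, BSREMSettings(beta=0.0, max_iterations=12)).image
        img1 = bsrem_reconstruct(y, att, None, BSREMSettings(beta=0.3, max_iterations=12)).image
        var0 = img0[lo3].var() + img0[hi3].var()
        var1 = img1[lo3].var() + img1[hi3].var()
        assert var1 <= var0 / 2.0
        diff0 = img0[hi3].mean() - img0[lo3].mean()
        diff1 = img1[hi3].mean() - img1[lo3].mean()
        assert abs(diff1 - diff0) / diff0 < 0.05


class TestCalibration:
    def test_background_mean_matches_a_b_exactly(self, small_setup):
        res = osem_reconstruct(small_setup["y"], small_setup["att"], None, OSEMSettings())
        img, factor = calibrate_to_concentration(res, small_setup["vol"])
        assert factor > 0
        region_mean = _calibration_region_mean(img, small_setup["vol"])
        assert region_mean == pytest.approx(5.3, rel=1e-3)

    def test_zero_image_rejected(self, small_setup):
        with pytest.raises(ValueError, match="calibration"):
            calibrate_to_concentration(np.zeros(SMALL_GRID.shape), small_setup["vol"])

    def test_factor_stable_across_durations(self, small_setup):
        factors = []
        for frac, seed in ((1.0, 0), (0.5, 1)):
            y = small_setup["y"] if frac == 1.0 else pp.thin_counts(small_setup["y"], frac, seed=seed)
            res = osem_reconstruct(y, small_setup["att"], None, OSEMSettings())
            _, f = calibrate_to_concentration(res, small_setup["vol"])
            factors.append(f)
        assert abs(factors[1] / factors[0] - 1.0) < 0.02


def _calibration_region_mean(img, vol):
    from scipy.ndimage import binary_erosion

    grid = vol.grid
    bg = vol.labels == 1
    n = max(int(round(15.0 / grid.pixel_size)), 1)
    r = np.arange(-n, n + 1)
    disk = (r[:, None] ** 2 + r[None, :] ** 2) <= n**2
    region = np.stack(
        [binary_erosion(bg[:, :, k], structure=disk) for k in range(grid.n_slices)], axis=2
    )
    return img[region].mean()


class TestConvergedContrast:
    def test_converged_osem_recovers_large_sphere_contrast(self, small_setup):
        """Noiseless matched-model data, many full iterations, no post-filter:
        the 37 mm sphere contrast recovery reaches at least 0.9."""
        res = osem_reconstruct(
            small_setup["noiseless"], small_setup["att"], None,
            OSEMSettings(iterations=100, subsets=16, postfilter_fwhm=0.0),
        )
        img, _ = calibrate_to_concentration(res, small_setup["vol"])
        vol = small_setup["vol"]
        sph = vol.labels == 10  # 37 mm sphere
        c_h = img[sph & (np.abs(vol.activity - 42.4) < 1)].mean()
        c_b = _calibration_region_mean(img, vol)
        cr = (c_h / c_b - 1.0) / 7.0
        assert cr >= 0.9
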
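"""Acquisition simulator: projections, attenuation, count budgets, sampling."""


import numpy as np
import pytest

import penpet as pp
from penpet import acquisition as acq_mod
from penpet.acquisition import Sinogram
from penpet.projection import GeometryError

GRID = pp.GridSpec(nx=80, ny=80, n_slices=3)
GEOM = pp.ProjectionGeometry(n_angles=48, n_bins=80, bin_width=2.5)


def disk_image(radius, value=1.0, grid=GRID):
    X, Y = grid.meshgrid()
    img = np.zeros(grid.shape)
    img[(X**2 + Y**2 < radius**2)] = value
    return img


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self):
        s = pp.forward_project(np.zeros(GRID.shape), GEOM, 0.0, GRID)
        assert s.total == 0.0

    def test_uniform_disk_central_chord(self):
        """A unit 50 mm-radius disk projects to a 100 mm central line integral."""
        s = pp.forward_project(disk_image(50.0), GEOM, 0.0, GRID)
        # pixel columns align exactly with bins at angle 0
        got = s.values[0, :, 0].max()
        assert got == pytest.approx(100.0, rel=0.02)

    def test_bin_sums_match_image_integral(self):
        rng = np.random.default_rng(0)
        img = np.zeros(GRID.shape)
        img[20:60, 20:60, :] = rng.uniform(0.5, 2.0, (40, 40, GRID.n_slices))
        s = pp.forward_project(img, GEOM, 4.0, GRID)
        integral = img[:, :, 0].sum() * GRID.pixel_size**2
        per_angle = s.values[:, :, 0].sum(axis=1) * GEOM.bin_width
        np.testing.assert_allclose(per_angle, integral, rtol=0.005)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, GRID.shape)
        b = rng.uniform(0, 1, GRID.shape)
        sa = pp.forward_project(a, GEOM, 3.0, GRID).values
        sb = pp.forward_project(b, GEOM, 3.0, GRID).values
        sab = pp.forward_project(a + 2 * b, GEOM, 3.0, GRID).values
        np.testing.assert_allclose(sab, sa + 2 * sb, atol=1e-9)

    def test_undersized_geometry_rejected(self):
        small = pp.ProjectionGeometry(n_angles=48, n_bins=40, bin_width=2.5)
        with pytest.raises(GeometryError, match="deficit"):
            pp.forward_project(np.zeros(GRID.shape), small, 0.0, GRID)


class TestAttenuation:
    def test_zero_mu_gives_unit_factors(self):
        f = pp.attenuation_factors(np.zeros(GRID.shape), GEOM, GRID)
        np.testing.assert_array_equal(f.values, 1.0)

    def test_water_path_closed_form(self):
        """20 cm of water at 0.096/cm attenuates by exp(-1.92)."""
        mu = disk_image(100.0, 0.096, pp.GridSpec(nx=96, ny=96, n_slices=1))
        geom = pp.ProjectionGeometry(n_angles=48, n_bins=96, bin_width=2.5)
        f = pp.attenuation_factors(mu, geom, pp.GridSpec(nx=96, ny=96, n_slices=1))
        center_bin = (geom.n_bins - 1) // 2
        # pixel projections align with bin centers at angle 0: exact chord
        got = min(f.values[0, center_bin, 0], f.values[0, center_bin + 1, 0])
        assert got == pytest.approx(np.exp(-1.92), rel=1e-6)

    def test_factors_decrease_with_path_length(self):
        grid1 = pp.GridSpec(nx=96, ny=96, n_slices=1)
        geom = pp.ProjectionGeometry(n_angles=48, n_bins=96, bin_width=2.5)
        center = (geom.n_bins - 1) // 2
        prev = 1.0
        for radius in (20.0, 40.0, 60.0, 80.0):
            mu = disk_image(radius, 0.096, grid1)
            f = pp.attenuation_factors(mu, geom, grid1).values[0, center, 0]
            assert f < prev
            prev = f

    def test_negative_mu_rejected(self):
        mu = np.zeros(GRID.shape)
        mu[0, 0, 0] = -1e-3
        with pytest.raises(ValueError, match="negative"):
            pp.attenuation_factors(mu, GEOM, GRID)


@pytest.fixture(scope="module")
def budget_inputs():
    grid = pp.GridSpec(nx=80, ny=80, n_slices=3)
    spec = pp.PhantomSpec(body_semiaxes=(90.0, 70.0), sphere_diameters=(22.0,),
                          sphere_ring_radius=45.0, sphere_angles_deg=(0.0,))
    vol = pp.build_phantom(spec, grid)
    true = pp.forward_project(vol, GEOM, psf_fwhm=4.5)
    att = pp.attenuation_factors(vol.mu, GEOM, grid)
    return vol, true, att


class TestExpectedCounts:
    def test_zero_activity_zero_mean(self):
        zero = pp.forward_project(np.zeros(GRID.shape), GEOM, 0.0, GRID)
        att = pp.attenuation_factors(np.zeros(GRID.shape), GEOM, GRID)
        m = pp.expected_counts(zero, att, pp.AcquisitionSettings())
        assert m.total == 0.0

    def test_exactly_linear_in_duration(self, budget_inputs):
        _, true, att = budget_inputs
        m600 = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=600.0))
        m300 = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=300.0))
        np.testing.assert_allclose(m600.values, 2.0 * m300.values, rtol=1e-12)

    def test_trues_total_matches_budget(self, budget_inputs):
        vol, true, att = budget_inputs
        acq = pp.AcquisitionSettings(duration=600.0, scatter_fraction=0.0)
        m = pp.expected_counts(true, att, acq)
        expect = acq.sensitivity * vol.total_activity_kbq * acq.duration
        assert m.total == pytest.approx(expect, rel=1e-9)

    def test_scatter_fraction_construction(self, budget_inputs):
        _, true, att = budget_inputs
        acq = pp.AcquisitionSettings(duration=600.0, scatter_fraction=0.417)
        m = pp.expected_counts(true, att, acq)
        scatter = m.meta["background"]
        assert scatter.sum() / m.values.sum() == pytest.approx(0.417, abs=1e-6)

    def test_randoms_term_flat(self, budget_inputs):
        _, true, att = budget_inputs
        acq = pp.AcquisitionSettings(duration=600.0, scatter_fraction=0.0, randoms_fraction=0.2)
        m = pp.expected_counts(true, att, acq)
        bg = m.meta["background"]
        assert np.ptp(bg) == pytest.approx(0.0, abs=1e-12)
        assert bg.sum() / m.values.sum() == pytest.approx(0.2, rel=1e-9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            pp.AcquisitionSettings(scatter_fraction=0.6, randoms_fraction=0.5)


class TestSampling:
    def test_zero_mean_zero_counts(self, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=1e-9))
        y = pp.sample_counts(m, seed=0)
        assert y.total <= 10  # duration ~ 0: essentially no counts

    def test_reproducible_for_fixed_seed(self, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=600.0))
        a = pp.sample_counts(m, seed=42)
        b = pp.sample_counts(m, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_total_counts_near_total_mean(self, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=1200.0))
        total_mean = m.total
        assert total_mean >= 1e5
        y = pp.sample_counts(m, seed=3)
        assert abs(y.total - total_mean) < 4.0 * np.sqrt(total_mean)

    def test_sampled_input_rejected(self, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=600.0))
        y = pp.sample_counts(m, seed=0)
        with pytest.raises(ValueError, match="mean"):
            pp.sample_counts(y, seed=1)


@pytest.fixture(scope="module")
def counts(budget_inputs):
    _, true, att = budget_inputs
    m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=1200.0))
    return pp.sample_counts(m, seed=5)


class TestThinning:
    def test_fraction_one_is_identity(self, counts):
        t = pp.thin_counts(counts, 1.0, seed=0)
        np.testing.assert_array_equal(t.values, counts.values)

    def test_fraction_out_of_range_rejected(self, counts):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pp.thin_counts(counts, bad, seed=0)

    def test_thinned_total_within_binomial_bound(self, counts):
        p = 0.37
        t = pp.thin_counts(counts, p, seed=11)
        n = counts.total
        sd = np.sqrt(n * p * (1 - p))
        assert abs(t.total - p * n) < 3.0 * sd

    def test_metadata_rescaled(self, counts):
        t = pp.thin_counts(counts, 0.25, seed=1)
        assert t.meta["scale"] == pytest.approx(0.25 * counts.meta["scale"])
        np.testing.assert_allclose(t.meta["background"], 0.25 * counts.meta["background"])

    def test_two_halvings_match_one_quartering(self):
        """thin(0.5) twice and thin(0.25) agree in mean and variance."""
        rng_mean = np.full((8, 8, 1), 200.0)
        m = Sinogram(rng_mean, GEOM_SMALL, "mean", {})
        totals_half2, totals_quarter = [], []
        for s in range(100):
            y = pp.sample_counts(m, seed=1000 + s)
            a = pp.thin_counts(pp.thin_counts(y, 0.5, seed=2000 + s), 0.5, seed=3000 + s)
            b = pp.thin_counts(y, 0.25, seed=4000 + s)
            totals_half2.append(a.total)
            totals_quarter.append(b.total)
        mu1, mu2 = np.mean(totals_half2), np.mean(totals_quarter)
        v1, v2 = np.var(totals_half2), np.var(totals_quarter)
        expect_mu = 0.25 * 200.0 * 64
        sem = np.sqrt(expect_mu / 100)  # Poisson-dominated spread of the mean
        assert abs(mu1 - expect_mu) < 4 * sem and abs(mu2 - expect_mu) < 4 * sem
        assert 0.5 < v1 / v2 < 2.0  # variances agree within sampling error

    def test_poisson_binomial_composition(self):
        """Mean of thin(sample(m), p) approaches p*m on aggregates."""
        m = Sinogram(np.full((16, 16, 1), 50.0), GEOM_SMALL, "mean", {})
        p = 0.4
        totals = [
            pp.thin_counts(pp.sample_counts(m, seed=s), p, seed=10_000 + s).total
            for s in range(60)
        ]
        expect = p * 50.0 * 256
        assert abs(np.mean(totals) - expect) / expect < 0.01

    def test_mean_sinogram_rejected(self, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=600.0))
        with pytest.raises(ValueError, match="sampled"):
            pp.thin_counts(m, 0.5, seed=0)


GEOM_SMALL = pp.ProjectionGeometry(n_angles=8, n_bins=8, bin_width=2.5)


class TestHDF5:
    def test_roundtrip(self, tmp_path, budget_inputs):
        _, true, att = budget_inputs
        m = pp.expected_counts(true, att, pp.AcquisitionSettings(duration=600.0))
        y = pp.sample_counts(m, seed=9)
        path = tmp_path / "sino.h5"
        acq_mod.save_sinogram(y, path)
        back = acq_mod.load_sinogram(path)
        np.testing.assert_array_equal(back.values, y.values)
        assert back.kind == "sampled"
        assert back.geom == y.geom
        assert back.meta["grid"] == y.meta["grid"]
        np.testing.assert_allclose(back.meta["background"], y.meta["background"])
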
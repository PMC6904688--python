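"""Shared fixtures.

Heavy simulation fixtures are session-scoped so the reconstruction-dependent
tests and the acceptance suite share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import penpet as pp
from penpet.acquisition import Sinogram


@pytest.fixture(scope="session")
def desk_grid() -> pp.GridSpec:
    return pp.GridSpec()


@pytest.fixture(scope="session")
def nema_volumes(desk_grid):
    """Default NEMA IQ phantom at ratio 8:1 on the desk grid."""
    return pp.build_phantom(pp.PhantomSpec(sphere_ratio=8.0), desk_grid)


# ---------------------------------------------------------------------------
# small reconstruction testbed: one 37 mm and one 22 mm sphere, 5 slices

SMALL_GRID = pp.GridSpec(nx=96, ny=96, n_slices=5)
SMALL_SPEC = pp.PhantomSpec(
    body_semiaxes=(100.0, 80.0),
    sphere_diameters=(37.0, 22.0),
    sphere_ring_radius=45.0,
    sphere_angles_deg=(0.0, 180.0),
    sphere_ratio=8.0,
)
SMALL_GEOM = pp.ProjectionGeometry(n_angles=72, n_bins=96, bin_width=2.5)


@pytest.fixture(scope="session")
def small_setup():
    """Phantom, attenuation, mean and one sampled sinogram on the small grid."""
    vol = pp.build_phantom(SMALL_SPEC, SMALL_GRID)
    acq = pp.AcquisitionSettings(duration=1200.0)
    true = pp.forward_project(vol, SMALL_GEOM, psf_fwhm=acq.psf_fwhm)
    att = pp.attenuation_factors(vol.mu, SMALL_GEOM, SMALL_GRID)
    mean = pp.expected_counts(true, att, acq)
    y = pp.sample_counts(mean, seed=7)
    noiseless = Sinogram(
        np.round(mean.values).astype(np.int64), SMALL_GEOM, "sampled", dict(mean.meta)
    )
    return {"vol": vol, "att": att, "mean": mean, "y": y, "noiseless": noiseless}


@pytest.fixture(scope="session")
def lesion_recon_noiseless(desk_grid):
    """Noiseless high-count OSEM reconstruction of the lesion phantom (SUV)."""
    from penpet import lesions as les

    vol = pp.build_lesion_phantom(pp.default_lesion_spec(), desk_grid)
    acq = pp.AcquisitionSettings(duration=1200.0)
    geom = pp.ProjectionGeometry()
    true = pp.forward_project(vol, geom, psf_fwhm=acq.psf_fwhm)
    att = pp.attenuation_factors(vol.mu, geom, desk_grid)
    mean = pp.expected_counts(true, att, acq)
    data = Sinogram(np.round(mean.values).astype(np.int64), geom, "sampled", dict(mean.meta))
    res = pp.osem_reconstruct(data, att, None, pp.OSEMSettings())
    cal, _ = pp.calibrate_to_concentration(res, vol)
    suv = les.suv_calibrate(cal, les.suv_calibration_factor(vol))
    return {"vol": vol, "suv": suv}


@pytest.fixture(scope="session")
def headline():
    """The full scaled-down noise-reduction study (shared with acceptance)."""
    from penpet.analysis import noise_reduction_summary

    return noise_reduction_summary(1, n_realizations=5)
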
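"""Projection-domain acquisition simulator with Poisson count statistics.

The chain is:

1. ``forward_project`` — noiseless line integrals of the (PSF-blurred)
   activity map.
2. ``attenuation_factors`` — per-LOR survival probabilities from the mu map.
3. ``expected_counts`` — scale the attenuated trues to the count budget of an
   acquisition (sensitivity x total activity x duration), add a smooth
   scatter background normalized to the scanner's scatter fraction and an
   optional flat randoms term.
4. ``sample_counts`` — an independent Poisson draw per sinogram element.
5. ``thin_counts`` — binomial thinning, the count-statistics equivalent of a
   retrospective list-mode selection of a shorter acquisition.

Default acquisition constants mirror a modern 3-ring SiPM TOF PET/CT
(sensitivity 7.5 cps/kBq, scatter fraction 41.7%); the simulator itself is a
non-TOF 2D multi-slice analog, so TOF-attributable gains are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .grids import GridSpec
from .phantom import PhantomVolumes
from .projection import (
    GeometryError,
    ProjectionGeometry,
    check_span,
    project_slices,
    system_matrix,
)

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = fwhm / (2 sqrt(2 ln 2))

#: Radial FWHM (mm) of the Gaussian used to shape the scatter background.
SCATTER_FWHM_MM = 100.0

#: NEMA system sensitivity of the modeled 3-ring TOF scanner (cps/kBq); it
#: counts coincidences over all oblique planes of the 15 cm axial FOV.
SENSITIVITY_3D_CPS_PER_KBQ = 7.5
AXIAL_FOV_MM = 150.0

#: Effective per-slice sensitivity of the slice-independent 2D analog: a 2D
#: acquisition accepts only in-plane coincidences, so the 3D sensitivity is
#: scaled by the geometric axial acceptance of one 2.78 mm plane.  This keeps
#: the simulated count density (and hence the image noise level) in the
#: regime of the real acquisition instead of concentrating the full 3D count
#: budget into a handful of direct planes.
SENSITIVITY_2D_CPS_PER_KBQ = SENSITIVITY_3D_CPS_PER_KBQ * 2.78 / AXIAL_FOV_MM


@dataclass(frozen=True)
class AcquisitionSettings:
    """Count-statistics parameters of one acquisition.

    duration: seconds (defaults model 20/10/5/2.5/1 min scans).
    sensitivity: cps/kBq; defaults to the effective per-slice 2D-analog
        value, see SENSITIVITY_2D_CPS_PER_KBQ (the scanner's 3D figure is
        available as SENSITIVITY_3D_CPS_PER_KBQ).
    scatter_fraction, randoms_fraction: fractions of total prompts.
    psf_fwhm: mm, isotropic in-plane resolution blur applied in image space.
    """

    duration: float = 1200.0
    sensitivity: float = SENSITIVITY_2D_CPS_PER_KBQ
    scatter_fraction: float = 0.417
    randoms_fraction: float = 0.0
    psf_fwhm: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0 <= self.scatter_fraction < 1) or not (0 <= self.randoms_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.scatter_fraction + self.randoms_fraction >= 1:
            raise ValueError("scatter_fraction + randoms_fraction must be < 1")


DEFAULT_DURATIONS_S = (1200.0, 600.0, 300.0, 150.0, 60.0)


@dataclass
class Sinogram:
    """Projection-domain array of shape (n_angles, n_bins, n_slices).

    ``kind`` is one of "mean" (expected counts or line integrals), "sampled"
    (integer counts) or "factors" (attenuation survival probabilities).
    ``meta`` carries the grid, the count-budget scale and the additive
    background needed by the reconstruction.
    """

    values: np.ndarray
    geom: ProjectionGeometry
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "sampled", "factors"):
            raise ValueError(f"unknown sinogram kind {self.kind!r}")
        if np.any(self.values < 0):
            raise ValueError("sinogram values must be non-negative")
        if self.kind == "sampled" and not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("sampled sinogram must be integer-valued")
            self.values = self.values.astype(np.int64)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def psf_blur(image: np.ndarray, psf_fwhm: float, pixel_size: float) -> np.ndarray:
    """In-plane isotropic Gaussian resolution blur (no axial blur)."""
    if psf_fwhm <= 0:
        return image
    sigma = psf_fwhm * FWHM_TO_SIGMA / pixel_size
    return gaussian_filter(image, sigma=(sigma, sigma, 0.0), mode="reflect")


def forward_project(
    volumes: PhantomVolumes | np.ndarray,
    geom: ProjectionGeometry,
    psf_fwhm: float = 0.0,
    grid: GridSpec | None = None,
) -> Sinogram:
    """Noiseless per-slice parallel projection of the activity map.

    The image is pre-convolved in-plane with an isotropic Gaussian of
    ``psf_fwhm`` mm; the operation is linear in the image.  Returns line
    integrals in (image units x mm).
    """
    if isinstance(volumes, PhantomVolumes):
        image = volumes.activity
        grid = volumes.grid
        total_activity = volumes.total_activity_kbq
    else:
        if grid is None:
            raise ValueError("grid required when projecting a bare array")
        image = np.asarray(volumes, dtype=np.float64)
        total_activity = float(image.sum()) * grid.voxel_volume_ml
    if image.shape != grid.shape:
        raise GeometryError(f"image shape {image.shape} does not match grid {grid.shape}")
    check_span(geom, grid)
    A = system_matrix(geom, grid)
    blurred = psf_blur(image, psf_fwhm, grid.pixel_size)
    values = project_slices(A, blurred, geom)
    return Sinogram(
        values=values,
        geom=geom,
        kind="mean",
        meta={"grid": grid, "total_activity_kbq": total_activity, "psf_fwhm": psf_fwhm},
    )


def attenuation_factors(
    mu_map: np.ndarray, geom: ProjectionGeometry, grid: GridSpec
) -> Sinogram:
    """Survival factors exp(-integral of mu) per LOR; mu in 1/cm, paths in mm."""
    mu_map = np.asarray(mu_map, dtype=np.float64)
    if np.any(mu_map < 0):
        raise ValueError("attenuation map contains negative values")
    check_span(geom, grid)
    A = system_matrix(geom, grid)
    line_int_mm = project_slices(A, mu_map, geom)  # (1/cm) x mm
    factors = np.exp(-line_int_mm / 10.0)
    return Sinogram(values=factors, geom=geom, kind="factors", meta={"grid": grid})


def expected_counts(
    true_sino: Sinogram, att: Sinogram, acq: AcquisitionSettings
) -> Sinogram:
    """Mean prompts sinogram for one acquisition.

    Attenuated trues are scaled so their total equals
    sensitivity (cps/kBq) x total activity (kBq) x duration (s); the scatter
    term is the trues convolved radially with a wide Gaussian and normalized
    so that scatter / prompts = scatter_fraction; randoms are flat.  Every
    component is linear in duration, so doubling the duration exactly doubles
    every mean.
    """
    if true_sino.values.shape != att.values.shape:
        raise ValueError("trues and attenuation sinograms have different shapes")
    if true_sino.kind != "mean":
        raise ValueError("true_sino must be a mean sinogram")
    total_activity = true_sino.meta.get("total_activity_kbq")
    if total_activity is None:
        raise ValueError("true_sino lacks total_activity_kbq metadata")

    attenuated = true_sino.values * att.values
    target_trues = acq.sensitivity * total_activity * acq.duration
    raw_total = attenuated.sum()
    if raw_total <= 0:
        scale = 0.0
        trues = np.zeros_like(attenuated)
    else:
        scale = target_trues / raw_total
        trues = scale * attenuated

    sf, rf = acq.scatter_fraction, acq.randoms_fraction
    prompts_total = target_trues / (1.0 - sf - rf)
    background = np.zeros_like(trues)
    if sf > 0 and trues.sum() > 0:
        sigma_bins = SCATTER_FWHM_MM * FWHM_TO_SIGMA / true_sino.geom.bin_width
        scatter = gaussian_filter1d(trues, sigma=sigma_bins, axis=1, mode="constant")
        background += scatter * (sf * prompts_total / scatter.sum())
    if rf > 0:
        background += rf * prompts_total / trues.size

    meta = dict(true_sino.meta)
    meta.update(
        scale=scale,
        background=background,
        duration=acq.duration,
        settings=asdict(acq),
    )
    return Sinogram(values=trues + background, geom=true_sino.geom, kind="mean", meta=meta)


def sample_counts(mean: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per element; reproducible for a fixed seed."""
    if mean.kind != "mean":
        raise ValueError("sample_counts requires a mean sinogram")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean.values)
    meta = dict(mean.meta)
    meta["seed"] = seed
    return Sinogram(values=counts, geom=mean.geom, kind="sampled", meta=meta)


def thin_counts(counts: Sinogram, fraction: float, seed: int) -> Sinogram:
    """Binomial thinning of a sampled sinogram.

    Each recorded event is kept independently with probability ``fraction``,
    which is distributionally identical to a Poisson acquisition of
    ``fraction`` times the duration.  The count-budget scale and additive
    background metadata are rescaled accordingly so the thinned data remain
    consistent with the reconstruction's forward model.
    """
    if counts.kind != "sampled":
        raise ValueError("thin_counts requires a sampled sinogram")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return Sinogram(counts.values.copy(), counts.geom, "sampled", dict(counts.meta))
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts.values.astype(np.int64), fraction)
    meta = dict(counts.meta)
    meta["thin_fraction"] = fraction * meta.get("thin_fraction", 1.0)
    if "scale" in meta:
        meta["scale"] = meta["scale"] * fraction
    if "background" in meta:
        meta["background"] = meta["background"] * fraction
    if "duration" in meta:
        meta["duration"] = meta["duration"] * fraction
    return Sinogram(values=thinned, geom=counts.geom, kind="sampled", meta=meta)


# ---------------------------------------------------------------------------
# HDF5 container

def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=sino.values)
        fh.attrs["kind"] = sino.kind
        for k in ("n_angles", "n_bins", "bin_width"):
            fh.attrs[k] = getattr(sino.geom, k)
        grid = sino.meta.get("grid")
        if grid is not None:
            fh.attrs["grid"] = [grid.nx, grid.ny, grid.n_slices, grid.pixel_size, grid.slice_thickness]
        for k in ("scale", "duration", "seed", "thin_fraction", "total_activity_kbq", "psf_fwhm"):
            if k in sino.meta:
                fh.attrs[k] = sino.meta[k]
        if "background" in sino.meta:
            fh.create_dataset("background", data=sino.meta["background"])


def load_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        values = fh["values"][...]
        geom = ProjectionGeometry(
            n_angles=int(fh.attrs["n_angles"]),
            n_bins=int(fh.attrs["n_bins"]),
            bin_width=float(fh.attrs["bin_width"]),
        )
        meta: dict = {}
        if "grid" in fh.attrs:
            nx, ny, nz, ps, st = fh.attrs["grid"]
            meta["grid"] = GridSpec(int(nx), int(ny), int(nz), float(ps), float(st))
        for k in ("scale", "duration", "seed", "thin_fraction", "total_activity_kbq", "psf_fwhm"):
            if k in fh.attrs:
                meta[k] = fh.attrs[k]
        if "background" in fh:
            meta["background"] = fh["background"][...]
        kind = str(fh.attrs["kind"])
    return Sinogram(values=values, geom=geom, kind=kind, meta=meta)
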
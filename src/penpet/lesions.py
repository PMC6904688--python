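"""Clinical-analysis metric suite applied to the synthetic lesion phantom.

Mirrors a whole-body FDG reading: images are mapped to an SUV-like scale
(the liver-like region's true concentration maps to SUV 2.2), lesion VOIs are
delineated at 41% of the maximum voxel value on the reference (OSEM)
reconstruction and propagated unchanged to the other reconstructions, and a
3.0 cm spherical reference VOI in the liver provides the noise estimate:

    noise    = SD / SUV_mean                    (liver reference VOI)
    SNR      = (lesion SUV_mean - liver SUV_mean) / liver SD
    contrast = lesion SUV_mean / liver SUV_mean
    MATV     = lesion SUV_mean x lesion volume  (SUV * ml, as defined here)

MATV as defined multiplies SUV_mean by volume, which is dimensionally a
total-lesion-glycolysis-like quantity rather than a volume; it is implemented
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec
from .phantom import LESION_BASE, LIVER, PhantomVolumes

LIVER_SUV_TARGET = 2.2
REFERENCE_VOI_DIAMETER_MM = 30.0
VOI_THRESHOLD_FRACTION = 0.41


class LesionError(ValueError):
    pass


@dataclass
class VOI:
    """3D voxel set: 6-connected component containing the seed maximum."""

    mask: np.ndarray  # 3D boolean
    volume_ml: float
    provenance: str = ""

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class SUVStats:
    suv_mean: float
    suv_max: float
    suv_sd: float


def suv_calibration_factor(volumes: PhantomVolumes, target: float = LIVER_SUV_TARGET) -> float:
    """Linear factor mapping the liver's true concentration to SUV ``target``."""
    liver = volumes.labels == LIVER
    if not liver.any():
        raise LesionError("phantom has no liver region")
    conc = float(volumes.activity[liver].mean())
    if conc <= 0:
        raise LesionError("liver concentration must be positive")
    return target / conc


def suv_calibrate(image: np.ndarray, factor: float) -> np.ndarray:
    """Map a concentration image (kBq/ml) to the SUV-analog scale."""
    if factor <= 0:
        raise LesionError("calibration factor must be positive")
    return np.asarray(image, dtype=np.float64) * factor


_CONN6 = ndimage.generate_binary_structure(3, 1)


def delineate_voi_41(
    image: np.ndarray, seed_mask: np.ndarray, grid: GridSpec, provenance: str = ""
) -> VOI:
    """41%-of-maximum isocontour VOI.

    The threshold is 0.41 x (maximum voxel inside the seed region); the VOI is
    the 6-connected component of {voxels >= threshold} that contains that
    maximum (ties at the threshold included).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 1:
        image = image[:, None, None]
    if seed_mask.ndim == 1:
        seed_mask = seed_mask[:, None, None]
    if not seed_mask.any():
        raise LesionError("empty seed region")
    seed_vals = np.where(seed_mask, image, -np.inf)
    vmax = float(seed_vals.max())
    if vmax <= 0:
        raise LesionError("flat or non-positive image: cannot threshold at 41% of max")
    argmax = np.unravel_index(int(np.argmax(seed_vals)), image.shape)
    above = image >= VOI_THRESHOLD_FRACTION * vmax
    labeled, _ = ndimage.label(above, structure=_CONN6)
    comp = labeled == labeled[argmax]
    volume = float(np.count_nonzero(comp)) * grid.voxel_volume_ml
    return VOI(mask=comp, volume_ml=volume, provenance=provenance)


def propagate_voi(voi: VOI, target: np.ndarray) -> SUVStats:
    """Statistics of the target image over the fixed voxel set (no re-delineation).

    Voxel SD uses the population (n) divisor; VOIs contain enough voxels for
    the divisor choice to be immaterial, but it is fixed for reproducibility.
    """
    if target.shape != voi.mask.shape:
        raise LesionError(
            f"target grid {target.shape} does not match VOI grid {voi.mask.shape}"
        )
    vals = target[voi.mask]
    return SUVStats(
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
        suv_sd=float(vals.std(ddof=0)),
    )


def liver_reference_voi(volumes: PhantomVolumes, diameter: float = REFERENCE_VOI_DIAMETER_MM) -> VOI:
    """Geometric spherical reference VOI placed at the liver center."""
    grid, spec = volumes.grid, volumes.spec
    X, Y = grid.meshgrid()
    r2 = (diameter / 2.0) ** 2
    d2 = (X - spec.liver_center[0]) ** 2 + (Y - spec.liver_center[1]) ** 2
    dz2 = grid.zs() ** 2
    mask = d2[:, :, None] + dz2[None, None, :] <= r2
    mask &= volumes.labels == LIVER
    if not mask.any():
        raise LesionError("liver reference VOI is empty")
    return VOI(mask=mask, volume_ml=float(np.count_nonzero(mask)) * grid.voxel_volume_ml,
               provenance="liver-reference")


def reference_noise(stats: SUVStats) -> float:
    """Liver noise level: SD / SUV_mean of the reference VOI."""
    if stats.suv_mean <= 0:
        raise LesionError("reference SUV_mean must be positive")
    return stats.suv_sd / stats.suv_mean


def lesion_snr(lesion_mean: float, reference_mean: float, reference_sd: float) -> float:
    """(lesion SUV_mean - reference SUV_mean) / reference SD."""
    if reference_sd <= 0:
        raise LesionError("reference SD must be positive")
    return (lesion_mean - reference_mean) / reference_sd


def lesion_contrast(lesion_mean: float, reference_mean: float) -> float:
    """Lesion SUV_mean over liver reference SUV_mean."""
    if reference_mean <= 0:
        raise LesionError("reference mean must be positive")
    return lesion_mean / reference_mean


def matv(lesion_mean: float, volume_ml: float) -> float:
    """Metabolically active tumor value: SUV_mean x volume (SUV * ml)."""
    return lesion_mean * volume_ml


LESION_COLUMNS = [
    "recon", "duration_min", "lesion_id", "volume_ml",
    "suv_mean", "suv_max", "suv_sd", "snr", "contrast", "matv",
]


def lesion_report(
    label: str,
    duration_min: float,
    suv_image: np.ndarray,
    vois: list[VOI],
    reference: SUVStats,
) -> pd.DataFrame:
    """One row per lesion VOI: SUV stats, SNR, contrast, MATV."""
    noise = reference_noise(reference)
    rows = []
    for k, voi in enumerate(vois):
        stats = propagate_voi(voi, suv_image)
        rows.append(
            {
                "recon": label,
                "duration_min": duration_min,
                "lesion_id": k,
                "volume_ml": voi.volume_ml,
                "suv_mean": stats.suv_mean,
                "suv_max": stats.suv_max,
                "suv_sd": stats.suv_sd,
                "snr": lesion_snr(stats.suv_mean, reference.suv_mean, reference.suv_sd),
                "contrast": lesion_contrast(stats.suv_mean, reference.suv_mean),
                "matv": matv(stats.suv_mean, voi.volume_ml),
            }
        )
    df = pd.DataFrame(rows, columns=LESION_COLUMNS[:1] + LESION_COLUMNS[1:])
    df.attrs["reference_noise"] = noise
    return df


def lesion_seed_masks(volumes: PhantomVolumes) -> list[np.ndarray]:
    """Seed regions (true lesion labels) for the 41% delineation."""
    return [
        volumes.labels == LESION_BASE + k for k in range(len(volumes.spec.lesions))
    ]
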
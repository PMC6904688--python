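"""NEMA NU-2 style image-quality analysis of the IQ phantom.

Implements the protocol used to compare the reconstructions: one circular ROI
per hot sphere on the central slice (diameter equal to the sphere's physical
inner diameter), 60 background ROIs per sphere diameter (12 fixed template
locations on each of five slices: central and nearest-slice realizations of
+-1 cm and +-2 cm), and the three headline metrics

    CR_j  = ((C_H,j / C_B,j) - 1) / ((a_H / a_B) - 1)
    COV_j = SD_j / C_B,j          (sample SD over the 60 background ROI means)
    CNR_j = CR_j / COV_j

ROIs are placed from the known phantom geometry; there is no detection step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .grids import GridSpec
from .phantom import BACKGROUND, LUNG, SPHERE_BASE, PhantomVolumes


class NemaError(ValueError):
    """ROI placement constraints violated or metric preconditions unmet."""


#: Fixed template of 12 background ROI center positions (mm), identical on
#: every background slice.  Chosen near the phantom periphery so that every
#: concentric ROI (diameters 10-37 mm) keeps >= 15 mm edge clearance from the
#: body boundary, does not overlap any sphere or the lung insert, and keeps
#: its center >= 15 mm away from their surfaces.  Validated at placement time.
BACKGROUND_ROI_TEMPLATE: tuple[tuple[float, float], ...] = (
    (100.0, 0.0),
    (-105.0, 0.0),
    (0.0, 78.0),
    (0.0, -78.0),
    (80.0, 45.0),
    (80.0, -45.0),
    (-80.0, 45.0),
    (-80.0, -45.0),
    (48.0, 72.0),
    (-48.0, 72.0),
    (70.0, -60.0),
    (-60.0, -62.0),
)

#: Axial background-slice offsets in mm (NEMA: central slice and +-1, +-2 cm).
BACKGROUND_SLICE_OFFSETS_MM: tuple[float, ...] = (0.0, 10.0, -10.0, 20.0, -20.0)


@dataclass
class ROI:
    """Circular 2D ROI on one slice; members are voxel centers inside the disk."""

    slice_index: int
    center: tuple[float, float]
    diameter: float
    mask: np.ndarray  # 2D boolean, shape (nx, ny)

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise NemaError(f"empty ROI at {self.center} (diameter {self.diameter} mm)")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def disk_mask(grid: GridSpec, center: tuple[float, float], diameter: float) -> np.ndarray:
    X, Y = grid.meshgrid()
    r2 = (diameter / 2.0) ** 2
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= r2


def background_slice_indices(grid: GridSpec) -> list[int]:
    """Nearest-integer slice realizations of the +-1 / +-2 cm offsets."""
    out = []
    for off in BACKGROUND_SLICE_OFFSETS_MM:
        k = grid.central_slice + int(round(off / grid.slice_thickness))
        if not (0 <= k < grid.n_slices):
            raise NemaError(f"background slice offset {off} mm falls outside the grid")
        out.append(k)
    return out


def place_sphere_rois(volumes: PhantomVolumes) -> list[ROI]:
    """One ROI per sphere, centered at the true center, on the central slice."""
    grid, spec = volumes.grid, volumes.spec
    half_x, half_y = grid.fov / 2.0, grid.ny * grid.pixel_size / 2.0
    rois = []
    for center, d in zip(spec.sphere_centers(), spec.sphere_diameters):
        if abs(center[0]) > half_x or abs(center[1]) > half_y:
            raise NemaError(f"sphere center {center} lies off the grid")
        rois.append(
            ROI(
                slice_index=grid.central_slice,
                center=(float(center[0]), float(center[1])),
                diameter=float(d),
                mask=disk_mask(grid, center, d),
            )
        )
    return rois


def _clearance_violations(
    spec, pos: tuple[float, float], roi_r: float, edge_mm: float = 15.0
) -> list[str]:
    """Placement rule: ROI edge >= edge_mm inside the body boundary; ROI does
    not overlap spheres/lung and its center stays >= edge_mm from their
    surfaces."""
    bad = []
    a, b = spec.body_semiaxes
    m = roi_r + edge_mm
    if (pos[0] / (a - m)) ** 2 + (pos[1] / (b - m)) ** 2 > 1.0:
        bad.append(f"boundary clearance < {edge_mm} mm at {pos}")
    for j, (c, d) in enumerate(zip(spec.sphere_centers(), spec.sphere_diameters)):
        r_s = d / 2.0
        dist = float(np.hypot(pos[0] - c[0], pos[1] - c[1]))
        if dist < r_s + max(roi_r, edge_mm):
            bad.append(f"too close to sphere_{j} ({d:g} mm): {dist:.1f} mm at {pos}")
    r_l = spec.lung_diameter / 2.0
    dist = float(np.hypot(*pos))
    if dist < r_l + max(roi_r, edge_mm):
        bad.append(f"too close to lung insert: {dist:.1f} mm at {pos}")
    return bad


def place_background_rois(volumes: PhantomVolumes) -> dict[float, list[ROI]]:
    """60 background ROIs per sphere diameter (12 locations x 5 slices).

    At every template location, concentric ROIs are placed at all sphere
    diameters.  Raises listing every violated clearance if the template does
    not fit the configured phantom/grid.
    """
    grid, spec = volumes.grid, volumes.spec
    slices = background_slice_indices(grid)
    violations: list[str] = []
    for pos in BACKGROUND_ROI_TEMPLATE:
        for d in spec.sphere_diameters:
            violations.extend(_clearance_violations(spec, pos, d / 2.0))
    if violations:
        raise NemaError("background ROI constraints unsatisfiable:\n" + "\n".join(violations))

    out: dict[float, list[ROI]] = {}
    for d in spec.sphere_diameters:
        rois = []
        for k in slices:
            for pos in BACKGROUND_ROI_TEMPLATE:
                rois.append(ROI(slice_index=k, center=pos, diameter=float(d), mask=disk_mask(grid, pos, d)))
        for roi in rois:
            lab = volumes.labels[:, :, roi.slice_index][roi.mask]
            if np.any(lab == LUNG) or np.any(lab >= SPHERE_BASE):
                raise NemaError(f"background ROI at {roi.center} intersects a sphere or the lung")
        out[float(d)] = rois
    return out


def roi_mean(image: np.ndarray, roi: ROI) -> float:
    """Arithmetic mean of the ROI's member voxel values."""
    if roi.slice_index >= image.shape[2]:
        raise NemaError("image does not cover the ROI slice")
    vals = image[:, :, roi.slice_index][roi.mask]
    if vals.size == 0:
        raise NemaError("empty ROI")
    return float(vals.mean())


def contrast_recovery(c_h: float, c_b: float, ratio: float) -> float:
    """Hot-sphere contrast recovery: ((C_H/C_B) - 1) / ((a_H/a_B) - 1)."""
    if c_b <= 0:
        raise NemaError("background mean must be positive")
    if ratio <= 1:
        raise NemaError("contrast recovery is undefined for ratio <= 1")
    return ((c_h / c_b) - 1.0) / (ratio - 1.0)


def background_cov(means: Iterable[float]) -> float:
    """COV = sample SD (n-1) of the background ROI means over their average."""
    arr = np.asarray(list(means), dtype=np.float64)
    if arr.size < 2:
        raise NemaError("need at least two background ROI means")
    mean = arr.mean()
    if mean <= 0:
        raise NemaError("background mean must be positive")
    return float(arr.std(ddof=1) / mean)


def cnr(cr: float, variability: float) -> float:
    """Contrast-to-noise ratio: CR divided by the background variability."""
    if variability <= 0:
        raise NemaError("background variability must be positive")
    return cr / variability


def sphere_metrics(
    image: np.ndarray,
    volumes: PhantomVolumes,
    sphere_rois: list[ROI] | None = None,
    bg_rois: dict[float, list[ROI]] | None = None,
) -> pd.DataFrame:
    """Per-sphere CR, background COV and CNR for one reconstructed image."""
    sphere_rois = sphere_rois or place_sphere_rois(volumes)
    bg_rois = bg_rois or place_background_rois(volumes)
    ratio = volumes.spec.sphere_ratio
    rows = []
    for roi in sphere_rois:
        c_h = roi_mean(image, roi)
        means = [roi_mean(image, r) for r in bg_rois[roi.diameter]]
        c_b = float(np.mean(means))
        cr = contrast_recovery(c_h, c_b, ratio)
        cov = background_cov(means)
        rows.append(
            {
                "diameter_mm": roi.diameter,
                "CR": cr,
                "COV": cov,
                "CNR": cnr(cr, cov) if cov > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


METRICS_COLUMNS = ["recon", "duration_min", "ratio", "diameter_mm", "CR", "COV", "CNR"]


def nema_table(
    entries: Iterable[tuple[str, float, float, np.ndarray | None, PhantomVolumes]],
) -> pd.DataFrame:
    """Long-format metrics table over (recon, duration, ratio) combinations.

    ``entries`` yields (recon label, duration_min, ratio, image, volumes);
    a missing image is recorded as NaN rows, not silently dropped.  Rows are
    deterministically ordered.
    """
    frames = []
    for label, duration_min, ratio, image, volumes in entries:
        if image is None:
            df = pd.DataFrame(
                {
                    "diameter_mm": list(volumes.spec.sphere_diameters),
                    "CR": np.nan,
                    "COV": np.nan,
                    "CNR": np.nan,
                }
            )
        else:
            df = sphere_metrics(image, volumes)
        df.insert(0, "ratio", ratio)
        df.insert(0, "duration_min", duration_min)
        df.insert(0, "recon", label)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(
        ["recon", "duration_min", "ratio", "diameter_mm"], kind="stable"
    ).reset_index(drop=True)[METRICS_COLUMNS]


def write_metrics_csv(table: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """CSV with 12-significant-digit floats plus a JSON metadata sidecar."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.12g")
    meta = {"columns": list(table.columns), "n_rows": int(len(table))}
    meta.update(metadata or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def export_rois_json(
    sphere_rois: list[ROI], bg_rois: dict[float, list[ROI]], path: str | Path
) -> None:
    doc = {
        "spheres": [
            {"slice": r.slice_index, "center_mm": list(r.center), "diameter_mm": r.diameter}
            for r in sphere_rois
        ],
        "background": {
            str(d): [
                {"slice": r.slice_index, "center_mm": list(r.center), "diameter_mm": r.diameter}
                for r in rois
            ]
            for d, rois in bg_rois.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
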
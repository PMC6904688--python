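"""Voxelized digital phantoms: the NEMA IEC image-quality phantom and a lesion phantom.

The NEMA IQ phantom is a torso-shaped body (approximated as an ellipse constant
across slices) with six fillable hot spheres on a ring around a low-density
lung insert.  The lesion phantom replaces spheres and lung by a uniform
liver-like region plus spherical lesions of varying volume embedded in a
low-uptake soft-tissue background; it is the synthetic stand-in for a
whole-body FDG study with lesions of different sizes.

Voxel membership is decided by a voxel-center-inside-shape test; partial-volume
effects arise naturally from the simulator's PSF and the grid, not from
sub-voxel weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .grids import GridSpec

# Label legend. Sphere j (0-based, in spec order) carries SPHERE_BASE + j,
# lesion k carries LESION_BASE + k.
OUTSIDE = 0
BACKGROUND = 1
LUNG = 2
LIVER = 3
SPHERE_BASE = 10
LESION_BASE = 30


class PhantomError(ValueError):
    """Invalid phantom specification (overlaps, out-of-body shapes, ...)."""


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion: in-plane center (mm), diameter (mm), activity (kBq/ml)."""

    center: tuple[float, float]
    diameter: float
    concentration: float


def sphere_diameter_for_volume(volume_ml: float) -> float:
    """Diameter (mm) of a sphere of the given volume (ml)."""
    return 2.0 * (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of the phantom geometry and fill concentrations.

    NEMA IQ defaults: body ellipse 300 x 230 mm, spheres 10-37 mm on a
    57.2 mm ring at 60 degree spacing, 44.5 mm cold lung insert, background
    5.3 kBq/ml, hot-sphere ratio a_H/a_B in {8, 6, 4, 2}.  Attenuation uses
    standard 511 keV coefficients (water 0.096/cm, lung 0.025/cm, air 0).

    For the lesion phantom the sphere/lung fields are ignored and the
    ``lesions`` / liver fields are used instead; ``soft_tissue_concentration``
    is the uptake of the body background the lesions sit in.
    """

    body_semiaxes: tuple[float, float] = (150.0, 115.0)
    sphere_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_ring_radius: float = 57.2
    sphere_angles_deg: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    lung_diameter: float = 44.5
    background_concentration: float = 5.3
    sphere_ratio: float = 8.0
    lesions: tuple[Lesion, ...] = ()
    liver_center: tuple[float, float] = (-60.0, 25.0)
    liver_radius: float = 45.0
    liver_concentration: float = 10.6
    soft_tissue_concentration: float = 2.65
    mu_water: float = 0.096
    mu_lung: float = 0.025

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.sphere_diameters):
            raise PhantomError("sphere diameters must be strictly positive")
        if len(set(self.sphere_diameters)) != len(self.sphere_diameters):
            raise PhantomError("sphere diameters must be unique")
        if self.sphere_ratio < 1:
            raise PhantomError("sphere_ratio must be >= 1")
        if self.background_concentration < 0:
            raise PhantomError("background concentration must be non-negative")
        if len(self.sphere_angles_deg) < len(self.sphere_diameters):
            raise PhantomError("need one ring angle per sphere")

    @property
    def hot_concentration(self) -> float:
        """a_H = ratio * a_B (kBq/ml)."""
        return self.sphere_ratio * self.background_concentration

    def sphere_centers(self) -> list[tuple[float, float]]:
        """In-plane sphere centers (mm) on the ring, one per diameter."""
        out = []
        for ang in self.sphere_angles_deg[: len(self.sphere_diameters)]:
            a = np.deg2rad(ang)
            out.append(
                (self.sphere_ring_radius * np.cos(a), self.sphere_ring_radius * np.sin(a))
            )
        return out


@dataclass
class PhantomVolumes:
    """Voxelized activity (kBq/ml), attenuation (1/cm) and integer label maps."""

    activity: np.ndarray
    mu: np.ndarray
    labels: np.ndarray
    spec: PhantomSpec
    grid: GridSpec

    def legend(self) -> dict[str, int]:
        leg = {"outside": OUTSIDE, "background": BACKGROUND}
        if np.any(self.labels == LUNG):
            leg["lung"] = LUNG
        if np.any(self.labels == LIVER):
            leg["liver"] = LIVER
        for j in range(len(self.spec.sphere_diameters)):
            if np.any(self.labels == SPHERE_BASE + j):
                leg[f"sphere_{j}"] = SPHERE_BASE + j
        for k in range(len(self.spec.lesions)):
            if np.any(self.labels == LESION_BASE + k):
                leg[f"lesion_{k}"] = LESION_BASE + k
        return leg

    def region_volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.grid.voxel_volume_ml

    @property
    def total_activity_kbq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml


def _ellipse_mask(grid: GridSpec, semiaxes: tuple[float, float]) -> np.ndarray:
    X, Y = grid.meshgrid()
    a, b = semiaxes
    return (X / a) ** 2 + (Y / b) ** 2 <= 1.0


def _cylinder_mask(grid: GridSpec, center: tuple[float, float], radius: float) -> np.ndarray:
    X, Y = grid.meshgrid()
    in_plane = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
    return np.repeat(in_plane[:, :, None], grid.n_slices, axis=2)

def _sphere_mask(
    grid: GridSpec, center: tuple[float, float], z_center: float, diameter: float
) -> np.ndarray:
    X, Y = grid.meshgrid()
    r2 = (diameter / 2.0) ** 2
    d2_plane = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    dz2 = (grid.zs() - z_center) ** 2
    return d2_plane[:, :, None] + dz2[None, None, :] <= r2


def _check_inside_body(
    name: str, center: tuple[float, float], radius: float, semiaxes: tuple[float, float]
) -> None:
    a, b = semiaxes
    if a - radius <= 0 or b - radius <= 0:
        raise PhantomError(f"{name}: radius {radius} mm exceeds body semi-axes")
    if (center[0] / (a - radius)) ** 2 + (center[1] / (b - radius)) ** 2 > 1.0:
        raise PhantomError(
            f"{name}: sphere at {center} with radius {radius} mm extends outside the body"
        )


def _check_no_overlap(
    names: list[str], centers: list[tuple[float, float]], radii: list[float]
) -> None:
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = np.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if d < radii[i] + radii[j]:
                raise PhantomError(f"{names[i]} overlaps {names[j]} (centers {d:.1f} mm apart)")


def build_phantom(spec: PhantomSpec, grid: GridSpec) -> PhantomVolumes:
    """Voxelize the NEMA IQ phantom.

    Spheres are centered axially on the central slice.  Activity is a_B in the
    background, a_H = ratio * a_B in the spheres, zero in the lung insert and
    outside the body.  Attenuation is water inside the body, lung in the
    insert, zero outside.
    """
    if grid.fov < 2 * spec.body_semiaxes[0] or grid.ny * grid.pixel_size < 2 * spec.body_semiaxes[1]:
        raise PhantomError("grid field of view does not contain the phantom body")

    centers = spec.sphere_centers()
    radii = [d / 2.0 for d in spec.sphere_diameters]
    names = [f"sphere_{j} ({d:g} mm)" for j, d in enumerate(spec.sphere_diameters)]
    for name, c, r in zip(names, centers, radii):
        _check_inside_body(name, c, r, spec.body_semiaxes)
        d_lung = np.hypot(*c)
        if d_lung < r + spec.lung_diameter / 2.0:
            raise PhantomError(f"{name} overlaps the lung insert")
    _check_no_overlap(names, centers, radii)

    body = np.repeat(_ellipse_mask(grid, spec.body_semiaxes)[:, :, None], grid.n_slices, axis=2)
    labels = np.where(body, BACKGROUND, OUTSIDE).astype(np.int16)
    lung = _cylinder_mask(grid, (0.0, 0.0), spec.lung_diameter / 2.0) & body
    labels[lung] = LUNG
    for j, (c, d) in enumerate(zip(centers, spec.sphere_diameters)):
        sph = _sphere_mask(grid, c, 0.0, d)
        labels[sph & body] = SPHERE_BASE + j

    activity, mu = _maps_from_labels(labels, spec)
    return PhantomVolumes(activity=activity, mu=mu, labels=labels, spec=spec, grid=grid)


def build_lesion_phantom(spec: PhantomSpec, grid: GridSpec) -> PhantomVolumes:
    """Voxelize the lesion phantom (liver-like region + spherical lesions).

    Lesions sit in the low-uptake soft-tissue background, clear of the liver,
    so that a 41%-of-maximum isocontour separates them from their
    surroundings; the liver is a uniform reference region only.
    """
    if grid.fov < 2 * spec.body_semiaxes[0] or grid.ny * grid.pixel_size < 2 * spec.body_semiaxes[1]:
        raise PhantomError("grid field of view does not contain the phantom body")

    names = [f"lesion_{k} ({les.diameter:g} mm)" for k, les in enumerate(spec.lesions)]
    centers = [les.center for les in spec.lesions]
    radii = [les.diameter / 2.0 for les in spec.lesions]
    for name, c, r in zip(names, centers, radii):
        _check_inside_body(name, c, r, spec.body_semiaxes)
        d_liver = np.hypot(c[0] - spec.liver_center[0], c[1] - spec.liver_center[1])
        if d_liver < r + spec.liver_radius:
            raise PhantomError(f"{name} overlaps the liver region")
    _check_no_overlap(names, centers, radii)

    body = np.repeat(_ellipse_mask(grid, spec.body_semiaxes)[:, :, None], grid.n_slices, axis=2)
    labels = np.where(body, BACKGROUND, OUTSIDE).astype(np.int16)
    liver = _cylinder_mask(grid, spec.liver_center, spec.liver_radius) & body
    labels[liver] = LIVER
    for k, les in enumerate(spec.lesions):
        sph = _sphere_mask(grid, les.center, 0.0, les.diameter)
        labels[sph & body] = LESION_BASE + k

    activity, mu = _maps_from_labels(labels, spec)
    return PhantomVolumes(activity=activity, mu=mu, labels=labels, spec=spec, grid=grid)


def _maps_from_labels(labels: np.ndarray, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Activity and attenuation are pure functions of the label map and spec."""
    activity = np.zeros(labels.shape, dtype=np.float64)
    mu = np.zeros(labels.shape, dtype=np.float64)
    body = labels != OUTSIDE
    mu[body] = spec.mu_water
    mu[labels == LUNG] = spec.mu_lung
    if np.any(labels == LIVER):  # lesion phantom
        activity[labels == BACKGROUND] = spec.soft_tissue_concentration
        activity[labels == LIVER] = spec.liver_concentration
        for k, les in enumerate(spec.lesions):
            activity[labels == LESION_BASE + k] = les.concentration
    else:
        activity[labels == BACKGROUND] = spec.background_concentration
        for j in range(len(spec.sphere_diameters)):
            activity[labels == SPHERE_BASE + j] = spec.hot_concentration
    return activity, mu


def default_lesion_spec(base: PhantomSpec | None = None) -> PhantomSpec:
    """Six-lesion phantom spanning 0.5-15 ml at ~2x liver uptake.

    Lesion uptake defaults to twice the liver concentration, i.e. SUV-analog
    4.4 against a liver at 2.2 and soft tissue at 0.55.
    """
    base = base or PhantomSpec()
    volumes_ml = (0.5, 1.0, 2.0, 4.0, 8.0, 15.0)
    positions = ((-15.0, -40.0), (0.0, 75.0), (0.0, -75.0), (45.0, 62.0), (45.0, -62.0), (70.0, 0.0))
    conc = 2.0 * base.liver_concentration
    lesions = tuple(
        Lesion(center=p, diameter=sphere_diameter_for_volume(v), concentration=conc)
        for v, p in zip(volumes_ml, positions)
    )
    return replace(base, lesions=lesions)


# ---------------------------------------------------------------------------
# configuration and volume I/O

def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["lesions"] = [asdict(l) for l in spec.lesions]
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    lesions = tuple(
        Lesion(center=tuple(l["center"]), diameter=l["diameter"], concentration=l["concentration"])
        for l in d.pop("lesions", [])
    )
    for key in ("body_semiaxes", "sphere_diameters", "sphere_angles_deg", "liver_center"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(lesions=lesions, **d)


def load_spec(path: str | Path) -> tuple[PhantomSpec, GridSpec]:
    """Read a phantom + grid specification from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    grid = GridSpec(**cfg.get("grid", {}))
    spec = spec_from_dict(cfg.get("phantom", {}))
    return spec, grid


def save_spec(spec: PhantomSpec, grid: GridSpec, path: str | Path) -> None:
    cfg = {"grid": asdict(grid), "phantom": spec_to_dict(spec)}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_volumes(vol: PhantomVolumes, directory: str | Path, stem: str = "phantom") -> list[Path]:
    """Write activity/mu/label maps as NIfTI plus a JSON label legend."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = vol.grid.affine()
    written = []
    for name, arr in (("activity", vol.activity), ("mu", vol.mu), ("labels", vol.labels)):
        p = directory / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), p)
        written.append(p)
    legend_path = directory / f"{stem}_legend.json"
    with open(legend_path, "w") as fh:
        json.dump(vol.legend(), fh, indent=2)
    written.append(legend_path)
    return written
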
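"""Voxel volumes, region statistics, and sphere-based diameter estimation.

Geometry conventions
--------------------
Voxel indices are 0-based; the world position (mm) of voxel ``(i, j, k)``
is ``origin_mm + index * spacing_mm`` — a voxel-*center* convention that
round-trips cleanly with NIfTI affines.  All geometric operations
(cropping, sphere membership, sphere fitting) work in world millimetres.

Diameter estimation mirrors the clinical workflow: an implant's bounding
sphere is recovered either from exactly three user-picked surface points
(the circumcircle of the three points promoted to the great circle of a
sphere — the only sphere uniquely determined by three points) or, more
robustly, by an algebraic least-squares (Kåsa) fit to many surface
points.  Voxels of a segmented implant are then classified as inside or
beyond the manufacturer's nominal ("factory") sphere, which is how
marginal spikes beyond the nominal diameter are quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "RegionMask",
    "RegionStats",
    "Sphere",
    "DegenerateGeometryError",
    "region_statistics",
    "crop_dedicated_volume",
    "sphere_from_three_points",
    "fit_sphere_least_squares",
    "classify_against_factory_sphere",
    "surface_voxel_centers",
    "estimate_diameter_mm",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]

#: Triangles with area below this (mm²) are treated as collinear.
COLLINEARITY_TOL_MM2 = 1e-9


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine a sphere."""


@dataclass(frozen=True)
class VoxelVolume:
    """3D scalar HU grid with isometric or anisometric voxel spacing."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "spacing_mm", np.asarray(self.spacing_mm, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "origin_mm", np.asarray(self.origin_mm, dtype=float).reshape(3)
        )
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D grid")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("all spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (n, 3) index array."""
        return self.origin_mm + np.asarray(indices, dtype=float) * self.spacing_mm

    def all_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of every voxel-center world coordinate."""
        grids = np.meshgrid(
            *[np.arange(n) for n in self.shape], indexing="ij"
        )
        idx = np.stack(grids, axis=-1).astype(float)
        return self.origin_mm + idx * self.spacing_mm


@dataclass(frozen=True)
class RegionMask:
    """Boolean selector congruent with a companion :class:`VoxelVolume`."""

    selector: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "selector", np.asarray(self.selector, dtype=bool))
        if self.selector.ndim != 3:
            raise ValueError("selector must be a 3D boolean grid")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.selector))


@dataclass(frozen=True)
class RegionStats:
    mean_hu: float
    sd_hu: float
    max_hu: float
    n_voxels: int
    volume_mm3: float


@dataclass(frozen=True)
class Sphere:
    """Center (world mm) and radius (mm) of a fitted sphere."""

    center_mm: np.ndarray
    radius_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center_mm", np.asarray(self.center_mm, dtype=float).reshape(3)
        )
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean membership (closed ball) for an (n, 3) point array."""
        d2 = np.sum((np.asarray(points_mm, float) - self.center_mm) ** 2, axis=-1)
        return d2 <= self.radius_mm**2


def region_statistics(volume: VoxelVolume, mask: RegionMask) -> RegionStats:
    """Mean, sample SD (n−1), max, count, physical volume over a region.

    The SD of a single-voxel region is defined as 0.
    """
    if mask.selector.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.selector.shape} != volume shape {volume.shape}"
        )
    selected = volume.values[mask.selector]
    if selected.size == 0:
        raise ValueError("region mask selects no voxels")
    sd = float(np.std(selected, ddof=1)) if selected.size > 1 else 0.0
    return RegionStats(
        mean_hu=float(np.mean(selected)),
        sd_hu=sd,
        max_hu=float(np.max(selected)),
        n_voxels=int(selected.size),
        volume_mm3=selected.size * volume.voxel_volume_mm3,
    )


def crop_dedicated_volume(
    volume: VoxelVolume, bounds_mm: Sequence[float] | Sequence[Sequence[float]]
) -> VoxelVolume:
    """Minimal sub-grid whose voxel centers lie inside an axis-aligned box.

    ``bounds_mm`` is ``(x0, x1, y0, y1, z0, z1)`` or three ``(lo, hi)``
    pairs, in world mm (inclusive).  The origin is updated so retained
    voxels keep their world coordinates.
    """
    b = np.asarray(bounds_mm, dtype=float).reshape(3, 2)
    if np.any(b[:, 0] > b[:, 1]):
        raise ValueError("box bounds must satisfy lo <= hi per axis")
    slices = []
    for ax in range(3):
        centers = volume.origin_mm[ax] + np.arange(volume.shape[ax]) * volume.spacing_mm[ax]
        inside = np.nonzero((centers >= b[ax, 0]) & (centers <= b[ax, 1]))[0]
        if inside.size == 0:
            raise ValueError("box does not contain any voxel center")
        slices.append(slice(inside[0], inside[-1] + 1))
    new_origin = volume.origin_mm + np.array(
        [s.start for s in slices], dtype=float
    ) * volume.spacing_mm
    return VoxelVolume(
        values=volume.values[tuple(slices)].copy(),
        spacing_mm=volume.spacing_mm,
        origin_mm=new_origin,
    )


def sphere_from_three_points(p1, p2, p3) -> Sphere:
    """Sphere whose great circle passes through three non-collinear points.

    The center is the circumcenter of the triangle (in its own plane) and
    the radius the circumradius; this is the unique sphere determined by
    exactly three points and is symmetric under any permutation of them.
    """
    a, b, c = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    area2 = np.linalg.norm(n)  # twice the triangle area
    if area2 / 2.0 < COLLINEARITY_TOL_MM2:
        raise DegenerateGeometryError(
            "three-point sphere needs non-collinear, distinct points"
        )
    # Circumcenter: a + alpha*ab + beta*ac with equal distances to a, b, c.
    d = 2.0 * (np.dot(ab, ab) * np.dot(ac, ac) - np.dot(ab, ac) ** 2)
    alpha = (np.dot(ac, ac) * (np.dot(ab, ab) - np.dot(ab, ac))) / d
    beta = (np.dot(ab, ab) * (np.dot(ac, ac) - np.dot(ab, ac))) / d
    center = a + alpha * ab + beta * ac
    radius = float(np.linalg.norm(center - a))
    return Sphere(center_mm=center, radius_mm=radius)


def fit_sphere_least_squares(points: Iterable[Sequence[float]]) -> Sphere:
    """Algebraic (Kåsa) least-squares sphere through ≥ 4 points.

    Linearises ``|p − c|² = r²`` to the normal equations
    ``[2p, 1] · [c, r² − |c|²] = |p|²`` and solves by least squares;
    exact whenever the points actually lie on a sphere.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise DegenerateGeometryError("least-squares sphere fit needs >= 4 3D points")
    A = np.hstack([2.0 * pts, np.ones((pts.shape[0], 1))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "rank-deficient sphere fit (coplanar-degenerate or coincident points)"
        )
    center = sol[:3]
    r2 = sol[3] + np.dot(center, center)
    if r2 <= 0:
        raise DegenerateGeometryError("fitted radius is not positive")
    return Sphere(center_mm=center, radius_mm=float(np.sqrt(r2)))


def classify_against_factory_sphere(
    mask: RegionMask, volume: VoxelVolume, factory: Sphere
) -> tuple[RegionMask, RegionMask]:
    """Partition a region by membership in the factory (nominal) sphere.

    Returns ``(inside, beyond)`` masks over voxel-center world
    coordinates; they partition the input mask exactly.
    """
    if mask.selector.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    idx = np.argwhere(mask.selector)
    centers = volume.voxel_centers_mm(idx)
    inside_flags = factory.contains(centers)
    inside = np.zeros(volume.shape, dtype=bool)
    beyond = np.zeros(volume.shape, dtype=bool)
    inside[tuple(idx[inside_flags].T)] = True
    beyond[tuple(idx[~inside_flags].T)] = True
    return (
        RegionMask(selector=inside, label=mask.label),
        RegionMask(selector=beyond, label=mask.label),
    )


def surface_voxel_centers(mask: RegionMask, volume: VoxelVolume) -> np.ndarray:
    """World coordinates of mask voxels with at least one outside 6-neighbor."""
    if mask.selector.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    eroded = ndimage.binary_erosion(mask.selector)
    surface = mask.selector & ~eroded
    idx = np.argwhere(surface)
    if idx.shape[0] == 0:
        raise ValueError("mask has no surface voxels")
    return volume.voxel_centers_mm(idx)


def estimate_diameter_mm(mask: RegionMask, volume: VoxelVolume) -> float:
    """Implant diameter estimate: least-squares sphere on surface voxels."""
    return fit_sphere_least_squares(surface_voxel_centers(mask, volume)).diameter_mm


# ---------------------------------------------------------------------------
# NIfTI I/O (scalar volumes; masks stored as 0/1 volumes)

def _affine(volume: VoxelVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(volume.spacing_mm)
    aff[:3, 3] = volume.origin_mm
    return aff


def save_volume(volume: VoxelVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume)), str(path))


def load_volume(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    return VoxelVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        spacing_mm=spacing,
        origin_mm=aff[:3, 3],
    )


def save_mask(mask: RegionMask, reference: VoxelVolume, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.selector.astype(np.uint8), _affine(reference)), str(path)
    )


def load_mask(path: str | Path, label: str = "other") -> RegionMask:
    img = nib.load(str(path))
    return RegionMask(selector=np.asarray(img.get_fdata()) > 0.5, label=label)
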
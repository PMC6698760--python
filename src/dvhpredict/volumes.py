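"""Voxel-lattice geometry, contour rasterization, mask algebra and dose
resampling.

Conventions
-----------
* World coordinates are millimetres; dose is Gray.
* Arrays are indexed ``[ix, iy, iz]`` with shape ``(nx, ny, nz)``.
* ``origin`` is the world coordinate of the *center* of voxel ``(0, 0, 0)``;
  the center of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import GeometryError, InvalidContourError

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "StructureMask",
    "DoseGrid",
    "ContourSet",
    "rasterize_contours",
    "subtract_masks",
    "resample_dose",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); each component >= 1.
    spacing : tuple of float
        Voxel pitch in mm along (x, y, z); each component > 0.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GeometryError("shape, spacing and origin must be 3-vectors")
        if any(n < 1 for n in self.shape):
            raise GeometryError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class StructureMask:
    """Binary occupancy of one structure on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    name: str
    role: str  # "target" or "oar"
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise GeometryError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ("target", "oar"):
            raise ValueError(f"role must be 'target' or 'oar', got {self.role!r}")
        if self.is_empty:
            warnings.warn(f"structure {self.name!r} has zero occupied voxels", stacklevel=2)

    @property
    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume


@dataclass
class DoseGrid:
    """Dose in Gy per voxel on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    dose: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise GeometryError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose values must be finite")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be >= 0")


@dataclass
class ContourSet:
    """Per-slice closed planar polygons for one structure.

    ``polygons`` is a list of ``(z, vertices)`` pairs where ``vertices`` is an
    ``(n, 2)`` array of (x, y) mm positions; the polygon is implicitly closed
    (last vertex joins back to the first).
    """

    name: str
    polygons: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        checked = []
        for z, verts in self.polygons:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise InvalidContourError(
                    f"contour of {self.name!r} at z={z} needs >= 3 (x, y) vertices"
                )
            checked.append((float(z), verts))
        self.polygons = checked


def _points_in_polygon(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Inside test with points exactly on an edge counted as inside
    (deterministic tie-break, equivalent to nudging the test point toward
    the polygon interior)."""
    poly = shapely.Polygon(verts)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    return shapely.intersects_xy(poly, points[:, 0], points[:, 1])


def rasterize_contours(contours: ContourSet, grid: VolumeGrid) -> StructureMask:
    """Voxelize planar contours with the even-odd rule at voxel centers.

    A voxel is occupied iff its center lies inside an odd number of the
    polygons assigned to its slice, so inner rings cut holes.  Contours whose
    z-plane matches no grid slice within half a slice spacing are skipped with
    a warning.
    """
    nx, ny, nz = grid.shape
    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    # voxel-center lattice of one slice, flattened in (x, y) index order
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    n_skipped = 0
    for z, verts in contours.polygons:
        iz = int(round((z - grid.origin[2]) / grid.spacing[2]))
        if iz < 0 or iz >= nz or abs(z - zs[min(max(iz, 0), nz - 1)]) > grid.spacing[2] / 2 + 1e-9:
            n_skipped += 1
            continue
        inside = _points_in_polygon(centers, verts).reshape(nx, ny)
        occ[:, :, iz] ^= inside  # even-odd across polygons of the slice

    if n_skipped:
        warnings.warn(
            f"{n_skipped} contour(s) of {contours.name!r} matched no grid slice "
            "within half a slice spacing and were ignored",
            stacklevel=2,
        )
    if not contours.polygons:
        warnings.warn(f"empty contour set for {contours.name!r}", stacklevel=2)
    return StructureMask(grid=grid, name=contours.name, role="oar", occupancy=occ)


def subtract_masks(a: StructureMask, b: StructureMask) -> StructureMask:
    """Boolean difference ``a AND NOT b`` on a shared grid (e.g. lung minus
    target)."""
    if not a.grid.same_geometry(b.grid):
        raise GeometryError(f"grid mismatch between {a.name!r} and {b.name!r}")
    occ = a.occupancy & ~b.occupancy
    return StructureMask(grid=a.grid, name=f"{a.name}-{b.name}", role=a.role, occupancy=occ)


def resample_dose(dose: DoseGrid, target: VolumeGrid) -> DoseGrid:
    """Trilinearly resample a dose grid onto another lattice.

    Target voxel centers outside the source extent receive 0 Gy; the count of
    such voxels is logged.  Raises :class:`GeometryError` if no target center
    falls inside the source extent.
    """
    from scipy.ndimage import map_coordinates

    src = dose.grid
    if target.same_geometry(src):
        return DoseGrid(grid=target, dose=dose.dose.copy())

    axes_idx = []
    for k in range(3):
        world = target.axis_coords(k)
        axes_idx.append((world - src.origin[k]) / src.spacing[k])
    ix, iy, iz = np.meshgrid(*axes_idx, indexing="ij")

    in_extent = np.ones(target.shape, dtype=bool)
    for coord, n in zip((ix, iy, iz), src.shape):
        in_extent &= (coord >= -1e-9) & (coord <= n - 1 + 1e-9)
    n_out = int((~in_extent).sum())
    if n_out == in_extent.size:
        raise GeometryError("target grid has zero spatial overlap with the dose grid")

    coords = np.stack([ix.ravel(), iy.ravel(), iz.ravel()])
    values = map_coordinates(dose.dose, coords, order=1, mode="nearest").reshape(target.shape)
    values[~in_extent] = 0.0
    if n_out:
        logger.info("resample_dose: %d target voxel(s) outside dose extent set to 0 Gy", n_out)
    return DoseGrid(grid=target, dose=np.clip(values, 0.0, None))
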
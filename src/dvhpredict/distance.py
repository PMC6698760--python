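"""Signed distance to the target boundary and (distance, dose) sample
extraction.

The signed distance ``t`` of a voxel is the Euclidean distance (mm, honoring
anisotropic spacing) from its center to the nearest voxel center of the
opposite class: positive outside the target, negative inside.  With this
center-to-center convention ``|t|`` is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import GeometryError, ModelInputError
from .volumes import DoseGrid, StructureMask, VolumeGrid

__all__ = ["SignedDistanceField", "DistanceDoseSamples", "signed_distance_field", "extract_samples"]


@dataclass
class SignedDistanceField:
    """Signed distance (mm) from every voxel center to the target boundary."""

    grid: VolumeGrid
    t: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != self.grid.shape:
            raise GeometryError(f"t shape {self.t.shape} != grid shape {self.grid.shape}")


@dataclass
class DistanceDoseSamples:
    """Paired (t, x) samples for one structure of one plan."""

    structure: str
    plan_id: str
    t: np.ndarray
    x: np.ndarray
    voxel_volume: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape or self.t.ndim != 1:
            raise ValueError("t and x must be 1-D arrays of equal length")
        if self.t.size < 1:
            raise ModelInputError(f"no samples for {self.structure!r}")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t must be finite")
        if np.any(self.x < 0):
            raise ValueError("dose samples must be >= 0")

    def __len__(self) -> int:
        return int(self.t.size)


def signed_distance_field(ptv: StructureMask) -> SignedDistanceField:
    """Signed minimal distance from each voxel center to the target boundary.

    Outside voxels get the distance to the nearest target voxel center;
    inside voxels get minus the distance to the nearest non-target voxel
    center.  If the target fills the whole grid, inside distances fall back
    to the distance to the closest grid boundary face.
    """
    if ptv.is_empty:
        raise ModelInputError("signed distance requires a non-empty target mask")
    if ptv.role != "target":
        raise ModelInputError(f"structure {ptv.name!r} has role {ptv.role!r}, expected 'target'")

    inside = ptv.occupancy
    spacing = ptv.grid.spacing
    if inside.all():
        # degenerate: no outside voxels; distance to nearest grid boundary face
        t_in = np.full(ptv.grid.shape, np.inf)
        for k, (n, s) in enumerate(zip(ptv.grid.shape, spacing)):
            idx = np.arange(n, dtype=float)
            d = (np.minimum(idx, n - 1 - idx) + 0.5) * s
            shape = [1, 1, 1]
            shape[k] = n
            t_in = np.minimum(t_in, d.reshape(shape))
        return SignedDistanceField(grid=ptv.grid, t=-t_in)

    # nonzero input voxels -> distance to nearest zero voxel (center-to-center)
    t_out = distance_transform_edt(~inside, sampling=spacing)
    t_in = distance_transform_edt(inside, sampling=spacing)
    t = np.where(inside, -t_in, t_out)
    return SignedDistanceField(grid=ptv.grid, t=t)


def extract_samples(
    oar: StructureMask,
    sdf: SignedDistanceField,
    dose: DoseGrid,
    max_samples: int | None = None,
    seed: int = 0,
    plan_id: str = "",
) -> DistanceDoseSamples:
    """Collect one (t, x) pair per occupied OAR voxel, in voxel-index order.

    If the voxel count exceeds ``max_samples`` a uniform random subsample of
    exactly ``max_samples`` pairs is drawn with ``seed`` (deterministic);
    surviving pairs keep voxel-index order.
    """
    if oar.is_empty:
        raise ModelInputError(f"OAR {oar.name!r} is empty")
    if not (oar.grid.same_geometry(sdf.grid) and oar.grid.same_geometry(dose.grid)):
        raise GeometryError("OAR mask, distance field and dose must share one grid")

    sel = oar.occupancy  # C-order boolean indexing = voxel-index order
    t = sdf.t[sel]
    x = dose.dose[sel]
    if max_samples is not None and t.size > max_samples:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(t.size, size=max_samples, replace=False))
        t, x = t[keep], x[keep]
    return DistanceDoseSamples(
        structure=oar.name,
        plan_id=plan_id,
        t=t,
        x=x,
        voxel_volume=oar.grid.voxel_volume,
    )
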
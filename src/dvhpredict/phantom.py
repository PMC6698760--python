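"""Synthetic cohorts of radiotherapy-like plans with a known dose-distance
law.

Each plan holds a central ellipsoidal target, a heart-like organ overlapping
the target, a paired-lung-like organ and a thin cord-like cylinder, on one
shared grid.  Voxel dose follows a logistic falloff in signed distance to the
target,

    x(v) = D_rx / (1 + exp((t(v) - t0) / tau_plan)) + noise,

with per-plan falloff variability (log-normal multiplier on tau) and
truncated-Gaussian voxel noise, so the conditional law the KDE model assumes
holds exactly and an analytic ground-truth DVH is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, truncnorm

from .distance import signed_distance_field
from .errors import PhantomSpecError
from .dvh import DvhCurve
from .volumes import DoseGrid, StructureMask, VolumeGrid

__all__ = ["PhantomSpec", "SyntheticPlan", "generate_plan", "generate_cohort", "true_dvh"]


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort recipe: geometry, dose falloff and variability parameters."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    prescription_gy: float = 50.0
    target_radii_mm: tuple[float, float, float] = (18.0, 18.0, 55.0)
    center_jitter_mm: float = 5.0
    falloff_offset_mm: float = 10.0  # t0: distance at which dose = D_rx / 2
    falloff_scale_mm: float = 4.0  # tau
    dose_noise_gy: float = 1.0  # sigma_a
    tau_sigma: float = 0.1  # sigma of log-normal per-plan tau multiplier
    seed: int = 0
    # per-OAR geometry: (kind, center offset mm, size mm)
    oars: tuple = (
        ("Heart", "ellipsoid", (0.0, 45.0, -35.0), (45.0, 40.0, 45.0)),
        ("Lung", "paired_ellipsoid", (47.0, 0.0, 10.0), (35.0, 45.0, 80.0)),
        ("Cord", "cylinder", (0.0, -35.0, 0.0), (5.0, 5.0, 100.0)),
    )

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise PhantomSpecError("prescription dose must be > 0")
        if self.falloff_scale_mm <= 0:
            raise PhantomSpecError("falloff scale tau must be > 0")
        if self.dose_noise_gy < 0:
            raise PhantomSpecError("dose noise sigma must be >= 0")
        if any(r <= 0 for r in self.target_radii_mm):
            raise PhantomSpecError("target radii must be > 0")

    def grid(self) -> VolumeGrid:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))
        return VolumeGrid(shape=self.shape, spacing=self.spacing, origin=origin)


@dataclass
class SyntheticPlan:
    """One generated plan: masks, dose and its generating parameters."""

    plan_id: str
    structures: dict[str, StructureMask]
    dose: DoseGrid
    ground_truth: dict = field(default_factory=dict)

    @property
    def target(self) -> StructureMask:
        for m in self.structures.values():
            if m.role == "target":
                return m
        raise KeyError("plan has no target structure")


def _ellipsoid(grid: VolumeGrid, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    axes = [grid.axis_coords(k) for k in range(3)]
    q = np.zeros(grid.shape)
    for k in range(3):
        shape = [1, 1, 1]
        shape[k] = grid.shape[k]
        q = q + (((axes[k] - center[k]) / radii[k]) ** 2).reshape(shape)
    return q <= 1.0


def _cylinder(grid: VolumeGrid, center: np.ndarray, size: np.ndarray) -> np.ndarray:
    # size = (radius_x, radius_y, half-length_z); axis along z
    axes = [grid.axis_coords(k) for k in range(3)]
    rx, ry, hz = size
    q = (((axes[0] - center[0]) / rx) ** 2).reshape(-1, 1, 1) + (
        ((axes[1] - center[1]) / ry) ** 2
    ).reshape(1, -1, 1)
    inz = (np.abs(axes[2] - center[2]) <= hz).reshape(1, 1, -1)
    return (q <= 1.0) & inz


def _plan_rng(spec: PhantomSpec, plan_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, int(plan_index)]))


def generate_plan(spec: PhantomSpec, plan_index: int) -> SyntheticPlan:
    """Deterministic function of ``(spec.seed, plan_index)``."""
    rng = _plan_rng(spec, plan_index)
    grid = spec.grid()
    jitter = rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, size=3)
    tau_plan = spec.falloff_scale_mm * float(np.exp(rng.normal(0.0, spec.tau_sigma)))

    target_occ = _ellipsoid(grid, jitter, np.asarray(spec.target_radii_mm))
    if not target_occ.any():
        raise PhantomSpecError("target ellipsoid rasterizes to zero voxels")
    structures = {
        "PTV": StructureMask(grid=grid, name="PTV", role="target", occupancy=target_occ)
    }
    for name, kind, offset, size in spec.oars:
        center = jitter + np.asarray(offset)
        if kind == "ellipsoid":
            occ = _ellipsoid(grid, center, np.asarray(size))
        elif kind == "paired_ellipsoid":
            occ = _ellipsoid(grid, center, np.asarray(size)) | _ellipsoid(
                grid, jitter - np.asarray(offset), np.asarray(size)
            )
        elif kind == "cylinder":
            occ = _cylinder(grid, center, np.asarray(size))
        else:
            raise PhantomSpecError(f"unknown OAR kind {kind!r}")
        structures[name] = StructureMask(grid=grid, name=name, role="oar", occupancy=occ)

    sdf = signed_distance_field(structures["PTV"])
    mu = spec.prescription_gy / (1.0 + np.exp((sdf.t - spec.falloff_offset_mm) / tau_plan))
    if spec.dose_noise_gy > 0:
        a = (0.0 - mu) / spec.dose_noise_gy  # lower truncation at 0 Gy
        dose = truncnorm.rvs(
            a.ravel(), np.inf, loc=mu.ravel(), scale=spec.dose_noise_gy, random_state=rng
        ).reshape(mu.shape)
    else:
        dose = mu
    plan_id = f"plan_{plan_index:03d}"
    return SyntheticPlan(
        plan_id=plan_id,
        structures=structures,
        dose=DoseGrid(grid=grid, dose=dose),
        ground_truth={
            "tau_plan_mm": tau_plan,
            "t0_mm": spec.falloff_offset_mm,
            "sigma_gy": spec.dose_noise_gy,
            "prescription_gy": spec.prescription_gy,
            "center_jitter_mm": jitter.tolist(),
        },
    )


def generate_cohort(spec: PhantomSpec, n_plans: int, start_index: int = 0) -> list[SyntheticPlan]:
    """Plans ``start_index .. start_index + n_plans - 1`` from one spec."""
    if n_plans < 1:
        raise PhantomSpecError("n_plans must be >= 1")
    return [generate_plan(spec, i) for i in range(start_index, start_index + n_plans)]


def true_dvh(plan: SyntheticPlan, oar: str, dose_axis: np.ndarray) -> DvhCurve:
    """Analytic ground-truth DVH of one organ from the generating law.

    DVH(D) = (1/M) * sum_j P(X_j >= D) with X_j a Gaussian of mean
    ``mu(t_j)`` truncated at 0.  The truncation renormalization is applied
    whenever ``mu / sigma <= 5`` and is negligible otherwise.
    """
    if oar not in plan.structures:
        raise KeyError(f"unknown structure {oar!r}; have {sorted(plan.structures)}")
    dose_axis = np.asarray(dose_axis, dtype=float)
    sdf = signed_distance_field(plan.target)
    t = sdf.t[plan.structures[oar].occupancy]
    gt = plan.ground_truth
    mu = gt["prescription_gy"] / (1.0 + np.exp((t - gt["t0_mm"]) / gt["tau_plan_mm"]))
    sigma = gt["sigma_gy"]
    if sigma == 0:
        vf = (mu[:, None] >= dose_axis[None, :]).mean(axis=0)
    else:
        upper = norm.sf((dose_axis[None, :] - mu[:, None]) / sigma)
        z0 = norm.sf((0.0 - mu) / sigma)  # total mass above the truncation point
        needs = mu / sigma <= 5.0
        denom = np.where(needs, z0, 1.0)
        vf = np.clip(upper / denom[:, None], 0.0, 1.0).mean(axis=0)
    vf = np.minimum.accumulate(np.clip(vf, 0.0, 1.0))
    vf[0] = 1.0
    return DvhCurve(structure=oar, dose_axis=dose_axis, volume_fraction=vf, kind="achieved")


def vary_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Convenience: same phantom family, different random seed."""
    return replace(spec, seed=seed)
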
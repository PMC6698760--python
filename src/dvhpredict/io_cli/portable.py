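"""Portable on-disk plan bundle: plan.json + one NRRD per volume."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import FormatError, VersionError
from ..phantom import SyntheticPlan
from ..volumes import ContourSet, DoseGrid, StructureMask
from .nrrd_io import read_nrrd, write_nrrd

SCHEMA_VERSION = 1

__all__ = ["PlanBundle", "write_plan", "read_plan"]


@dataclass
class PlanBundle:
    """One plan as loaded from disk: structures (masks or contours) + dose."""

    plan_id: str
    masks: dict[str, StructureMask] = field(default_factory=dict)
    contours: dict[str, ContourSet] = field(default_factory=dict)
    dose: DoseGrid | None = None
    prescription_gy: float | None = None
    ground_truth: dict | None = None

    @property
    def structure_names(self) -> list[str]:
        return sorted(set(self.masks) | set(self.contours))


def write_plan(plan: SyntheticPlan | PlanBundle, out_dir: str | Path) -> Path:
    """Serialize a plan to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(plan, SyntheticPlan):
        masks = plan.structures
        dose = plan.dose
        plan_id = plan.plan_id
        ground_truth = plan.ground_truth
        prescription = plan.ground_truth.get("prescription_gy")
    else:
        masks, dose, plan_id = plan.masks, plan.dose, plan.plan_id
        ground_truth, prescription = plan.ground_truth, plan.prescription_gy
    if dose is None:
        raise FormatError("cannot write a plan bundle without a dose grid")

    structures = []
    for name in sorted(masks):
        m = masks[name]
        fname = f"mask_{name.replace('/', '_')}.nrrd"
        write_nrrd(out / fname, m.occupancy, m.grid)
        structures.append({"name": name, "role": m.role, "file": fname})
    write_nrrd(out / "dose.nrrd", dose.dose, dose.grid)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "plan_id": plan_id,
        "prescription_gy": prescription,
        "dose": "dose.nrrd",
        "structures": structures,
        "ground_truth": ground_truth,
    }
    (out / "plan.json").write_text(json.dumps(doc, indent=1))
    return out


def read_plan(plan_dir: str | Path) -> PlanBundle:
    """Lossless reload of a bundle written by :func:`write_plan`."""
    plan_dir = Path(plan_dir)
    manifest = plan_dir / "plan.json"
    if not manifest.exists():
        raise FormatError(f"{plan_dir}: no plan.json found")
    doc = json.loads(manifest.read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise VersionError(
            f"{manifest}: schema version {doc.get('schema_version')!r}, expected {SCHEMA_VERSION}"
        )
    dose_path = plan_dir / doc["dose"]
    if not dose_path.exists():
        raise OSError(f"missing volume file: {dose_path}")
    dose_arr, dose_grid = read_nrrd(dose_path)
    bundle = PlanBundle(
        plan_id=doc["plan_id"],
        dose=DoseGrid(grid=dose_grid, dose=np.asarray(dose_arr, dtype=float)),
        prescription_gy=doc.get("prescription_gy"),
        ground_truth=doc.get("ground_truth"),
    )
    for s in doc["structures"]:
        path = plan_dir / s["file"]
        if not path.exists():
            raise OSError(f"missing volume file: {path}")
        occ, grid = read_nrrd(path)
        bundle.masks[s["name"]] = StructureMask(
            grid=grid, name=s["name"], role=s["role"], occupancy=occ.astype(bool)
        )
    return bundle
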
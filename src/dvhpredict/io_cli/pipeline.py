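"""End-to-end pipeline: plan resolution, cohort training, prediction and
cohort evaluation."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..distance import DistanceDoseSamples, extract_samples, signed_distance_field
from ..dvh import DvhCurve, DvhMetrics, density_to_dvh, dvh_metrics, samples_to_dvh
from ..errors import ModelInputError
from ..evaluation import EvaluationReport, build_report
from ..kde_model import KdeModel, predict_dose_density, train_model
from ..volumes import DoseGrid, StructureMask, rasterize_contours, resample_dose, subtract_masks
from .config import PipelineConfig
from .matching import match_structures
from .portable import PlanBundle

logger = logging.getLogger(__name__)

__all__ = ["ResolvedPlan", "resolve_plan", "train_cohort", "predict_plan", "evaluate_cohort"]


@dataclass
class ResolvedPlan:
    """A plan after structure matching, rasterization and derived-structure
    construction: everything on one shared grid."""

    plan_id: str
    target: StructureMask
    oars: dict[str, StructureMask]  # keyed by OAR class
    dose: DoseGrid


def _structure_mask(bundle: PlanBundle, name: str, grid) -> StructureMask:
    if name in bundle.masks:
        return bundle.masks[name]
    return rasterize_contours(bundle.contours[name], grid)


def resolve_plan(bundle: PlanBundle, cfg: PipelineConfig) -> ResolvedPlan:
    """Match structures, voxelize contours on the shared lattice and build
    derived structures (e.g. lung minus target)."""
    if bundle.dose is None:
        raise ModelInputError(f"plan {bundle.plan_id!r} has no dose grid")
    target_name, assignment = match_structures(bundle.structure_names, cfg.match_table)

    # default shared lattice: the dose grid; if masks come on their own grid,
    # keep it and bring the dose there instead
    mask_grids = {m.grid for m in bundle.masks.values()} if bundle.masks else set()
    if mask_grids:
        grid = next(iter(mask_grids))
        dose = resample_dose(bundle.dose, grid) if not grid.same_geometry(bundle.dose.grid) else bundle.dose
    else:
        grid = bundle.dose.grid
        dose = bundle.dose

    target = _structure_mask(bundle, target_name, grid)
    target = StructureMask(grid=target.grid, name=target.name, role="target",
                           occupancy=target.occupancy)
    oars: dict[str, StructureMask] = {}
    for name, cls in assignment.items():
        if cls in oars:
            logger.warning("plan %s: multiple structures for class %s; keeping %s",
                           bundle.plan_id, cls, oars[cls].name)
            continue
        oars[cls] = _structure_mask(bundle, name, grid)
    for derived_cls, base_cls in cfg.derived.items():
        if derived_cls not in oars and base_cls in oars:
            oars[derived_cls] = subtract_masks(oars[base_cls], target)
    oars = {c: m for c, m in oars.items() if not m.is_empty}
    if not oars:
        raise ModelInputError(f"plan {bundle.plan_id!r} has no non-empty OAR after matching")
    return ResolvedPlan(plan_id=bundle.plan_id, target=target, oars=oars, dose=dose)


def _sample_seed(base_seed: int, plan_id: str, structure: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(f"{plan_id}/{structure}".encode())) % 2**31


def plan_class_samples(resolved: ResolvedPlan, cfg: PipelineConfig) -> dict[str, DistanceDoseSamples]:
    """Per-class (t, x) samples for one resolved plan (seeded subsampling
    cap)."""
    sdf = signed_distance_field(resolved.target)
    out = {}
    for cls, mask in resolved.oars.items():
        out[cls] = extract_samples(
            mask,
            sdf,
            resolved.dose,
            max_samples=cfg.max_samples_per_structure,
            seed=_sample_seed(cfg.seed, resolved.plan_id, cls),
            plan_id=resolved.plan_id,
        )
    return out


def train_cohort(bundles: list[PlanBundle], cfg: PipelineConfig) -> dict[str, KdeModel]:
    """Train one KDE model per OAR class from a cohort of plans."""
    if not bundles:
        raise ModelInputError("train_cohort needs at least one plan")
    per_class: dict[str, list[DistanceDoseSamples]] = {}
    for bundle in bundles:
        resolved = resolve_plan(bundle, cfg)
        for cls, samples in plan_class_samples(resolved, cfg).items():
            per_class.setdefault(cls, []).append(samples)
    models = {}
    for cls in sorted(per_class):
        models[cls] = train_model(
            per_class[cls],
            oar_class=cls,
            dx=cfg.dose_bin_gy,
            bandwidth_method=cfg.bandwidth_method,
            plan_equal_weight=cfg.plan_equal_weight,
        )
        logger.info("trained %s: %d pairs from %d plans, h_t=%.3f mm h_x=%.3f Gy",
                    cls, models[cls].n_train, len(per_class[cls]),
                    models[cls].h_t, models[cls].h_x)
    return models


@dataclass
class PlanPrediction:
    """Predicted and achieved DVHs plus metrics for one plan."""

    plan_id: str
    curves: list[DvhCurve] = field(default_factory=list)  # predicted + achieved per class
    predicted_metrics: dict[str, DvhMetrics] = field(default_factory=dict)
    achieved_metrics: dict[str, DvhMetrics] = field(default_factory=dict)

    def metric_records(self, cfg: PipelineConfig) -> list[dict]:
        recs = []
        for cls in sorted(self.predicted_metrics):
            pm, am = self.predicted_metrics[cls], self.achieved_metrics[cls]
            keys = ["mean_gy"] + [f"v{d:g}_pct" for d in sorted(cfg.cutpoints.get(cls, []))]
            if cls in cfg.report_near_max:
                keys.append("near_max_gy")
            pd_, ad = pm.as_dict(), am.as_dict()
            recs.append(
                {
                    "plan_id": self.plan_id,
                    "oar_class": cls,
                    "predicted": {k: pd_[k] for k in keys},
                    "achieved": {k: ad[k] for k in keys},
                }
            )
        return recs


def predict_plan(models: dict[str, KdeModel], bundle: PlanBundle, cfg: PipelineConfig,
                 method: str = "auto") -> PlanPrediction:
    """Predict per-class DVHs for one plan and extract achieved ones from its
    dose."""
    resolved = resolve_plan(bundle, cfg)
    sdf = signed_distance_field(resolved.target)
    pred = PlanPrediction(plan_id=bundle.plan_id)
    for cls, mask in sorted(resolved.oars.items()):
        model = models.get(cls)
        if model is None:
            logger.warning("plan %s: no model for class %s, skipped", bundle.plan_id, cls)
            continue
        query_t = sdf.t[mask.occupancy]
        density = predict_dose_density(model, query_t, dx=cfg.dose_bin_gy, method=method)
        curve = density_to_dvh(density, structure=cls)
        achieved_x = resolved.dose.dose[mask.occupancy]
        x_max = max(model.x_max, float(achieved_x.max()))
        achieved_curve = samples_to_dvh(achieved_x, cfg.dose_bin_gy, x_max, structure=cls)
        cut = cfg.cutpoints.get(cls, [])
        pred.curves += [curve, achieved_curve]
        pred.predicted_metrics[cls] = dvh_metrics(curve, cut, cfg.near_max_fraction)
        pred.achieved_metrics[cls] = dvh_metrics(achieved_x, cut, x_max=x_max)
    if not pred.predicted_metrics:
        raise ModelInputError(f"plan {bundle.plan_id!r}: no OAR class matched a trained model")
    return pred


def evaluate_cohort(models: dict[str, KdeModel], bundles: list[PlanBundle],
                    cfg: PipelineConfig, method: str = "auto") -> tuple[EvaluationReport, list[PlanPrediction]]:
    """Predict every plan and aggregate predicted-vs-achieved statistics."""
    predictions = [predict_plan(models, b, cfg, method=method) for b in bundles]
    records: list[dict] = []
    curve_pairs = []
    for p in predictions:
        records += p.metric_records(cfg)
        by_struct: dict[str, dict[str, DvhCurve]] = {}
        for c in p.curves:
            by_struct.setdefault(c.structure, {})[c.kind] = c
        for pair in by_struct.values():
            if "predicted" in pair and "achieved" in pair:
                curve_pairs.append((p.plan_id, pair["predicted"], pair["achieved"]))
    return build_report(records, curve_pairs), predictions


def save_models(models: dict[str, KdeModel], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cls, model in sorted(models.items()):
        (out / f"model_{cls}.json").write_text(model.to_json())


def load_models(model_dir: str | Path) -> dict[str, KdeModel]:
    models = {}
    for path in sorted(Path(model_dir).glob("model_*.json")):
        model = KdeModel.from_json(path.read_text())
        models[model.oar_class] = model
    if not models:
        raise ModelInputError(f"no model_*.json files in {model_dir}")
    return models
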
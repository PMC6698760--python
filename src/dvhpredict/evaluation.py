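"""Cohort-level comparison of predicted and achieved DVHs.

Per metric: mean of the per-plan (predicted - achieved) differences and their
root mean square error, RMSE = sqrt(sum(diff^2) / N_plans).  Per plan and
structure: ordinary least squares of predicted volume fraction on achieved
volume fraction over the full common dose axis, with R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvh import DvhCurve
from .errors import DegenerateFitError, PairingError

__all__ = ["EvaluationReport", "metric_differences", "dvh_linear_fit", "build_report"]


@dataclass
class EvaluationReport:
    """Aggregated predicted-vs-achieved statistics for one cohort."""

    n_plans: int
    metric_rows: pd.DataFrame = field(repr=False)  # oar_class, metric, mean_difference, rmse
    fit_rows: pd.DataFrame = field(repr=False)  # plan_id, structure, slope, intercept, r_squared

    def to_text(self) -> str:
        """Human-readable table mirroring a per-OAR mean/RMSE layout."""
        lines = [f"Predicted-to-achieved value difference ({self.n_plans} plans)", ""]
        lines.append(f"{'OAR':<12} {'Metric':<14} {'Mean':>8} {'RMSE':>8}")
        for _, r in self.metric_rows.iterrows():
            lines.append(
                f"{r.oar_class:<12} {r.metric:<14} {r.mean_difference:>8.2f} {r.rmse:>8.2f}"
            )
        if len(self.fit_rows):
            lines += ["", f"{'Plan':<12} {'Structure':<14} {'Slope':>8} {'R^2':>8}"]
            for _, r in self.fit_rows.iterrows():
                lines.append(f"{r.plan_id:<12} {r.structure:<14} {r.slope:>8.3f} {r.r_squared:>8.3f}")
        return "\n".join(lines) + "\n"


def metric_differences(
    predicted: dict[str, dict[str, float]],
    achieved: dict[str, dict[str, float]],
) -> dict[str, tuple[float, float]]:
    """Per-metric (mean difference, RMSE) across plans.

    Both arguments map plan id -> {metric name -> value}; the plan sets and
    per-plan metric sets must pair up exactly.
    """
    if set(predicted) != set(achieved):
        unmatched = sorted(set(predicted) ^ set(achieved))
        raise PairingError(f"unmatched plan ids: {unmatched}")
    if not predicted:
        raise PairingError("no plans to compare")
    metrics = None
    diffs: dict[str, list[float]] = {}
    for pid in sorted(predicted):
        p, a = predicted[pid], achieved[pid]
        if set(p) != set(a):
            raise PairingError(f"plan {pid!r}: metric sets differ: {sorted(set(p) ^ set(a))}")
        if metrics is None:
            metrics = set(p)
            diffs = {m: [] for m in sorted(metrics)}
        elif set(p) != metrics:
            raise PairingError(f"plan {pid!r} carries a different metric set")
        for m in p:
            diffs[m].append(p[m] - a[m])
    out = {}
    for m, d in diffs.items():
        d = np.asarray(d, dtype=float)
        out[m] = (float(d.mean()), float(np.sqrt(np.mean(d**2))))
    return out


def dvh_linear_fit(predicted: DvhCurve, achieved: DvhCurve) -> tuple[float, float, float]:
    """OLS of predicted on achieved volume fraction: (slope, intercept, R^2).

    Curves on different axes are first brought onto the finer common axis by
    linear interpolation.
    """
    if predicted.dose_axis.shape == achieved.dose_axis.shape and np.allclose(
        predicted.dose_axis, achieved.dose_axis
    ):
        x = achieved.volume_fraction
        y = predicted.volume_fraction
    else:
        end = min(predicted.dose_axis[-1], achieved.dose_axis[-1])
        step = min(
            predicted.dose_axis[1] - predicted.dose_axis[0],
            achieved.dose_axis[1] - achieved.dose_axis[0],
        )
        axis = np.arange(int(round(end / step)) + 1) * step
        x = np.interp(axis, achieved.dose_axis, achieved.volume_fraction)
        y = np.interp(axis, predicted.dose_axis, predicted.volume_fraction)
    sx = float(np.std(x))
    if np.ptp(x) == 0 or sx < 1e-12:
        raise DegenerateFitError(
            f"achieved DVH of {achieved.structure!r} is constant; linear fit undefined"
        )
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, float(np.clip(r2, 0.0, 1.0))


def build_report(
    plan_metrics: list[dict],
    curve_pairs: list[tuple[str, DvhCurve, DvhCurve]] | None = None,
) -> EvaluationReport:
    """Assemble the cohort report.

    ``plan_metrics`` holds one dict per (plan, structure) with keys
    ``plan_id``, ``oar_class`` and per-metric ``predicted``/``achieved``
    sub-dicts.  ``curve_pairs`` holds (plan_id, predicted, achieved) DVH
    pairs for the per-plan linear fits.  Row ordering is deterministic
    regardless of input order.
    """
    if not plan_metrics:
        raise PairingError("build_report needs at least one evaluated plan")

    by_class: dict[str, tuple[dict, dict]] = {}
    plan_ids = set()
    for rec in plan_metrics:
        pid, cls = rec["plan_id"], rec["oar_class"]
        plan_ids.add(pid)
        pred, ach = by_class.setdefault(cls, ({}, {}))
        pred[pid] = dict(rec["predicted"])
        ach[pid] = dict(rec["achieved"])

    metric_rows = []
    for cls in sorted(by_class):
        pred, ach = by_class[cls]
        for metric, (mean_d, rmse) in sorted(metric_differences(pred, ach).items()):
            metric_rows.append(
                {"oar_class": cls, "metric": metric, "mean_difference": mean_d, "rmse": rmse}
            )

    fit_rows = []
    for pid, pred_curve, ach_curve in sorted(
        curve_pairs or [], key=lambda r: (r[0], r[1].structure)
    ):
        try:
            slope, intercept, r2 = dvh_linear_fit(pred_curve, ach_curve)
        except DegenerateFitError:
            slope = intercept = r2 = float("nan")
        fit_rows.append(
            {
                "plan_id": pid,
                "structure": pred_curve.structure,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
            }
        )

    return EvaluationReport(
        n_plans=len(plan_ids),
        metric_rows=pd.DataFrame(
            metric_rows, columns=["oar_class", "metric", "mean_difference", "rmse"]
        ),
        fit_rows=pd.DataFrame(
            fit_rows, columns=["plan_id", "structure", "slope", "intercept", "r_squared"]
        ),
    )
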
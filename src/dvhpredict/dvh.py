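"""Cumulative DVH curves and clinical DVH metrics.

A DVH gives, for each dose ``D``, the fraction of a structure's volume
receiving at least ``D`` Gy.  Predicted curves come from integrating a dose
probability density, ``DVH(D) = 1 - \\int_0^D p_D(x) dx``; achieved curves
come directly from voxel dose samples.  Cut-point metrics ``Vd`` use the
strict "received dose higher than d" convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ContractError, ModelInputError, RangeError
from .kde_model import PredictedDensity

__all__ = ["DvhCurve", "DvhMetrics", "density_to_dvh", "samples_to_dvh", "dvh_metrics"]


@dataclass
class DvhCurve:
    """Cumulative relative-volume DVH on a uniform dose axis starting at 0."""

    structure: str
    dose_axis: np.ndarray
    volume_fraction: np.ndarray = field(repr=False)
    kind: str = "predicted"  # "predicted" or "achieved"

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_axis.shape != self.volume_fraction.shape or self.dose_axis.ndim != 1:
            raise ValueError("dose_axis and volume_fraction must be equal-length 1-D arrays")
        if self.dose_axis[0] != 0 or np.any(np.diff(self.dose_axis) <= 0):
            raise ValueError("dose_axis must ascend from 0")
        if self.kind not in ("predicted", "achieved"):
            raise ValueError(f"kind must be 'predicted' or 'achieved', got {self.kind!r}")
        if np.any(self.volume_fraction < -1e-12) or np.any(self.volume_fraction > 1 + 1e-12):
            raise ValueError("volume fractions must lie in [0, 1]")
        if np.any(np.diff(self.volume_fraction) > 1e-9):
            raise ValueError("a DVH must be non-increasing")

    def at(self, d: float) -> float:
        """Volume fraction at dose ``d`` (linear interpolation on the axis)."""
        if d < self.dose_axis[0] - 1e-12 or d > self.dose_axis[-1] + 1e-12:
            raise RangeError(f"dose {d} Gy outside DVH axis [0, {self.dose_axis[-1]}]")
        return float(np.interp(d, self.dose_axis, self.volume_fraction))


@dataclass
class DvhMetrics:
    """Clinical summary of one DVH: mean dose, Vd cut-points, near-max."""

    mean_gy: float
    v_cutpoints: dict[float, float]  # cut dose (Gy) -> percent volume
    near_max_gy: float

    def as_dict(self) -> dict[str, float]:
        out = {"mean_gy": self.mean_gy}
        for d in sorted(self.v_cutpoints):
            out[f"v{d:g}_pct"] = self.v_cutpoints[d]
        out["near_max_gy"] = self.near_max_gy
        return out


def density_to_dvh(p: PredictedDensity, structure: str = "") -> DvhCurve:
    """Cumulative trapezoid integration of a normalized dose density."""
    if abs(p.integral - 1.0) > 1e-3:
        raise ContractError(f"density integral {p.integral:.6f} deviates from 1 by > 1e-3")
    cum = cumulative_trapezoid(p.density, p.dose_axis, initial=0.0)
    vf = np.clip(1.0 - cum, 0.0, 1.0)
    vf[0] = 1.0
    vf = np.minimum.accumulate(vf)  # guard float jitter in the tail
    return DvhCurve(structure=structure, dose_axis=p.dose_axis, volume_fraction=vf, kind="predicted")


def samples_to_dvh(x: np.ndarray, dx: float, x_max: float, structure: str = "") -> DvhCurve:
    """Empirical cumulative DVH of voxel dose samples.

    At each axis point ``D`` the curve holds the fraction of samples with
    dose >= D, so DVH(0) = 1 for any nonnegative sample set.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ModelInputError("samples_to_dvh needs at least one dose sample")
    if x_max < x.max():
        raise ValueError(f"x_max={x_max} below max sample {x.max():.3f}")
    axis = np.arange(int(round(x_max / dx)) + 1) * dx
    xs = np.sort(x)
    vf = 1.0 - np.searchsorted(xs, axis, side="left") / x.size
    return DvhCurve(structure=structure, dose_axis=axis, volume_fraction=vf, kind="achieved")


def _vd_from_samples(x: np.ndarray, d: float) -> float:
    return 100.0 * float((x > d).mean())  # strict "higher than d"


def dvh_metrics(
    source: DvhCurve | np.ndarray,
    cutpoints: list[float] | tuple[float, ...] = (),
    near_max_fraction: float = 0.001,
    x_max: float | None = None,
) -> DvhMetrics:
    """Mean dose, Vd cut-points and near-max from a curve or raw samples.

    From a curve: mean is the trapezoidal area under the DVH (equal to
    ``∫ x p(x) dx`` for a density-derived curve), Vd interpolates the curve
    and near-max is the smallest axis dose where the curve drops to
    ``near_max_fraction``.  From samples: mean and strict-inequality Vd are
    computed directly and near-max is the literal sample maximum.
    """
    if isinstance(source, DvhCurve):
        axis, vf = source.dose_axis, source.volume_fraction
        for d in cutpoints:
            if d > axis[-1] + 1e-12:
                raise RangeError(f"cutpoint {d} Gy beyond DVH axis end {axis[-1]} Gy")
        mean = float(np.trapezoid(vf, axis))
        v = {float(d): 100.0 * source.at(float(d)) for d in cutpoints}
        below = vf <= near_max_fraction
        near_max = float(axis[np.argmax(below)]) if below.any() else float(axis[-1])
        return DvhMetrics(mean_gy=mean, v_cutpoints=v, near_max_gy=near_max)

    x = np.asarray(source, dtype=float).ravel()
    if x.size == 0:
        raise ModelInputError("dvh_metrics needs a curve or a nonempty sample set")
    if x_max is not None:
        for d in cutpoints:
            if d > x_max + 1e-12:
                raise RangeError(f"cutpoint {d} Gy beyond dose domain {x_max} Gy")
    return DvhMetrics(
        mean_gy=float(x.mean()),
        v_cutpoints={float(d): _vd_from_samples(x, float(d)) for d in cutpoints},
        near_max_gy=float(x.max()),
    )


def dvh_to_frame(curves: list[DvhCurve]):
    """Long-format table of DVH curves (structure, kind, dose_gy, volume_pct)."""
    import pandas as pd

    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "structure": c.structure,
                    "kind": c.kind,
                    "dose_gy": c.dose_axis,
                    "volume_pct": 100.0 * c.volume_fraction,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
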
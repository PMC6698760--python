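"""Pipeline configuration with YAML overrides.

Every paper-gap default (bin width, bandwidth rule, subsampling cap,
near-max fraction, per-class cut-points, match table, seed) lives here so it
is visible and overridable in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .matching import MatchTable, default_match_table

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    dose_bin_gy: float = 0.1
    max_dose_gy: float | None = None  # None = auto from training doses
    bandwidth_method: str = "reference"  # "reference" | "lscv"
    max_samples_per_structure: int = 20000
    near_max_fraction: float = 0.001
    plan_equal_weight: bool = False
    seed: int = 0
    # metrics reported per class; "mean", "near_max" or "v<d>" cut-points
    cutpoints: dict[str, list[float]] = field(
        default_factory=lambda: {"heart": [30.0], "lung": [20.0, 5.0], "lung_ptv": [20.0, 5.0], "cord": []}
    )
    report_near_max: list[str] = field(default_factory=lambda: ["cord"])
    # derived structures: new class -> (oar class to subtract from, subtract target)
    derived: dict[str, str] = field(default_factory=lambda: {"lung_ptv": "lung"})
    match_table: MatchTable = field(default_factory=default_match_table)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Defaults, optionally overridden by a YAML mapping."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    doc = yaml.safe_load(Path(path).read_text()) or {}
    table = doc.pop("match_table", None)
    if table is not None:
        cfg = replace(
            cfg,
            match_table=MatchTable(
                target_patterns=list(table.get("target", cfg.match_table.target_patterns)),
                oar_patterns={k: list(v) for k, v in table.get("oars", cfg.match_table.oar_patterns).items()},
            ),
        )
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return replace(cfg, **doc)
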
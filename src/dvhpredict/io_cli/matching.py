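"""Structure-name matching: map free-text structure names to model classes."""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

from ..errors import MatchingError

logger = logging.getLogger(__name__)

__all__ = ["MatchTable", "match_structures", "default_match_table"]


@dataclass
class MatchTable:
    """Case-insensitive glob patterns per OAR class, plus target patterns."""

    target_patterns: list[str]
    oar_patterns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.target_patterns:
            raise MatchingError("match table needs at least one target pattern")
        for cls, pats in self.oar_patterns.items():
            if not pats:
                raise MatchingError(f"class {cls!r} has no patterns")


def default_match_table() -> MatchTable:
    return MatchTable(
        target_patterns=["ptv*", "target*"],
        oar_patterns={
            "heart": ["heart*", "cor"],
            "lung": ["lung", "lungs", "both lungs", "lung_total", "lung-total", "whole lung"],
            "lung_ptv": ["lung-ptv*", "lung_ptv*", "lungs-ptv*"],
            "cord": ["*cord*", "sc", "myelon*", "spinalcord*"],
        },
    )


def _matches(name: str, patterns: list[str]) -> bool:
    low = name.lower()
    return any(fnmatch.fnmatchcase(low, p.lower()) for p in patterns)


def match_structures(names: list[str], table: MatchTable) -> tuple[str, dict[str, str]]:
    """Assign roles to structure names.

    Returns ``(target_name, {structure name -> oar class})``.  Unmatched
    names are logged and excluded.  Raises :class:`MatchingError` unless
    exactly one name matches the target patterns.
    """
    targets = [n for n in names if _matches(n, table.target_patterns)]
    if len(targets) != 1:
        raise MatchingError(
            f"expected exactly one target match, got {len(targets)}: {sorted(targets)}"
        )
    assignment: dict[str, str] = {}
    unmatched = []
    for name in names:
        if name == targets[0]:
            continue
        for cls, pats in table.oar_patterns.items():
            if _matches(name, pats):
                assignment[name] = cls
                break
        else:
            unmatched.append(name)
    if unmatched:
        logger.info("structures excluded by match table: %s", sorted(unmatched))
    return targets[0], assignment
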
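"""Weighted threshold scoring of functional/basis combinations.

Each combination collects points in three categories:

* 9 scored properties (two hydroxyl bond lengths, the intramolecular
  hydrogen bond length, BDE at C3/C4, adiabatic EA and IP, PA at C3/C4),
* 2 computational-performance entries (normalized CPU time of the SCF and
  two-electron-integral program stages),
* 2 frontier-orbital entries (vertical IP/EA from Janak's theorem),

on a 0/1/2 scale: 2 points if the error magnitude is below 1% of the
reference magnitude (or, for timings, if the normalized time is below 1% of
the slowest combination's), 1 point below 5%, 0 otherwise.  Boundary values
fall to the less favourable tier since the tier inequalities are strict.
The total

    SCORE = 0.6 * sum(property points) + 0.3 * sum(performance points)
          + 0.1 * sum(Janak points)

is expressed as a percentage of its maximum (12.4 for the default 9+2+2
configuration).  Weights, tier thresholds and the property list are
configurable; the maximum is always derived from the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .constants import round_half_up

__all__ = [
    "DEFAULT_PROPERTIES",
    "PERFORMANCE_STAGES",
    "JANAK_ENTRIES",
    "ScoringConfig",
    "ScoreCard",
    "property_points",
    "performance_points",
    "janak_points",
    "total_score",
    "rank_combinations",
]

DEFAULT_PROPERTIES: tuple[str, ...] = (
    "r_oh_c3",
    "r_oh_c4",
    "r_hbond",
    "bde_c3",
    "bde_c4",
    "aea",
    "aip",
    "pa_c3",
    "pa_c4",
)
PERFORMANCE_STAGES: tuple[str, ...] = ("link502", "link703")
JANAK_ENTRIES: tuple[str, ...] = ("vip", "vea")


@dataclass(frozen=True)
class ScoringConfig:
    properties: tuple[str, ...] = DEFAULT_PROPERTIES
    performance_stages: tuple[str, ...] = PERFORMANCE_STAGES
    janak_entries: tuple[str, ...] = JANAK_ENTRIES
    weight_property: float = 0.6
    weight_performance: float = 0.3
    weight_janak: float = 0.1
    tier_fine: float = 0.01
    tier_coarse: float = 0.05

    @property
    def max_raw(self) -> float:
        """Maximum attainable weighted score for this configuration."""
        return 2.0 * (
            self.weight_property * len(self.properties)
            + self.weight_performance * len(self.performance_stages)
            + self.weight_janak * len(self.janak_entries)
        )


_DEFAULT_CONFIG = ScoringConfig()


def _tier(magnitude: float, scale: float, fine: float, coarse: float) -> int:
    # strict '<' on both tier bounds: exact boundaries drop to the lower tier
    if magnitude < fine * scale:
        return 2
    if magnitude < coarse * scale:
        return 1
    return 0


def property_points(xi: float, x_ref: float, config: ScoringConfig = _DEFAULT_CONFIG) -> int:
    """Points for a property error ``xi`` against reference ``x_ref``."""
    if x_ref == 0.0:
        raise ValueError("x_ref must be non-zero: relative tiers are undefined at zero")
    return _tier(abs(xi), abs(x_ref), config.tier_fine, config.tier_coarse)


def performance_points(t: float, t_max: float, config: ScoringConfig = _DEFAULT_CONFIG) -> int:
    """Points for a normalized stage time against the slowest combination's."""
    if t_max <= 0.0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    if t < 0.0:
        raise ValueError(f"normalized time must be non-negative, got {t}")
    return _tier(t, t_max, config.tier_fine, config.tier_coarse)


def janak_points(xi: float, x_ref: float, config: ScoringConfig = _DEFAULT_CONFIG) -> int:
    """Points for a vertical IP/EA error (same tiers as properties)."""
    return property_points(xi, x_ref, config)


@dataclass(frozen=True)
class ScoreCard:
    """Per-category points and the weighted percentage score of one combination."""

    combination: tuple[str, str]
    points_property: Mapping[str, int]
    points_performance: Mapping[str, int]
    points_janak: Mapping[str, int]
    raw_score: float
    percent: float
    config: ScoringConfig = field(default=_DEFAULT_CONFIG, compare=False)

    @property
    def display_percent(self) -> int:
        """Integer percentage, rounded half-up, as printed in score tables."""
        return int(round_half_up(self.percent, 0))


def total_score(
    combination: tuple[str, str],
    points_property: Mapping[str, int],
    points_performance: Mapping[str, int],
    points_janak: Mapping[str, int],
    config: ScoringConfig = _DEFAULT_CONFIG,
) -> ScoreCard:
    """Weighted score of one combination from its per-entry points.

    Every configured property, performance stage and Janak entry must be
    present; the percentage is normalized by the configuration's own maximum.
    """
    for label, expected, got in (
        ("property", config.properties, points_property),
        ("performance", config.performance_stages, points_performance),
        ("janak", config.janak_entries, points_janak),
    ):
        missing = [k for k in expected if k not in got]
        if missing:
            raise ValueError(f"missing {label} point entries: {', '.join(missing)}")

    raw = (
        config.weight_property * sum(points_property[p] for p in config.properties)
        + config.weight_performance * sum(points_performance[s] for s in config.performance_stages)
        + config.weight_janak * sum(points_janak[j] for j in config.janak_entries)
    )
    return ScoreCard(
        combination=combination,
        points_property=dict(points_property),
        points_performance=dict(points_performance),
        points_janak=dict(points_janak),
        raw_score=raw,
        percent=100.0 * raw / config.max_raw,
        config=config,
    )


def rank_combinations(cards: Sequence[ScoreCard]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score matrix (basis rows x functional columns) and a flat ranking.

    The flat ranking is sorted by percent descending; ties share a rank
    (competition style) and are ordered alphabetically within the tie.
    """
    if len(cards) == 0:
        raise ValueError("no score cards to rank")
    flat = pd.DataFrame(
        {
            "functional": [c.combination[0] for c in cards],
            "basis": [c.combination[1] for c in cards],
            "percent": [c.percent for c in cards],
            "display_percent": [c.display_percent for c in cards],
        }
    )
    flat = flat.sort_values(["functional", "basis"], kind="stable")
    flat["rank"] = flat["percent"].rank(method="min", ascending=False).astype(int)
    flat = flat.sort_values(["rank", "functional", "basis"], kind="stable").reset_index(drop=True)
    matrix = flat.pivot(index="basis", columns="functional", values="display_percent")
    return matrix, flat
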
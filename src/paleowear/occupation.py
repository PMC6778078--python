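"""Occupation-pattern inference per stratigraphic level.

Combines three lines of evidence, each per taxon within a level:

* the mortality-event duration zone (A/B/C) from scratch variability,
* the meso/micro dietary discrepancy flag,
* the pooled cementum season-of-death distribution,

into a deterministic rule cascade.  The cascade distinguishes events in
non-consecutive seasons, occupation spanning several seasons of the
annual cycle, and short (seasonal) occupation confined to a contiguous
seasonal window; with wear-only evidence a long-term pattern can never
be excluded, and the cascade says so explicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cementochronology import Season, CementumResult
from .data_model import CementumResultRow, Taxon
from .wear_seasonality import WearDiscrepancy, Zone, ZoneCall

#: annual cycle order used for window contiguity
SEASON_CYCLE = (Season.bad, Season.good_beginning, Season.good_middle, Season.good_end)

_WINDOW_NAMES = {
    Season.bad: ("bad season", "bad season"),
    Season.good_beginning: ("beginning of good season", "beginning of good season"),
    Season.good_middle: ("middle of good season", "first half of good season"),
    Season.good_end: ("end of good season", "end of good season"),
}


class OccupationLabel(str, enum.Enum):
    single_short_seasonal = "single_short_seasonal"
    repeated_short_same_season = "repeated_short_same_season"
    long_or_repeated_multi_season = "long_or_repeated_multi_season"
    non_consecutive_events = "non_consecutive_events"
    indeterminate = "indeterminate"


class Confidence(str, enum.Enum):
    wear_only = "wear_only"
    wear_plus_cementum = "wear_plus_cementum"


@dataclass
class SeasonDistribution:
    """Tally of season-of-death determinations for one assemblage."""

    counts: dict[Season, int]
    n_no_data: int = 0

    def __post_init__(self) -> None:
        self.counts = {s: int(self.counts.get(s, 0)) for s in SEASON_CYCLE}

    @property
    def n_determined(self) -> int:
        return sum(self.counts.values())

    @property
    def categories(self) -> frozenset[Season]:
        return frozenset(s for s, c in self.counts.items() if c > 0)


def pool_cementum_seasons(
    results: Iterable[CementumResult | CementumResultRow],
) -> SeasonDistribution:
    """Tally per-tooth season determinations into an assemblage distribution.

    Accepts either computed per-tooth results or published-style summary
    rows; indeterminate teeth count only toward ``n_no_data``.
    """

    counts: dict[Season, int] = {}
    no_data = 0
    for r in results:
        if isinstance(r, CementumResultRow):
            from .cementochronology import LABEL_TO_SEASON

            season = LABEL_TO_SEASON.get(r.season.lower(), Season.unknown)
        else:
            season = r.season
        if season is Season.unknown:
            no_data += 1
        else:
            counts[season] = counts.get(season, 0) + 1
    return SeasonDistribution(counts=counts, n_no_data=no_data)


@dataclass
class RuleFiring:
    rule: str
    detail: str


@dataclass
class OccupationPattern:
    level: str
    label: OccupationLabel
    season_window: str = ""
    evidence: list[RuleFiring] = field(default_factory=list)
    confidence: Confidence = Confidence.wear_only

    def summary(self) -> str:
        lines = [f"Level {self.level}: {self.label.value}"]
        if self.season_window:
            lines.append(f"  seasonal window: {self.season_window}")
        lines.append(f"  confidence: {self.confidence.value}")
        for f in self.evidence:
            lines.append(f"  - [{f.rule}] {f.detail}")
        return "\n".join(lines)


def _contiguous_window(categories: frozenset[Season]) -> tuple[Season, ...] | None:
    """Smallest contiguous seasonal window covering the categories, or None.

    Contiguity is linear in the cycle order bad -> beginning -> middle ->
    end; a wrap across the year boundary (end -> bad) is accepted only
    for two-category windows (a fall-to-winter span).  A three-category
    arc that wraps — deaths at both shoulders of the good season plus
    winter — is not a window: it covers most of the annual cycle.
    """

    if not categories:
        return None
    idx = sorted(SEASON_CYCLE.index(s) for s in categories)
    if idx[-1] - idx[0] == len(idx) - 1:  # linear run
        return tuple(SEASON_CYCLE[i] for i in range(idx[0], idx[-1] + 1))
    if categories == frozenset({Season.good_end, Season.bad}):
        return (Season.good_end, Season.bad)
    return None


def _window_text(window: Sequence[Season]) -> str:
    if len(window) == 1:
        return _WINDOW_NAMES[window[0]][0]
    start = _WINDOW_NAMES[window[0]][0]
    end = _WINDOW_NAMES[window[-1]][1]
    return f"{start} through {end}"


def infer_occupation(
    level: str,
    zone_calls: Mapping[Taxon | str, ZoneCall],
    discrepancies: Mapping[Taxon | str, WearDiscrepancy] | None = None,
    season_dists: Mapping[Taxon | str, SeasonDistribution] | None = None,
) -> OccupationPattern:
    """Deterministic rule cascade for one level.

    In priority order: any zone-C call means separate events in
    non-consecutive seasons; any zone-B call, or season-of-death
    categories that cannot form a contiguous seasonal window (per taxon
    or pooled), means occupation spanning several seasons of the annual
    cycle; all-zone-A with a contiguous window means short occupation(s)
    within that window; all-zone-A without cementum evidence means short
    occupation(s) in recurrently similar conditions, with the explicit
    caveat that a long-term pattern cannot be excluded.
    """

    discrepancies = discrepancies or {}
    season_dists = season_dists or {}
    evidence: list[RuleFiring] = []

    informative_dists = {t: d for t, d in season_dists.items() if d.n_determined >= 1}
    confidence = (
        Confidence.wear_plus_cementum if informative_dists else Confidence.wear_only
    )
    for taxon, disc in discrepancies.items():
        if disc.flag:
            evidence.append(RuleFiring("wear_discrepancy", f"{taxon}: {disc.description}"))

    if not zone_calls:
        evidence.append(RuleFiring("no_evidence", "no assemblage yielded a zone call"))
        return OccupationPattern(
            level=level,
            label=OccupationLabel.indeterminate,
            evidence=evidence,
            confidence=confidence,
        )

    zones = {t: c.zone for t, c in zone_calls.items()}
    for taxon, zone in zones.items():
        evidence.append(RuleFiring("zone", f"{taxon}: zone {zone.value}"))

    if any(z is Zone.C for z in zones.values()):
        evidence.append(
            RuleFiring(
                "nonconsecutive_rule",
                "a zone-C assemblage indicates >= 2 events in non-consecutive seasons",
            )
        )
        return OccupationPattern(
            level=level,
            label=OccupationLabel.non_consecutive_events,
            evidence=evidence,
            confidence=confidence,
        )

    multi_reasons: list[str] = []
    if any(z in (Zone.B, Zone.boundary_BC) for z in zones.values()):
        multi_reasons.append("a zone-B mortality event spans more than one season")
    pooled: frozenset[Season] = frozenset()
    for taxon, dist in informative_dists.items():
        pooled |= dist.categories
        if _contiguous_window(dist.categories) is None:
            multi_reasons.append(
                f"{taxon} deaths ({', '.join(s.value for s in sorted(dist.categories, key=SEASON_CYCLE.index))}) "
                "span the annual cycle"
            )
    if pooled and _contiguous_window(pooled) is None:
        multi_reasons.append("pooled deaths across taxa span the annual cycle")

    if multi_reasons:
        for r in multi_reasons:
            evidence.append(RuleFiring("multi_season_rule", r))
        return OccupationPattern(
            level=level,
            label=OccupationLabel.long_or_repeated_multi_season,
            evidence=evidence,
            confidence=confidence,
        )

    if pooled:
        window = _contiguous_window(pooled)
        assert window is not None
        text = _window_text(window)
        evidence.append(
            RuleFiring(
                "contiguous_window_rule",
                f"all zones A and deaths confined to a contiguous window: {text}",
            )
        )
        label = (
            OccupationLabel.single_short_seasonal
            if len(window) == 1
            else OccupationLabel.repeated_short_same_season
        )
        return OccupationPattern(
            level=level,
            label=label,
            season_window=text,
            evidence=evidence,
            confidence=confidence,
        )

    evidence.append(
        RuleFiring(
            "wear_only_rule",
            "all zones A without cementum evidence: short occupation(s) in "
            "recurrently similar seasons; a long-term pattern cannot be excluded",
        )
    )
    return OccupationPattern(
        level=level,
        label=OccupationLabel.repeated_short_same_season,
        season_window="",
        evidence=evidence,
        confidence=Confidence.wear_only,
    )
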
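"""Cementum increment analysis: age and season of death.

Acellular extrinsic fibre cementum grows in annual couplets: a wide,
fast-growing translucid band (TB) laid down during the favourable
("good") season and a thin, hyper-mineralized opaque band (OB, the
annulus) laid down during the unfavourable ("bad") season.  Counting
complete TB+OB pairs and typing the outermost increment therefore gives
age at death (pairs + pre-eruption age) and season of death; when the
animal died during the good season the outermost band is an incomplete
TB whose growth ratio against the mean complete-TB thickness (%Dev)
places the death at the beginning, middle or end of the good season.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_model import eruption_ages_path, parse_tooth_code


class BandType(str, enum.Enum):
    TB = "TB"
    OB = "OB"


class Season(str, enum.Enum):
    bad = "bad"
    good_beginning = "good_beginning"
    good_middle = "good_middle"
    good_end = "good_end"
    unknown = "unknown"


#: printed season labels <-> season categories
SEASON_LABELS = {
    Season.bad: "Bad Season",
    Season.good_beginning: "Beginning Good Season",
    Season.good_middle: "Middle Good Season",
    Season.good_end: "End Good Season",
    Season.unknown: "No data",
}
LABEL_TO_SEASON = {v.lower(): k for k, v in SEASON_LABELS.items()}

#: %Dev category bounds within the good season, applied after rounding
#: %Dev to one decimal (half-up): beginning 1-33.3, middle 33.4-66.6,
#: end 66.7-100.
PCT_DEV_MIDDLE_FROM = 33.4
PCT_DEV_END_FROM = 66.7


@dataclass(frozen=True)
class CementumIncrement:
    index: int  # innermost = 1
    band_type: BandType
    thickness: float  # micrometres
    complete: bool = True

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("increment thickness must be > 0 um")


@dataclass
class CementumSeries:
    """Ordered increment sequence for one tooth (innermost first)."""

    specimen_id: str
    increments: Sequence[CementumIncrement] = ()
    readable: bool = True
    tooth_code: str = ""

    def __post_init__(self) -> None:
        if not self.readable and self.increments:
            raise ValueError("an unreadable series carries no increments")
        for inc in self.increments[:-1]:
            if not inc.complete:
                raise ValueError("only the outermost increment may be incomplete")

    def validate_alternation(self) -> None:
        for prev, cur in zip(self.increments, self.increments[1:]):
            if prev.band_type is cur.band_type:
                raise ValueError(
                    f"{self.specimen_id}: non-alternating band sequence at "
                    f"increment {cur.index} ({cur.band_type.value} follows "
                    f"{prev.band_type.value})"
                )


@dataclass
class AgeEstimate:
    """Age at death in years, as a point value or a half-open interval.

    A trailing incomplete TB adds a partial year of unknown fraction, so
    the estimate widens to [low, high).
    """

    low: float
    high: float

    @property
    def is_interval(self) -> bool:
        return self.high > self.low

    def __str__(self) -> str:
        if self.is_interval:
            return f"[{self.low:g}, {self.high:g})"
        return f"{self.low:g}"


@dataclass
class CementumResult:
    specimen_id: str
    readable: bool
    n_pairs: int | None
    trailing_incomplete_tb: bool
    last_band: BandType | None
    pct_dev: float | None
    pct_dev_exceeds_reference: bool
    season: Season
    age: AgeEstimate | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_cb_text(self) -> str:
        """Printed-style band count, e.g. ``5 (+TB)``."""
        if self.n_pairs is None:
            return ""
        text = str(self.n_pairs)
        if self.trailing_incomplete_tb:
            text += " (+TB)"
        return text


def count_increment_pairs(series: CementumSeries) -> tuple[int | None, bool]:
    """Count complete TB+OB couplets; flag a trailing incomplete TB.

    A trailing incomplete TB (death during the good season) is never
    counted as a pair.  An unreadable series returns ``(None, False)``.
    Raises on a non-alternating band sequence.
    """

    if not series.readable or not series.increments:
        return None, False
    series.validate_alternation()
    incs = list(series.increments)
    trailing_tb = incs[-1].band_type is BandType.TB and not incs[-1].complete
    pairs = 0
    i = 0
    while i < len(incs) - 1:
        if (
            incs[i].band_type is BandType.TB
            and incs[i].complete
            and incs[i + 1].band_type is BandType.OB
            and incs[i + 1].complete
        ):
            pairs += 1
            i += 2
        else:
            i += 1
    return pairs, trailing_tb


def compute_pct_dev(series: CementumSeries) -> tuple[float, bool]:
    """Growth ratio of the final incomplete TB (%Dev).

    100 x (last TB thickness) / (mean thickness of the complete TBs).
    Raw values above 100 — the final year's band outgrowing the average
    of the older ones — are clamped to 100 and flagged rather than
    rejected, since annual thickness varies.  Only complete TBs enter
    the reference mean: opaque bands are too thin to measure reliably.
    """

    if not series.increments:
        raise ValueError("empty series")
    last = series.increments[-1]
    if last.band_type is not BandType.TB or last.complete:
        raise ValueError(
            "%Dev is defined only for a trailing incomplete TB; for an OB last "
            "band use season_of_death directly"
        )
    reference = [
        inc.thickness
        for inc in series.increments[:-1]
        if inc.band_type is BandType.TB and inc.complete
    ]
    if not reference:
        raise ValueError("no complete TB to serve as growth reference")
    raw = 100.0 * last.thickness / (sum(reference) / len(reference))
    if raw > 100.0:
        return 100.0, True
    return raw, False


def season_of_death(last_band: BandType | str | None, pct_dev: float | None) -> Season:
    """Season category from the outermost band and its growth ratio.

    An opaque last band means death in the bad season.  A translucid
    last band is placed within the good season by %Dev (rounded to one
    decimal, half-up): beginning up to 33.3, middle 33.4-66.6, end from
    66.7.  A TB without a measurable %Dev is indeterminate.
    """

    from .pipeline import round_half_up

    if last_band is None or last_band == "":
        return Season.unknown
    band = BandType(last_band)
    if band is BandType.OB:
        return Season.bad
    if pct_dev is None:
        return Season.unknown
    v = round_half_up(float(pct_dev), 1)
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"%Dev {pct_dev} outside [0, 100]")
    if v < PCT_DEV_MIDDLE_FROM:
        return Season.good_beginning
    if v < PCT_DEV_END_FROM:
        return Season.good_middle
    return Season.good_end


def load_eruption_ages(path: str | Path | None = None) -> dict[tuple[str, str], float]:
    """Taxon x tooth-position pre-eruption ages (years), from config CSV."""

    df = pd.read_csv(path if path is not None else eruption_ages_path())
    return {(str(r.taxon), str(r.tooth)): float(r.age_years) for r in df.itertuples()}


def estimate_age(
    n_pairs: int,
    trailing_tb: bool,
    tooth_code: str,
    taxon: str,
    eruption_table: dict[tuple[str, str], float] | None = None,
) -> AgeEstimate:
    """Age at death: band pairs plus the tooth's pre-eruption age.

    A trailing incomplete TB adds a partial final year, reported as the
    half-open interval [e + pairs, e + pairs + 1).
    """

    table = eruption_table if eruption_table is not None else load_eruption_ages()
    position = parse_tooth_code(tooth_code).position
    try:
        eruption = table[(str(taxon), position)]
    except KeyError:
        raise ValueError(
            f"no eruption age for taxon {taxon!r}, tooth {position!r}"
        ) from None
    low = eruption + n_pairs
    return AgeEstimate(low=low, high=low + 1.0 if trailing_tb else low)


def analyze_series(
    series: CementumSeries,
    taxon: str | None = None,
    eruption_table: dict[tuple[str, str], float] | None = None,
) -> CementumResult:
    """Full per-tooth cementum workup: pairs, last band, %Dev, season, age."""

    n_pairs, trailing_tb = count_increment_pairs(series)
    if n_pairs is None:
        return CementumResult(
            specimen_id=series.specimen_id,
            readable=False,
            n_pairs=None,
            trailing_incomplete_tb=False,
            last_band=None,
            pct_dev=None,
            pct_dev_exceeds_reference=False,
            season=Season.unknown,
            notes=["unreadable series"],
        )
    last_band = series.increments[-1].band_type
    pct_dev = None
    exceeds = False
    notes: list[str] = []
    if trailing_tb:
        try:
            pct_dev, exceeds = compute_pct_dev(series)
            if exceeds:
                notes.append("%Dev exceeds the complete-TB reference; clamped to 100")
        except ValueError as err:
            notes.append(str(err))
    season = season_of_death(last_band, pct_dev)
    age = None
    if taxon is not None:
        try:
            age = estimate_age(n_pairs, trailing_tb, series.tooth_code, taxon, eruption_table)
        except ValueError as err:
            notes.append(str(err))
    return CementumResult(
        specimen_id=series.specimen_id,
        readable=True,
        n_pairs=n_pairs,
        trailing_incomplete_tb=trailing_tb,
        last_band=last_band,
        pct_dev=pct_dev,
        pct_dev_exceeds_reference=exceeds,
        season=season,
        age=age,
        notes=notes,
    )


_N_CB_RE = re.compile(
    r"^(?:(?P<lead>OB)\s*\+\s*)?(?P<pairs>\d+)(?P<tb>\s*\(\+TB\))?(?P<atleast>\s*\(at least\))?$"
)


@dataclass(frozen=True)
class BandCountText:
    """Parsed printed band-count cell, e.g. ``OB + 3 (+TB)``."""

    n_pairs: int
    leading_ob: bool
    trailing_tb: bool
    at_least: bool


def parse_n_cb(text: str) -> BandCountText | None:
    """Parse a printed band-count cell; empty / dash cells return None."""

    t = text.strip().replace("—", "").replace("-", "")
    if not text.strip() or not t:
        return None
    m = _N_CB_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable band-count text {text!r}")
    return BandCountText(
        n_pairs=int(m.group("pairs")),
        leading_ob=m.group("lead") is not None,
        trailing_tb=m.group("tb") is not None,
        at_least=m.group("atleast") is not None,
    )
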
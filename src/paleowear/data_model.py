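"""Domain types, CSV schemas and screening filters.

The package operates on per-specimen tabular records grouped into
*assemblages* — all teeth of one taxon from one stratigraphic level.
Every downstream statistic (mesowear score, scratch/pit summary,
cementum season tally) is computed per assemblage.

CSV dialect for every table kind: comma-separated, UTF-8, ``.`` decimal
separator, missing values written as the empty string.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Taxon(str, enum.Enum):
    cervus = "cervus"
    equus = "equus"
    bos_bison = "bos_bison"
    other = "other"


class WearStage(str, enum.Enum):
    unworn = "unworn"
    adult_worn = "adult_worn"
    senescent = "senescent"


class TaphonomyFlag(str, enum.Enum):
    digested = "digested"
    abraded = "abraded"
    eroded = "eroded"
    cracked = "cracked"
    concretion = "concretion"
    manganese = "manganese"
    weathered = "weathered"
    recrystallized = "recrystallized"
    technical_defect = "technical_defect"


class DietMain(str, enum.Enum):
    browser = "browser"
    mixed = "mixed"
    grazer = "grazer"


class DietQualifier(str, enum.Enum):
    none = "none"
    browse_dominated = "browse_dominated"
    grass_dominated = "grass_dominated"


_TOOTH_RE = re.compile(r"^([mM][123])(?:\s*([LR]))?$")

#: canonical screening order: wear stage is checked before taphonomy flags
_FLAG_ORDER = list(TaphonomyFlag)


class SchemaError(ValueError):
    """A table does not match the declared schema (missing/renamed column)."""


class RowError(ValueError):
    """A row holds an unparseable value; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class ToothCode:
    """Parsed tooth position, e.g. ``m2 L`` -> (m2, L).

    Lower-case ``m`` is a lower molar, upper-case ``M`` an upper molar;
    the side letter is optional.
    """

    position: str  # m1..m3 / M1..M3
    side: str  # "L", "R" or "unknown"

    def __str__(self) -> str:  # round-trips through parse_tooth_code
        return self.position if self.side == "unknown" else f"{self.position} {self.side}"


def parse_tooth_code(text: str) -> ToothCode:
    m = _TOOTH_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable tooth code {text!r} (expected e.g. 'm2 L', 'M1')")
    return ToothCode(position=m.group(1), side=m.group(2) or "unknown")


@dataclass(frozen=True)
class AssemblageKey:
    """Grouping unit for every summary: one taxon within one level."""

    taxon: Taxon
    level: str


@dataclass
class SpecimenRecord:
    specimen_id: str
    taxon: Taxon
    level: str
    tooth_code: str
    wear_stage: WearStage
    taphonomy_flags: frozenset[TaphonomyFlag] = frozenset()
    extra: dict = field(default_factory=dict)

    @property
    def tooth(self) -> ToothCode:
        return parse_tooth_code(self.tooth_code)

    @property
    def key(self) -> AssemblageKey:
        return AssemblageKey(self.taxon, self.level)


@dataclass
class MesowearSummary:
    """Assemblage mesowear: mean stage (0-6) and sample SD (n-1 denominator)."""

    n: int
    mws_mean: float
    mws_sd: float | None  # None when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("mesowear summary requires n >= 1")
        if not 0.0 <= self.mws_mean <= 6.0:
            raise ValueError(f"mws_mean {self.mws_mean} outside the 0-6 stage scale")
        if self.mws_sd is not None and self.mws_sd < 0:
            raise ValueError("mws_sd must be >= 0")


@dataclass
class MicrowearSummary:
    """Assemblage scratch/pit statistics on the 0.16 mm^2 counting field.

    ``ns_cv_star``/``np_cv_star`` carry the small-sample corrected
    coefficient of variation; SD/CV fields are None when n < 2.
    Percentages (``lsr_pct``, ``pct_*``) are fractions of teeth, 0-100.
    """

    n: int
    ns_mean: float
    ns_sd: float | None
    ns_cv: float | None
    ns_cv_star: float | None
    np_mean: float
    np_sd: float | None
    np_cv_star: float | None
    lsr_pct: float
    pct_lp: float
    pct_g: float
    pct_xs: float
    pct_ch: float
    sws_mean: float

    def __post_init__(self) -> None:
        for name in ("lsr_pct", "pct_lp", "pct_g", "pct_xs", "pct_ch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not 0.0 <= self.sws_mean <= 4.0:
            raise ValueError("sws_mean outside the 0-4 texture scale")


@dataclass(frozen=True)
class DietClass:
    """Dietary classification with optional mixed-feeder dominance qualifier.

    ``boundary_flag`` marks values falling in a gap or overlap between the
    published diagnostic ranges; the qualifier then records which side of
    the boundary the value leans to.
    """

    main: DietMain
    qualifier: DietQualifier = DietQualifier.none
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if (
            self.qualifier is not DietQualifier.none
            and self.main is not DietMain.mixed
            and not self.boundary_flag
        ):
            raise ValueError("qualifier only applies to mixed feeders or boundary calls")

    def __str__(self) -> str:
        label = self.main.value
        if self.qualifier is not DietQualifier.none:
            label = f"{self.qualifier.value.replace('_', '-')} {label}"
        if self.boundary_flag:
            label = f"boundary ({label} side)"
        return label


# ---------------------------------------------------------------------------
# CSV schemas

TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "specimens": ("specimen_id", "taxon", "level", "tooth_code", "wear_stage", "flags"),
    "mesowear_obs": ("specimen_id", "cusp_relief", "cusp_shape"),
    "microwear_obs": (
        "specimen_id",
        "field_index",
        "n_scratches",
        "n_pits",
        "texture_score",
        "large_pits",
        "gouges",
        "cross_scratches",
        "coarse_scratches",
    ),
    "cementum_series": ("specimen_id", "increment_index", "band_type", "thickness_um", "complete"),
    "assemblage_summary": (
        "taxon",
        "level",
        "meso_n",
        "mws",
        "mws_sd",
        "micro_n",
        "lsr",
        "ns",
        "ns_cv_star",
        "ns_sd",
        "np",
        "np_cv_star",
        "np_sd",
        "pct_lp",
        "pct_g",
        "pct_xs",
        "pct_ch",
        "sws",
    ),
    "cementum_results": ("taxon", "level", "specimen_id", "tooth_code", "n_cb", "lcb", "pct_dev", "season"),
}

_BOOL_TRUE = {"1", "true", "yes", "y"}
_BOOL_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(text: str, row: int, column: str) -> bool:
    t = str(text).strip().lower()
    if t in _BOOL_TRUE:
        return True
    if t in _BOOL_FALSE:
        return False
    raise RowError(row, f"unparseable boolean {text!r} in column '{column}'")


def _parse_enum(cls, text: str, row: int, column: str):
    try:
        return cls(str(text).strip())
    except ValueError:
        valid = ", ".join(e.value for e in cls)
        raise RowError(row, f"invalid {column} {text!r} (expected one of: {valid})") from None


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == "") or pd.isna(value):
        return None
    return float(value)


def _read_csv(path: str | Path, table_kind: str) -> pd.DataFrame:
    if table_kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_SCHEMAS[table_kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing} for table kind '{table_kind}'"
        )
    return df


def read_specimen_table(path: str | Path, table_kind: str) -> list:
    """Read and validate one CSV table; returns typed records.

    Unknown columns are preserved in each record's ``extra`` mapping
    (or as plain keys on the row dataclass for summary kinds); row
    numbers are 1-based over data rows and appear in every row-level
    error message.
    """

    df = _read_csv(path, table_kind)
    known = set(TABLE_SCHEMAS[table_kind])
    records: list = []
    for i, raw in enumerate(df.to_dict(orient="records"), start=1):
        extra = {k: v for k, v in raw.items() if k not in known}
        records.append(_parse_row(table_kind, raw, i, extra))
    if table_kind == "specimens":
        seen: dict[str, int] = {}
        for i, rec in enumerate(records, start=1):
            if rec.specimen_id in seen:
                raise RowError(i, f"duplicate specimen_id {rec.specimen_id!r}")
            seen[rec.specimen_id] = i
    return records


def _parse_row(table_kind: str, raw: dict, row: int, extra: dict):
    if table_kind == "specimens":
        flags = frozenset(
            _parse_enum(TaphonomyFlag, f, row, "flags")
            for f in str(raw["flags"]).split(";")
            if f.strip()
        )
        rec = SpecimenRecord(
            specimen_id=raw["specimen_id"],
            taxon=_parse_enum(Taxon, raw["taxon"], row, "taxon"),
            level=str(raw["level"]),
            tooth_code=raw["tooth_code"],
            wear_stage=_parse_enum(WearStage, raw["wear_stage"], row, "wear_stage"),
            taphonomy_flags=flags,
            extra=extra,
        )
        try:
            rec.tooth
        except ValueError as exc:
            raise RowError(row, str(exc)) from None
        return rec
    if table_kind == "mesowear_obs":
        from .mesowear import CuspRelief, CuspShape, MesowearObservation

        return MesowearObservation(
            specimen_id=raw["specimen_id"],
            cusp_relief=_parse_enum(CuspRelief, raw["cusp_relief"], row, "cusp_relief"),
            cusp_shape=_parse_enum(CuspShape, raw["cusp_shape"], row, "cusp_shape"),
        )
    if table_kind == "microwear_obs":
        from .microwear import MicrowearObservation

        try:
            obs = MicrowearObservation(
                specimen_id=raw["specimen_id"],
                field_index=int(raw["field_index"]),
                n_scratches=float(raw["n_scratches"]),
                n_pits=float(raw["n_pits"]),
                texture_score=int(raw["texture_score"]),
                large_pits=_parse_bool(raw["large_pits"], row, "large_pits"),
                gouges=_parse_bool(raw["gouges"], row, "gouges"),
                cross_scratches=_parse_bool(raw["cross_scratches"], row, "cross_scratches"),
                coarse_scratches=_parse_bool(raw["coarse_scratches"], row, "coarse_scratches"),
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(row, str(exc)) from None
        return obs
    if table_kind == "cementum_series":
        from .cementochronology import BandType, CementumIncrement

        try:
            return _CementumSeriesRow(
                specimen_id=raw["specimen_id"],
                increment=CementumIncrement(
                    index=int(raw["increment_index"]),
                    band_type=_parse_enum(BandType, raw["band_type"], row, "band_type"),
                    thickness=float(raw["thickness_um"]),
                    complete=_parse_bool(raw["complete"], row, "complete"),
                ),
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(row, str(exc)) from None
    if table_kind == "assemblage_summary":
        return AssemblageSummaryRow(
            taxon=_parse_enum(Taxon, raw["taxon"], row, "taxon"),
            level=str(raw["level"]),
            meso_n=int(raw["meso_n"]) if str(raw["meso_n"]).strip() else None,
            mws=_opt_float(raw["mws"]),
            mws_sd=_opt_float(raw["mws_sd"]),
            micro_n=int(raw["micro_n"]) if str(raw["micro_n"]).strip() else None,
            lsr=_opt_float(raw["lsr"]),
            ns=_opt_float(raw["ns"]),
            ns_cv_star=_opt_float(raw["ns_cv_star"]),
            ns_sd=_opt_float(raw["ns_sd"]),
            np=_opt_float(raw["np"]),
            np_cv_star=_opt_float(raw["np_cv_star"]),
            np_sd=_opt_float(raw["np_sd"]),
            pct_lp=_opt_float(raw["pct_lp"]),
            pct_g=_opt_float(raw["pct_g"]),
            pct_xs=_opt_float(raw["pct_xs"]),
            pct_ch=_opt_float(raw["pct_ch"]),
            sws=_opt_float(raw["sws"]),
            extra=extra,
        )
    if table_kind == "cementum_results":
        return CementumResultRow(
            taxon=_parse_enum(Taxon, raw["taxon"], row, "taxon"),
            level=str(raw["level"]),
            specimen_id=raw["specimen_id"],
            tooth_code=raw["tooth_code"],
            n_cb=str(raw["n_cb"]).strip(),
            lcb=str(raw["lcb"]).strip(),
            pct_dev=_opt_float(raw["pct_dev"]),
            season=str(raw["season"]).strip(),
            extra=extra,
        )
    raise AssertionError(table_kind)


@dataclass
class _CementumSeriesRow:
    specimen_id: str
    increment: "object"


@dataclass
class AssemblageSummaryRow:
    """One published-style summary row: taxon x level wear statistics."""

    taxon: Taxon
    level: str
    meso_n: int | None
    mws: float | None
    mws_sd: float | None
    micro_n: int | None
    lsr: float | None
    ns: float | None
    ns_cv_star: float | None
    ns_sd: float | None
    np: float | None
    np_cv_star: float | None
    np_sd: float | None
    pct_lp: float | None
    pct_g: float | None
    pct_xs: float | None
    pct_ch: float | None
    sws: float | None
    extra: dict = field(default_factory=dict)

    @property
    def key(self) -> AssemblageKey:
        return AssemblageKey(self.taxon, self.level)


@dataclass
class CementumResultRow:
    """One cementum determination: band count, last-band type, growth ratio."""

    taxon: Taxon
    level: str
    specimen_id: str
    tooth_code: str
    n_cb: str  # as-printed text, e.g. "5 (+TB)" or "OB + 3 (+TB)"
    lcb: str  # "TB", "OB" or ""
    pct_dev: float | None
    season: str  # printed label, e.g. "Bad Season", "No data"
    extra: dict = field(default_factory=dict)

    @property
    def determined(self) -> bool:
        return self.season not in ("", "No data")

    @property
    def key(self) -> AssemblageKey:
        return AssemblageKey(self.taxon, self.level)


# ---------------------------------------------------------------------------
# Writers


def _fmt(value, decimals: int = 2) -> str:
    """Fixed-decimal text for round-trip-stable numeric CSV cells."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        from .pipeline import round_half_up

        if float(value).is_integer():
            return str(int(value))
        return f"{round_half_up(value, decimals):.{decimals}f}"
    return str(value)


def write_table(records: Sequence, path: str | Path, table_kind: str) -> None:
    """Write typed records back to CSV in the declared schema."""

    cols = TABLE_SCHEMAS[table_kind]
    rows = []
    for rec in records:
        if table_kind == "specimens":
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "taxon": rec.taxon.value,
                    "level": rec.level,
                    "tooth_code": rec.tooth_code,
                    "wear_stage": rec.wear_stage.value,
                    "flags": ";".join(sorted(f.value for f in rec.taphonomy_flags)),
                }
            )
        elif table_kind == "mesowear_obs":
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "cusp_relief": rec.cusp_relief.value,
                    "cusp_shape": rec.cusp_shape.value,
                }
            )
        elif table_kind == "microwear_obs":
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "field_index": rec.field_index,
                    "n_scratches": _fmt(rec.n_scratches),
                    "n_pits": _fmt(rec.n_pits),
                    "texture_score": rec.texture_score,
                    "large_pits": _fmt(rec.large_pits),
                    "gouges": _fmt(rec.gouges),
                    "cross_scratches": _fmt(rec.cross_scratches),
                    "coarse_scratches": _fmt(rec.coarse_scratches),
                }
            )
        elif table_kind == "cementum_series":
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "increment_index": rec.increment.index,
                    "band_type": rec.increment.band_type.value,
                    "thickness_um": _fmt(rec.increment.thickness, 4),
                    "complete": _fmt(rec.increment.complete),
                }
            )
        elif table_kind == "assemblage_summary":
            rows.append(
                {
                    "taxon": rec.taxon.value,
                    "level": rec.level,
                    "meso_n": _fmt(rec.meso_n),
                    "mws": _fmt(rec.mws),
                    "mws_sd": _fmt(rec.mws_sd),
                    "micro_n": _fmt(rec.micro_n),
                    "lsr": _fmt(rec.lsr),
                    "ns": _fmt(rec.ns),
                    "ns_cv_star": _fmt(rec.ns_cv_star),
                    "ns_sd": _fmt(rec.ns_sd),
                    "np": _fmt(rec.np),
                    "np_cv_star": _fmt(rec.np_cv_star),
                    "np_sd": _fmt(rec.np_sd),
                    "pct_lp": _fmt(rec.pct_lp),
                    "pct_g": _fmt(rec.pct_g),
                    "pct_xs": _fmt(rec.pct_xs),
                    "pct_ch": _fmt(rec.pct_ch),
                    "sws": _fmt(rec.sws),
                }
            )
        elif table_kind == "cementum_results":
            rows.append(
                {
                    "taxon": rec.taxon.value,
                    "level": rec.level,
                    "specimen_id": rec.specimen_id,
                    "tooth_code": rec.tooth_code,
                    "n_cb": rec.n_cb,
                    "lcb": rec.lcb,
                    "pct_dev": _fmt(rec.pct_dev),
                    "season": rec.season,
                }
            )
        else:
            raise ValueError(f"unknown table kind {table_kind!r}")
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Screening


@dataclass(frozen=True)
class Exclusion:
    record: SpecimenRecord
    reason: str


def screen_wear_preservation(
    records: Iterable[SpecimenRecord],
) -> tuple[list[SpecimenRecord], list[Exclusion]]:
    """Apply the wear-stage and taphonomy screen.

    Only adult, worn teeth free of post-mortem alteration enter the wear
    analyses: unworn teeth carry no facets yet and senescent teeth are
    over-worn, while digestion, abrasion, erosion etc. obliterate the
    microwear signal.  Each exclusion carries the first triggering
    reason; the wear-stage check runs before the taphonomy flags.
    """

    kept: list[SpecimenRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if rec.wear_stage is not WearStage.adult_worn:
            excluded.append(Exclusion(rec, rec.wear_stage.value))
            continue
        bad = [f for f in _FLAG_ORDER if f in rec.taphonomy_flags]
        if bad:
            excluded.append(Exclusion(rec, bad[0].value))
            continue
        kept.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(*parts: str) -> Path:
    return Path(resources.files("paleowear").joinpath("data", *parts))


def load_table1_assemblages() -> list[AssemblageSummaryRow]:
    """Published-style per-assemblage wear summary table (15 taxon x level rows)."""
    return read_specimen_table(_data_path("fixtures", "table1_assemblages.csv"), "assemblage_summary")


def load_table2_cementum() -> list[CementumResultRow]:
    """Published-style cementum determinations (21 sampled teeth)."""
    return read_specimen_table(_data_path("fixtures", "table2_cementum.csv"), "cementum_results")


def eruption_ages_path() -> Path:
    return _data_path("config", "eruption_ages.csv")


def reference_microwear_path() -> Path:
    return _data_path("references", "extant_microwear_synthetic.csv")
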
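"""End-to-end orchestration: tables in, occupation report out.

Two entry granularities share one classification path:

* **raw** mode starts from per-tooth observation tables (specimens,
  mesowear cusps, microwear counting fields, cementum increments),
  screens and summarizes them;
* **summary** mode starts from already-summarized assemblage statistics
  and cementum determinations, as published summary tables survive.

Presentation rounding (2 decimals, half-up) is applied only in the
writers; all computation runs at full precision.
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from . import data_model as dm
from .cementochronology import (
    CementumSeries,
    analyze_series,
    load_eruption_ages,
    SEASON_LABELS,
)
from .data_model import (
    AssemblageKey,
    AssemblageSummaryRow,
    CementumResultRow,
    DietClass,
    Taxon,
)
from .mesowear import classify_diet_mws, specimen_stage, summarize_mws, DEFAULT_MWS_CUTPOINTS
from .microwear import (
    classify_diet_lsr,
    summarize_microwear,
    tooth_microwear_counts,
    DEFAULT_MIXED_MIDPOINT,
)
from .occupation import SeasonDistribution, infer_occupation, pool_cementum_seasons
from .wear_seasonality import (
    BoundaryModel,
    WearDiscrepancy,
    ZoneCall,
    default_boundary_model,
    detect_wear_discrepancy,
    DEFAULT_TAU,
)

logger = logging.getLogger("paleowear")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up, matching printed-table conventions."""

    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP))


_KNOWN_KEYS = {
    "mode",
    "specimens",
    "mesowear_obs",
    "microwear_obs",
    "cementum_series",
    "assemblage_summary",
    "cementum_results",
    "out_dir",
    "seed",
    "log_level",
    "mesowear_cutpoints",
    "cusp_rule",
    "mixed_midpoint",
    "zone_tau",
    "boundary_model",
    "eruption_ages",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str = "raw"
    specimens: str | None = None
    mesowear_obs: str | None = None
    microwear_obs: str | None = None
    cementum_series: str | None = None
    assemblage_summary: str | None = None
    cementum_results: str | None = None
    out_dir: str = "paleowear_out"
    seed: int = 0
    log_level: str = "INFO"
    mesowear_cutpoints: tuple[float, float, float] = DEFAULT_MWS_CUTPOINTS
    cusp_rule: str = "sharpest"
    mixed_midpoint: float = DEFAULT_MIXED_MIDPOINT
    zone_tau: float = DEFAULT_TAU
    boundary_model: str | None = None  # path to a serialized BoundaryModel
    eruption_ages: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "summary"):
            raise ValueError(f"mode must be 'raw' or 'summary', got {self.mode!r}")
        if self.mode == "raw":
            if not any((self.specimens, self.mesowear_obs, self.microwear_obs, self.cementum_series)):
                raise ValueError("raw mode needs at least one observation table")
        else:
            if not any((self.assemblage_summary, self.cementum_results)):
                raise ValueError("summary mode needs at least one summary table")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        unknown = set(payload) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**payload)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError("configuration file must hold a mapping")
        return cls.from_dict(payload)


@dataclass
class AssemblageAnalysis:
    """Per-assemblage classification bundle."""

    key: AssemblageKey
    summary: AssemblageSummaryRow
    diet_meso: DietClass | None = None
    diet_micro: DietClass | None = None
    discrepancy: WearDiscrepancy | None = None
    zone: ZoneCall | None = None


def analyze_summary_rows(
    rows: list[AssemblageSummaryRow],
    model: BoundaryModel | None = None,
    cutpoints=DEFAULT_MWS_CUTPOINTS,
    mixed_midpoint: float = DEFAULT_MIXED_MIDPOINT,
    tau: float = DEFAULT_TAU,
) -> dict[AssemblageKey, AssemblageAnalysis]:
    """Classify diets, discrepancy and event-duration zone per assemblage."""

    model = model if model is not None else default_boundary_model()
    out: dict[AssemblageKey, AssemblageAnalysis] = {}
    for row in rows:
        a = AssemblageAnalysis(key=row.key, summary=row)
        if row.mws is not None:
            a.diet_meso = classify_diet_mws(row.mws, cutpoints)
        if row.lsr is not None:
            a.diet_micro = classify_diet_lsr(row.lsr, mixed_midpoint)
        if a.diet_meso is not None and a.diet_micro is not None:
            a.discrepancy = detect_wear_discrepancy(a.diet_meso, a.diet_micro)
        if row.ns_cv_star is not None and row.ns_sd is not None and (row.micro_n or 0) >= 2:
            a.zone = model.classify(row.ns_cv_star, row.ns_sd, tau=tau)
        out[row.key] = a
    return out


def summarize_observations(
    specimens: list[dm.SpecimenRecord],
    meso_obs: list,
    micro_obs: list,
    cusp_rule: str = "sharpest",
) -> tuple[list[AssemblageSummaryRow], list[dm.Exclusion]]:
    """Screen specimens and build per-assemblage summary rows from raw counts."""

    kept, excluded = dm.screen_wear_preservation(specimens)
    for ex in excluded:
        logger.info("excluded %s: %s", ex.record.specimen_id, ex.reason)
    kept_ids = {r.specimen_id for r in kept}
    by_specimen_meso = defaultdict(list)
    for o in meso_obs:
        if o.specimen_id in kept_ids:
            by_specimen_meso[o.specimen_id].append(o)
    by_specimen_micro = defaultdict(list)
    for o in micro_obs:
        if o.specimen_id in kept_ids:
            by_specimen_micro[o.specimen_id].append(o)

    spec_by_id = {r.specimen_id: r for r in kept}
    stages_by_key: dict[AssemblageKey, list[float]] = defaultdict(list)
    for sid, obs in by_specimen_meso.items():
        stages_by_key[spec_by_id[sid].key].append(specimen_stage(obs, cusp_rule))
    teeth_by_key = defaultdict(list)
    for sid, obs in by_specimen_micro.items():
        teeth_by_key[spec_by_id[sid].key].append(tooth_microwear_counts(obs))

    rows: list[AssemblageSummaryRow] = []
    for key in sorted(set(stages_by_key) | set(teeth_by_key), key=lambda k: (k.level, k.taxon.value)):
        meso = summarize_mws(stages_by_key[key]) if stages_by_key.get(key) else None
        micro = summarize_microwear(teeth_by_key[key]) if teeth_by_key.get(key) else None
        rows.append(
            AssemblageSummaryRow(
                taxon=key.taxon,
                level=key.level,
                meso_n=meso.n if meso else None,
                mws=meso.mws_mean if meso else None,
                mws_sd=meso.mws_sd if meso else None,
                micro_n=micro.n if micro else None,
                lsr=micro.lsr_pct if micro else None,
                ns=micro.ns_mean if micro else None,
                ns_cv_star=micro.ns_cv_star if micro else None,
                ns_sd=micro.ns_sd if micro else None,
                np=micro.np_mean if micro else None,
                np_cv_star=micro.np_cv_star if micro else None,
                np_sd=micro.np_sd if micro else None,
                pct_lp=micro.pct_lp if micro else None,
                pct_g=micro.pct_g if micro else None,
                pct_xs=micro.pct_xs if micro else None,
                pct_ch=micro.pct_ch if micro else None,
                sws=micro.sws_mean if micro else None,
            )
        )
    return rows, excluded


def analyze_cementum_tables(
    series_rows: list,
    specimens: list[dm.SpecimenRecord],
    eruption_path: str | Path | None = None,
) -> list[CementumResultRow]:
    """Group raw increment rows into series and analyze each tooth."""

    spec_by_id = {r.specimen_id: r for r in specimens}
    table = load_eruption_ages(eruption_path)
    grouped = defaultdict(list)
    for row in series_rows:
        grouped[row.specimen_id].append(row.increment)
    results: list[CementumResultRow] = []
    for sid in sorted(grouped):
        incs = sorted(grouped[sid], key=lambda i: i.index)
        spec = spec_by_id.get(sid)
        taxon = spec.taxon if spec else Taxon.other
        tooth_code = spec.tooth_code if spec else ""
        level = spec.level if spec else ""
        series = CementumSeries(specimen_id=sid, increments=incs, tooth_code=tooth_code)
        res = analyze_series(series, taxon=taxon.value, eruption_table=table)
        results.append(
            CementumResultRow(
                taxon=taxon,
                level=level,
                specimen_id=sid,
                tooth_code=tooth_code,
                n_cb=res.n_cb_text,
                lcb=res.last_band.value if res.last_band else "",
                pct_dev=res.pct_dev,
                season=SEASON_LABELS[res.season],
            )
        )
    return results


def build_occupation_reports(
    analyses: dict[AssemblageKey, AssemblageAnalysis],
    cementum_rows: list[CementumResultRow],
) -> dict[str, dict]:
    """Per-level occupation inference combining zones, discrepancies, seasons."""

    levels = sorted(
        {k.level for k in analyses} | {r.level for r in cementum_rows if r.level}
    )
    reports: dict[str, dict] = {}
    for level in levels:
        zone_calls = {}
        discrepancies = {}
        season_dists: dict[str, SeasonDistribution] = {}
        for key, a in analyses.items():
            if key.level != level:
                continue
            if a.zone is not None:
                zone_calls[key.taxon.value] = a.zone
            if a.discrepancy is not None:
                discrepancies[key.taxon.value] = a.discrepancy
        by_taxon = defaultdict(list)
        for r in cementum_rows:
            if r.level == level:
                by_taxon[r.taxon.value].append(r)
        for taxon, rows in by_taxon.items():
            season_dists[taxon] = pool_cementum_seasons(rows)
        pattern = infer_occupation(level, zone_calls, discrepancies, season_dists)
        reports[level] = {
            "level": level,
            "label": pattern.label.value,
            "season_window": pattern.season_window,
            "confidence": pattern.confidence.value,
            "evidence": [dataclasses.asdict(e) for e in pattern.evidence],
            "zones": {
                t: {
                    "zone": c.zone.value,
                    "p_single": c.p_single,
                    "p_two_consecutive": c.p_two_consecutive,
                    "p_nonconsecutive": c.p_nonconsecutive,
                    "error_probability": c.error_probability,
                }
                for t, c in zone_calls.items()
            },
            "discrepancies": {
                t: {"flag": d.flag, "description": d.description}
                for t, d in discrepancies.items()
            },
            "season_distributions": {
                t: {
                    "counts": {s.value: c for s, c in d.counts.items()},
                    "n_determined": d.n_determined,
                    "n_no_data": d.n_no_data,
                }
                for t, d in season_dists.items()
            },
        }
    return reports


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow and write the output bundle.

    Outputs (under ``config.out_dir``): ``assemblage_summary.csv``,
    ``cementum_results.csv``, ``occupation_report.json`` and ``run.log``.
    Any schema error aborts before outputs are written.  Deterministic
    given inputs and seed (timestamps appear only in the log).
    """

    out_dir = Path(config.out_dir)
    log_records: list[str] = []
    handler_target = logger
    handler = logging.Handler()
    handler.emit = lambda record: log_records.append(handler.format(record))  # type: ignore[assignment]
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    handler_target.addHandler(handler)
    handler_target.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        # --- read everything first: schema errors abort before any write
        specimens: list[dm.SpecimenRecord] = []
        meso_obs: list = []
        micro_obs: list = []
        series_rows: list = []
        summary_rows: list[AssemblageSummaryRow] = []
        cementum_rows: list[CementumResultRow] = []
        if config.mode == "raw":
            if config.specimens:
                specimens = dm.read_specimen_table(config.specimens, "specimens")
            if config.mesowear_obs:
                meso_obs = dm.read_specimen_table(config.mesowear_obs, "mesowear_obs")
            if config.microwear_obs:
                micro_obs = dm.read_specimen_table(config.microwear_obs, "microwear_obs")
            if config.cementum_series:
                series_rows = dm.read_specimen_table(config.cementum_series, "cementum_series")
        else:
            if config.assemblage_summary:
                summary_rows = dm.read_specimen_table(config.assemblage_summary, "assemblage_summary")
            if config.cementum_results:
                cementum_rows = dm.read_specimen_table(config.cementum_results, "cementum_results")

        model = (
            BoundaryModel.from_json(Path(config.boundary_model))
            if config.boundary_model
            else default_boundary_model()
        )

        if config.mode == "raw":
            summary_rows, excluded = summarize_observations(
                specimens, meso_obs, micro_obs, cusp_rule=config.cusp_rule
            )
            cementum_rows = analyze_cementum_tables(
                series_rows, specimens, eruption_path=config.eruption_ages
            )
        if not summary_rows and not cementum_rows:
            logger.warning("no usable input: writing an indeterminate report")

        analyses = analyze_summary_rows(
            summary_rows,
            model=model,
            cutpoints=tuple(config.mesowear_cutpoints),
            mixed_midpoint=config.mixed_midpoint,
            tau=config.zone_tau,
        )
        for key, a in analyses.items():
            if a.discrepancy is not None and a.discrepancy.flag:
                logger.info(
                    "discrepancy %s level %s: %s", key.taxon.value, key.level, a.discrepancy.description
                )
        reports = build_occupation_reports(analyses, cementum_rows)

        out_dir.mkdir(parents=True, exist_ok=True)
        dm.write_table(summary_rows, out_dir / "assemblage_summary.csv", "assemblage_summary")
        dm.write_table(cementum_rows, out_dir / "cementum_results.csv", "cementum_results")
        report = {
            "seed": config.seed,
            "mode": config.mode,
            "levels": reports,
        }
        (out_dir / "occupation_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "run.log").write_text("\n".join(log_records) + "\n")
        return report
    finally:
        handler_target.removeHandler(handler)
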
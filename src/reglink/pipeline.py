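"""End-to-end orchestration: configuration, I/O, and the full linkage run.

``run_linkage`` ties the stages together in memory (standardize -> blocking
and deterministic cascade -> probabilistic passes -> rule-based review ->
optional one-to-one enforcement -> per-kind deduplication -> link-key
assignment); ``run_pipeline`` wraps it with CSV/YAML I/O, evaluation reports
and a run log whose per-pass counts are sufficient to redraw the linkage
flow diagram for the run.  Identical configuration and seed give
byte-identical outputs.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import evaluation
from .blocking import BlockScheme
from .deterministic import PassLog, run_pass_sequence
from .model import (
    ConfigError,
    FieldModel,
    LinkDecision,
    PassSpec,
    RegistryRecord,
    SourceRecord,
    Thresholds,
)
from .resolution import (
    ReviewRule,
    assign_link_keys,
    auto_review,
    deduplicate,
    enforce_one_to_one,
)
from .standardize import PostalCityTable, standardize_registry, standardize_source
from .synthetic import SOURCE_BASE_COLUMNS, REGISTRY_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "LinkageResult",
    "default_pass_sequence",
    "default_postal_table",
    "run_linkage",
    "run_pipeline",
    "validate_config",
    "read_registry_csv",
    "read_source_csv",
    "read_truth_csv",
]


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def default_postal_table() -> PostalCityTable:
    """The shipped toy postal-prefix -> city conversion table."""
    path = resources.files("reglink.data").joinpath("postal_city_toy.csv")
    with resources.as_file(path) as p:
        return PostalCityTable.from_csv(p)


def _prob_models_name_block() -> tuple[FieldModel, ...]:
    # u values are stand-ins for within-block chance agreement; overridable
    return (
        FieldModel("surname_clean", 0.95, 0.02),
        FieldModel("given_first", 0.92, 0.02),
        FieldModel("birth_year", 0.97, 0.03),
        FieldModel("birth_month", 0.97, 0.083),
        FieldModel("birth_day", 0.97, 0.033),
    )


def _prob_models_year_block() -> tuple[FieldModel, ...]:
    return (
        FieldModel("surname_nysiis", 0.90, 0.03),
        FieldModel("given_initial", 0.95, 0.06),
        FieldModel("birth_month", 0.97, 0.083),
        FieldModel("birth_day", 0.97, 0.033),
    )


def default_pass_sequence(
    kind: str,
    thresholds: Thresholds = Thresholds(4.0, 8.0),
    margin: float = 1.0,
) -> list[PassSpec]:
    """The default cascade: three deterministic passes (strict to lenient),
    a death-specific windowed pass, then two probabilistic passes.

    The exact pass parameters of production systems are unpublished; these
    are declared, fully overridable configuration, not a claim about any
    particular system.
    """
    sex_block = BlockScheme(("sex",))
    passes = [
        PassSpec(
            1, "deterministic", sex_block,
            (("surname_clean", "exact"), ("given_first", "exact"),
             ("birth_date", "date_exact"), ("sex", "exact")),
        ),
        PassSpec(
            2, "deterministic", sex_block,
            (("surname_nysiis", "nysiis_exact"), ("given_initial", "exact"),
             ("birth_date", "date_exact"), ("sex", "exact")),
        ),
        # sex-free: catches records with missing/miscoded sex
        PassSpec(
            3, "deterministic", BlockScheme(("surname_nysiis",)),
            (("surname_clean", "exact"), ("birth_date", "date_exact")),
        ),
    ]
    if kind == "death":
        passes.append(
            PassSpec(
                4, "deterministic", BlockScheme(("sex", "surname_nysiis")),
                (("given_first", "exact"),
                 ("birth_date", "date_transpose_tolerant"),
                 ("event_date", "event_within_window")),
                window_days=30,
            )
        )
    passes.append(
        PassSpec(
            5, "probabilistic", BlockScheme(("sex", "surname_nysiis")),
            (("surname_clean", "exact"), ("given_first", "exact"),
             ("birth_year", "year_exact"), ("birth_month", "exact"),
             ("birth_day", "exact")),
            thresholds=thresholds, models=_prob_models_name_block(), margin=margin,
        )
    )
    passes.append(
        PassSpec(
            6, "probabilistic", BlockScheme(("sex", "birth_year"), "broadcast"),
            (("surname_nysiis", "nysiis_exact"), ("given_initial", "exact"),
             ("birth_month", "exact"), ("birth_day", "exact")),
            thresholds=thresholds, models=_prob_models_year_block(), margin=margin,
        )
    )
    return passes


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one linkage run (mirrors the CLI flags / YAML keys)."""

    registry: str = ""
    source: str = ""
    output_dir: str = "out"
    kind: str = "immigration"
    truth: Optional[str] = None
    postal_table: Optional[str] = None
    seed: int = 0
    t_lower: float = 4.0
    t_upper: float = 8.0
    margin: float = 1.0
    review_require_city: bool = True
    review_min_weight: float = 4.0
    review_max_competitor_gap: float = 1.0
    unique_per_person: bool = False
    dedup: bool = True
    link_key_salt: Optional[str] = None
    stratify_by: tuple[str, ...] = ()
    era_band_width: int = 5
    passes: Optional[list] = None       # raw pass dicts from YAML, or None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stratify_by" in raw and raw["stratify_by"] is not None:
            raw["stratify_by"] = tuple(raw["stratify_by"])
        return cls(**raw)

    def effective_stratify(self) -> tuple[str, ...]:
        if self.stratify_by:
            return self.stratify_by
        return (
            ("immigrant_class", "region_of_birth")
            if self.kind == "immigration"
            else ("cause_of_death",)
        )

    def pass_specs(self) -> list[PassSpec]:
        th = Thresholds(self.t_lower, self.t_upper)
        if self.passes is None:
            return default_pass_sequence(self.kind, th, self.margin)
        return [_parse_pass(d, th, self.margin) for d in self.passes]

    def review_rule(self) -> ReviewRule:
        return ReviewRule(
            require_city_agreement=self.review_require_city,
            min_weight=self.review_min_weight,
            max_competitor_gap=self.review_max_competitor_gap,
        )


def _parse_pass(d: dict, default_th: Thresholds, default_margin: float) -> PassSpec:
    try:
        scheme = BlockScheme(
            tuple(d["block"]), d.get("missing_policy", "own_block")
        )
        th = None
        models: tuple[FieldModel, ...] = ()
        if d["mode"] == "probabilistic":
            th = Thresholds(
                float(d.get("t_lower", default_th.t_lower)),
                float(d.get("t_upper", default_th.t_upper)),
            )
            models = tuple(
                FieldModel(m["field"], float(m["m"]), float(m["u"]))
                for m in d.get("models", [])
            )
        return PassSpec(
            int(d["pass_id"]), d["mode"], scheme,
            tuple((f["field"], f["comparator"]) for f in d["match"]),
            thresholds=th, models=models,
            window_days=int(d.get("window_days", 30)),
            margin=float(d.get("margin", default_margin)),
        )
    except KeyError as e:
        raise ConfigError(f"pass definition missing key {e.args[0]!r}") from None


def validate_config(config: RunConfig) -> list[str]:
    """All violations (empty list iff runnable); messages name the key."""
    problems: list[str] = []
    if config.kind not in ("immigration", "death"):
        problems.append(f"kind: must be immigration or death, got {config.kind!r}")
    for key in ("registry", "source"):
        path = getattr(config, key)
        if not path:
            problems.append(f"{key}: path is required")
        elif not Path(path).exists():
            problems.append(f"{key}: file not found: {path}")
    for key in ("truth", "postal_table"):
        path = getattr(config, key)
        if path and not Path(path).exists():
            problems.append(f"{key}: file not found: {path}")
    if config.t_lower > config.t_upper:
        problems.append(
            f"thresholds: t_lower ({config.t_lower}) > t_upper ({config.t_upper})"
        )
    if config.review_min_weight < min(config.t_lower, config.t_upper):
        problems.append(
            "review_min_weight: must be >= t_lower "
            f"({config.review_min_weight} < {config.t_lower})"
        )
    if config.era_band_width < 1:
        problems.append("era_band_width: must be >= 1")
    if config.kind in ("immigration", "death"):
        try:
            config.pass_specs()
        except (ConfigError, KeyError, TypeError, ValueError) as e:
            problems.append(f"passes: {e}")
    return problems


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_registry_csv(path) -> list[RegistryRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"registry file missing columns: {sorted(missing)}")
    return [RegistryRecord(**{c: row[c] for c in REGISTRY_COLUMNS})
            for row in df.to_dict("records")]


def read_source_csv(path) -> list[SourceRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(SOURCE_BASE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"source file missing columns: {sorted(missing)}")
    attr_cols = [c for c in df.columns if c not in SOURCE_BASE_COLUMNS]
    out = []
    for row in df.to_dict("records"):
        out.append(
            SourceRecord(
                **{c: row[c] for c in SOURCE_BASE_COLUMNS},
                attrs={c: row[c] for c in attr_cols},
            )
        )
    return out


def read_truth_csv(path) -> dict[str, Optional[str]]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return {
        r["source_id"]: (r["registry_key"] or None)
        for r in df.to_dict("records")
    }


# ---------------------------------------------------------------------------
# Core run
# ---------------------------------------------------------------------------

@dataclass
class LinkageResult:
    decisions: list[LinkDecision]
    link_keys: dict[str, str]           # source_id -> opaque link key
    dedup_survivors: set[str]
    dedup_audit: list[dict]
    review_audit: list[dict]
    pass_log: PassLog
    n_review_accepted: int = 0
    n_review_rejected: int = 0


def run_linkage(
    registry: list[RegistryRecord],
    source: list[SourceRecord],
    kind: str,
    passes: Optional[list[PassSpec]] = None,
    review_rule: Optional[ReviewRule] = None,
    postal_table: Optional[PostalCityTable] = None,
    unique_per_person: bool = False,
    dedup: bool = True,
    link_key_salt: Optional[str] = None,
) -> LinkageResult:
    """Run the full linkage in memory and return decisions plus audits."""
    if kind not in ("immigration", "death"):
        raise ConfigError(f"kind must be immigration or death, got {kind!r}")
    table = postal_table if postal_table is not None else default_postal_table()
    passes = passes if passes is not None else default_pass_sequence(kind)
    rule = review_rule if review_rule is not None else ReviewRule()

    std_registry = standardize_registry(registry, table)
    std_source = standardize_source(source, table)
    reg_by_id = {r.rid: r for r in std_registry}
    src_by_id = {s.rid: s for s in std_source}

    plog = PassLog()
    decisions, queue = run_pass_sequence(std_source, std_registry, passes, plog)

    review_audit = [
        {
            "source_id": it.source_id,
            "registry_key": it.registry_key,
            "weight": round(it.weight, 4),
            "competitor_gap": "" if it.competitor_gap == float("inf")
            else round(it.competitor_gap, 4),
            "city_source": it.city_source,
            "city_registry": it.city_registry,
            "pass_id": it.pass_id,
            **{f"cmp_{k}": v for k, v in sorted(it.vector.items())},
        }
        for it in queue
    ]
    reviewed = auto_review(queue, rule)
    n_acc = sum(1 for d in reviewed if d.linked)
    decisions = decisions + reviewed

    if unique_per_person:
        decisions = enforce_one_to_one(decisions)

    if dedup:
        survivors, dedup_audit = deduplicate(decisions, src_by_id, kind, reg_by_id)
    else:
        survivors = {d.source_id for d in decisions if d.linked}
        dedup_audit = []

    _, link_keys = assign_link_keys(decisions, salt=link_key_salt)
    return LinkageResult(
        decisions=decisions,
        link_keys=link_keys,
        dedup_survivors=survivors,
        dedup_audit=dedup_audit,
        review_audit=review_audit,
        pass_log=plog,
        n_review_accepted=n_acc,
        n_review_rejected=len(reviewed) - n_acc,
    )


def decisions_frame(
    result: LinkageResult, source: list[SourceRecord]
) -> pd.DataFrame:
    """Per-record frame joining decisions to source attributes."""
    by_id = {d.source_id: d for d in result.decisions}
    rows = []
    for rec in source:
        d = by_id[rec.source_id]
        event_year = rec.attrs.get("event_year") or (
            rec.event_date[:4] if rec.event_date else ""
        )
        rows.append(
            {
                "source_id": rec.source_id,
                "status": d.status,
                "linked": d.linked,
                "registry_key": d.registry_key or "",
                "pass_id": d.pass_id if d.pass_id is not None else "",
                "weight": d.weight if d.weight is not None else "",
                "link_key": result.link_keys.get(rec.source_id, ""),
                "dedup": (
                    "survivor" if rec.source_id in result.dedup_survivors
                    else ("discarded" if d.linked else "")
                ),
                "event_year": float(event_year) if event_year else None,
                **rec.attrs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline with file I/O
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Validate, run, evaluate and write all artifacts; returns the summary."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    registry = read_registry_csv(config.registry)
    source = read_source_csv(config.source)
    table = (
        PostalCityTable.from_csv(config.postal_table)
        if config.postal_table
        else default_postal_table()
    )
    result = run_linkage(
        registry, source, config.kind,
        passes=config.pass_specs(),
        review_rule=config.review_rule(),
        postal_table=table,
        unique_per_person=config.unique_per_person,
        dedup=config.dedup,
        link_key_salt=config.link_key_salt,
    )

    df = decisions_frame(result, source)

    # link table: one row per source record, opaque keys only
    link_cols = ["source_id", "link_key", "status", "pass_id", "weight", "dedup"]
    df[link_cols].to_csv(outdir / "link_table.csv", index=False)
    pd.DataFrame(result.review_audit).to_csv(outdir / "review_audit.csv", index=False)
    pd.DataFrame(result.dedup_audit).to_csv(outdir / "dedup_audit.csv", index=False)

    strata_reports = {}
    for var in config.effective_stratify():
        if var not in df.columns:
            log.warning("stratification variable %r not present; skipped", var)
            continue
        tab = evaluation.build_stratum_table(df, var)
        tab.to_csv(outdir / f"strata_{var}.tsv", sep="\t", index=False)
        strata_reports[var] = tab

    era = evaluation.rates_by_period(df, "event_year", config.era_band_width)
    era.to_csv(outdir / "era_series.tsv", sep="\t", index=False)

    mix = evaluation.method_mix(result.decisions)
    n_linked = int(df["linked"].sum())
    summary = {
        "kind": config.kind,
        "n_registry": len(registry),
        "n_source": len(source),
        "n_linked": n_linked,
        "overall_linkage_rate": evaluation.round_half_up(
            evaluation.linkage_rate(n_linked, len(source) - n_linked), 1
        ),
        "method_mix": {k: round(v, 2) for k, v in mix.as_dict().items()},
        "review_queue": len(result.review_audit),
        "review_accepted": result.n_review_accepted,
        "review_rejected": result.n_review_rejected,
        "dedup_discarded": len(result.dedup_audit),
        "passes": result.pass_log.as_dicts(),
    }
    if config.truth:
        truth = read_truth_csv(config.truth)
        tm = evaluation.truth_metrics(result.decisions, truth)
        summary["truth_metrics"] = {
            k: (round(v, 4) if isinstance(v, float) else v)
            for k, v in tm.as_dict().items()
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_run_log(outdir / "run.log", config, summary)
    return summary


def _write_run_log(path, config: RunConfig, summary: dict) -> None:
    lines = [
        f"reglink run ({summary['kind']})",
        f"registry={config.registry} source={config.source}",
        "nysiis_variant=original-1970 code_length=uncapped",
        f"records: registry={summary['n_registry']} source={summary['n_source']}",
    ]
    for row in summary["passes"]:
        lines.append(
            "pass {pass_id} [{mode}] in={records_in} linked={linked} "
            "review={to_review} candidates={candidates}".format(**row)
        )
    lines.append(
        "review: queued={} accepted={} rejected={}".format(
            summary["review_queue"], summary["review_accepted"],
            summary["review_rejected"],
        )
    )
    lines.append(f"dedup discarded={summary['dedup_discarded']}")
    lines.append(
        "overall linkage rate={} method mix={}".format(
            summary["overall_linkage_rate"], summary["method_mix"]
        )
    )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
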
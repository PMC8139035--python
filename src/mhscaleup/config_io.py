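"""Input schemas, file I/O and the command-line entry point.

The model consumes five tabular inputs (population, epidemiology, unit
costs, economics, optional explicit coverage) plus a YAML configuration
document that names the disorders, interventions, program-cost profile,
scalar economic settings and sensitivity scenarios.  All money is carried
internally as integer Iranian rial (the rial is treated as the minor unit);
conversion to USD / Intl$ happens only at report time, so conservation
checks on cost tables are exact integer identities.

Conventions
-----------
* Coverage is stored as percent (0–100).
* Years are calendar-labelled; "year index t" = year − horizon_start.
* CSV dialect: comma-separated, UTF-8, mandatory header row.

The module also exposes the published base-case projection tables for the
Iranian socio-mental health scale-up programme (2020–2030) as packaged CSV
fixtures (``published_*`` functions): the printed coverage rows, the annual
cost table, the healthy-life-year table, and the eight-column sensitivity
matrix.  These are authoritative *inputs* — the printed trajectories are fed
through :func:`mhscaleup.coverage.from_table`, and the printed component
totals drive identity checks and ratio recomputation.
"""

from __future__ import annotations

import argparse
import json
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .coverage import PATTERNS, PatternName

# ---------------------------------------------------------------------------
# Constants and numeric conventions
# ---------------------------------------------------------------------------

#: 17 five-year age bands (GBD-style), two sexes → 34 population groups.
AGE_BANDS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80+",
)
SEXES: tuple[str, ...] = ("female", "male")
N_GROUPS = len(AGE_BANDS) * len(SEXES)

DISORDER_IDS: tuple[str, ...] = ("depression", "anxiety", "bipolar", "epilepsy")

_DATA_DIR = Path(__file__).parent / "data"


class InputError(Exception):
    """A required input file is missing or unreadable."""


class SchemaError(ValueError):
    """An input parsed but violates the model's schema or cross-references."""


def round_half_up(x: float) -> int:
    """Round a non-negative quantity half-up to an integer.

    Used everywhere a person count or a rial amount is finalised; group- or
    cadre-level terms stay at full precision and are rounded only after
    summation.
    """
    if x < 0:
        raise ValueError("round_half_up expects non-negative input")
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class AgeSexGroup(BaseModel):
    """One cell of the 34-group population partition."""

    sex: Literal["female", "male"]
    age_band: str

    @field_validator("age_band")
    @classmethod
    def _known_band(cls, v: str) -> str:
        if v not in AGE_BANDS:
            raise ValueError(f"unknown age band {v!r}")
        return v


def all_groups() -> list[AgeSexGroup]:
    return [AgeSexGroup(sex=s, age_band=b) for s in SEXES for b in AGE_BANDS]


class DisorderSpec(BaseModel):
    """A modelled disorder and its disability weight (severity in (0,1))."""

    id: str
    name: str = ""
    disability_weight: float = Field(gt=0, lt=1)

    @model_validator(mode="after")
    def _default_name(self) -> "DisorderSpec":
        if not self.name:
            object.__setattr__(self, "name", self.id)
        return self


class InterventionSpec(BaseModel):
    """One treatment package.

    ``eligible_fraction`` is the share of prevalent cases the package
    targets (basic tier → moderate cases, intensive tier → severe cases);
    ``effect_size`` is the fraction of disability time averted per treated
    case-year.
    """

    id: str
    disorder: str
    tier: Literal["basic", "intensive"]
    eligible_fraction: float = Field(gt=0, le=1)
    effect_size: float = Field(ge=0, le=1)
    baseline_coverage_pct: float = Field(ge=0, le=100)
    target_coverage_pct: float = Field(ge=0, le=100)

    @model_validator(mode="after")
    def _ordered_coverage(self) -> "InterventionSpec":
        if self.baseline_coverage_pct > self.target_coverage_pct:
            raise ValueError(
                f"{self.id}: baseline coverage exceeds target coverage"
            )
        return self


class VisitCost(BaseModel):
    """Outpatient contact time for one staff cadre, per case-year."""

    cadre: str
    minutes_per_case_year: float = Field(ge=0)
    salary_per_minute_irr: float = Field(ge=0)


class UnitCostProfile(BaseModel):
    """Per case-year resource use for one intervention (rial amounts)."""

    intervention: str
    commodity_cost_irr: float = Field(ge=0)  # drugs + supplies
    visits: list[VisitCost] = Field(default_factory=list)

    @property
    def labor_cost_per_case_irr(self) -> float:
        return math.fsum(
            v.minutes_per_case_year * v.salary_per_minute_irr for v in self.visits
        )

    @property
    def total_per_case_irr(self) -> float:
        """Declared per-case total = commodity + Σ minutes × salary (exact)."""
        return self.commodity_cost_irr + self.labor_cost_per_case_irr


class ProgramCostProfile(BaseModel):
    """Annual programme overheads (management, supervision, training).

    National amounts are booked once; provincial amounts once per province.
    """

    management_national_irr: float = Field(ge=0, default=0)
    management_provincial_irr: float = Field(ge=0, default=0)
    supervision_irr: float = Field(ge=0, default=0)   # per province
    training_irr: float = Field(ge=0, default=0)      # per province

    def annual_total_irr(self, n_provinces: int) -> float:
        return self.management_national_irr + n_provinces * (
            self.management_provincial_irr + self.supervision_irr + self.training_irr
        )


class EconomicSettings(BaseModel):
    """Inflation series, exchange rate and PPP/GDP scalars.

    ``exchange_rate_irr_per_usd`` defaults to the June-2020 UN rate; an
    optional per-year series supports the extrapolated-exchange-rate mode.
    """

    inflation: dict[int, float]
    exchange_rate_irr_per_usd: float = Field(gt=0, default=194_881.0)
    exchange_rate_by_year: Optional[dict[int, float]] = None
    ppp_factor_intl_per_usd: float = Field(gt=0, default=9.63)
    gdp_per_capita_usd: float = Field(gt=0, default=5550.0)

    @field_validator("inflation")
    @classmethod
    def _rates_above_minus_one(cls, v: dict[int, float]) -> dict[int, float]:
        bad = {y: r for y, r in v.items() if r <= -1}
        if bad:
            raise ValueError(f"inflation rates must exceed -1: {bad}")
        return v

    def exchange_rate_for(self, year: int) -> float:
        if self.exchange_rate_by_year and year in self.exchange_rate_by_year:
            return self.exchange_rate_by_year[year]
        return self.exchange_rate_irr_per_usd


class CoverageOverride(BaseModel):
    """Scenario override of coverage endpoints; ``None`` inherits base."""

    baseline_pct: Optional[float] = Field(default=None, ge=0, le=100)
    target_pct: Optional[float] = Field(default=None, ge=0, le=100)


class ScenarioSpec(BaseModel):
    """One sensitivity run: a pattern, an epidemiology bound, and optional
    per-tier coverage endpoint overrides."""

    name: str
    pattern: PatternName = "front_loaded"
    epi_bound: Literal["point", "lower", "upper"] = "point"
    coverage_overrides: dict[str, CoverageOverride] = Field(default_factory=dict)

    @field_validator("coverage_overrides")
    @classmethod
    def _tiers_known(cls, v: dict[str, CoverageOverride]) -> dict[str, CoverageOverride]:
        unknown = set(v) - {"basic", "intensive"}
        if unknown:
            raise ValueError(f"coverage overrides keyed by tier; unknown: {unknown}")
        return v


class ModelConfig(BaseModel):
    """Validated top-level configuration for one projection run."""

    horizon_start: int = 2020
    horizon_end: int = 2030
    country_label: str = "Iran"
    currency_local: str = "IRR"
    n_provinces: int = Field(ge=1, default=31)

    population_csv: Path
    epi_csv: Path
    unit_costs_csv: Path
    economics_csv: Path
    coverage_csv: Optional[Path] = None

    disorders: list[DisorderSpec]
    interventions: list[InterventionSpec]
    program_costs: ProgramCostProfile = Field(default_factory=ProgramCostProfile)

    exchange_rate_irr_per_usd: float = Field(gt=0, default=194_881.0)
    ppp_factor_intl_per_usd: float = Field(gt=0, default=9.63)
    gdp_per_capita_usd: float = Field(gt=0, default=5550.0)

    scenarios: list[ScenarioSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.horizon_end <= self.horizon_start:
            raise ValueError("horizon_end must exceed horizon_start")
        disorder_ids = {d.id for d in self.disorders}
        for iv in self.interventions:
            if iv.disorder not in disorder_ids:
                raise ValueError(
                    f"intervention {iv.id!r} references unknown disorder "
                    f"{iv.disorder!r}"
                )
        seen: set[str] = set()
        for iv in self.interventions:
            if iv.id in seen:
                raise ValueError(f"duplicate intervention id {iv.id!r}")
            seen.add(iv.id)
        for sc in self.scenarios:
            if sc.pattern not in PATTERNS:  # Literal already enforces; belt+braces
                raise ValueError(f"scenario {sc.name!r}: unknown pattern")
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.horizon_start, self.horizon_end + 1))


# ---------------------------------------------------------------------------
# Input bundle (config + loaded tables)
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    """Everything one projection needs, loaded and horizon-aligned."""

    config: ModelConfig
    population: pd.DataFrame    # year, sex, age_band, count
    epi: pd.DataFrame           # disorder, sex, age_band, prevalence_per_1000, ...
    unit_costs: dict[str, UnitCostProfile]
    economics: EconomicSettings
    coverage_table: Optional[dict[str, dict[int, float]]] = None

    @property
    def years(self) -> list[int]:
        return self.config.years

    @property
    def disorders(self) -> list[DisorderSpec]:
        return self.config.disorders

    @property
    def interventions(self) -> list[InterventionSpec]:
        return self.config.interventions


_EPI_COLUMNS = [
    "disorder", "sex", "age_band", "prevalence_per_1000", "prev_lo", "prev_hi",
    "incidence_per_1000", "inc_lo", "inc_hi",
]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML configuration document.

    Relative table paths are resolved against the config file's directory;
    every referenced path must exist before the run starts.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path.name}: expected a mapping at top level")
    cfg = ModelConfig.model_validate(raw)
    base = path.parent
    for attr in ("population_csv", "epi_csv", "unit_costs_csv",
                 "economics_csv", "coverage_csv"):
        p = getattr(cfg, attr)
        if p is None:
            continue
        resolved = p if p.is_absolute() else base / p
        if not resolved.exists():
            raise InputError(f"{attr} does not resolve: {resolved}")
        setattr(cfg, attr, resolved)
    return cfg


def load_bundle(config: ModelConfig) -> InputBundle:
    """Load the five side tables referenced by a validated config."""
    pop = _read_csv(config.population_csv, ["year", "sex", "age_band", "count"])
    epi = _read_csv(config.epi_csv, _EPI_COLUMNS)
    uc = _read_csv(config.unit_costs_csv,
                   ["intervention", "component"])
    econ = _read_csv(config.economics_csv, ["year", "inflation_rate"])

    profiles = unit_cost_profiles_from_frame(uc)
    for iv in config.interventions:
        if iv.id not in profiles:
            raise SchemaError(f"unit_costs.csv missing intervention {iv.id!r}")

    inflation = dict(zip(econ["year"].astype(int), econ["inflation_rate"].astype(float)))
    exch_series = None
    if "exchange_rate" in econ.columns and econ["exchange_rate"].notna().any():
        sub = econ.dropna(subset=["exchange_rate"])
        exch_series = dict(zip(sub["year"].astype(int), sub["exchange_rate"].astype(float)))
    economics = EconomicSettings(
        inflation=inflation,
        exchange_rate_irr_per_usd=config.exchange_rate_irr_per_usd,
        exchange_rate_by_year=exch_series,
        ppp_factor_intl_per_usd=config.ppp_factor_intl_per_usd,
        gdp_per_capita_usd=config.gdp_per_capita_usd,
    )

    coverage_table = None
    if config.coverage_csv is not None:
        cov = _read_csv(config.coverage_csv, ["intervention", "year", "percent"])
        coverage_table = {}
        for iv_id, grp in cov.groupby("intervention"):
            coverage_table[str(iv_id)] = dict(
                zip(grp["year"].astype(int), grp["percent"].astype(float))
            )

    return InputBundle(config=config, population=pop, epi=epi,
                       unit_costs=profiles, economics=economics,
                       coverage_table=coverage_table)


def unit_cost_profiles_from_frame(df: pd.DataFrame) -> dict[str, UnitCostProfile]:
    """Assemble :class:`UnitCostProfile` objects from the long CSV layout.

    Rows with ``component == "commodity"`` carry ``amount_irr``; rows with
    ``component == "visit"`` carry cadre, minutes and per-minute salary.  A
    ``declared_total_irr`` value, when present, is checked against the
    reconstructed commodity + labor total.
    """
    profiles: dict[str, UnitCostProfile] = {}
    for iv_id, grp in df.groupby("intervention", sort=False):
        commodity = 0.0
        visits: list[VisitCost] = []
        declared = None
        for _, row in grp.iterrows():
            comp = row["component"]
            if comp == "commodity":
                commodity += float(row["amount_irr"])
            elif comp == "visit":
                visits.append(VisitCost(
                    cadre=str(row["cadre"]),
                    minutes_per_case_year=float(row["minutes_per_case_year"]),
                    salary_per_minute_irr=float(row["salary_per_minute_irr"]),
                ))
            elif comp == "declared_total":
                declared = float(row["amount_irr"])
            else:
                raise SchemaError(f"unit_costs: unknown component {comp!r}")
        prof = UnitCostProfile(intervention=str(iv_id),
                               commodity_cost_irr=commodity, visits=visits)
        if declared is not None and not math.isclose(
                declared, prof.total_per_case_irr, rel_tol=0, abs_tol=0.5):
            raise SchemaError(
                f"unit_costs: declared total for {iv_id!r} ({declared}) != "
                f"commodity + Σ minutes×salary ({prof.total_per_case_irr})"
            )
        profiles[str(iv_id)] = prof
    return profiles


def unit_cost_profiles_to_frame(profiles: Mapping[str, UnitCostProfile]) -> pd.DataFrame:
    rows = []
    for prof in profiles.values():
        rows.append({"intervention": prof.intervention, "component": "commodity",
                     "cadre": "", "minutes_per_case_year": "",
                     "salary_per_minute_irr": "",
                     "amount_irr": prof.commodity_cost_irr})
        for v in prof.visits:
            rows.append({"intervention": prof.intervention, "component": "visit",
                         "cadre": v.cadre,
                         "minutes_per_case_year": v.minutes_per_case_year,
                         "salary_per_minute_irr": v.salary_per_minute_irr,
                         "amount_irr": ""})
        rows.append({"intervention": prof.intervention,
                     "component": "declared_total", "cadre": "",
                     "minutes_per_case_year": "", "salary_per_minute_irr": "",
                     "amount_irr": prof.total_per_case_irr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference tables (packaged CSV fixtures)
# ---------------------------------------------------------------------------

def published_coverage() -> pd.DataFrame:
    """The seven printed front-loaded coverage rows (long format)."""
    return pd.read_csv(_DATA_DIR / "base_case_coverage.csv")


def published_costs() -> pd.DataFrame:
    """Printed base-case annual cost table (USD), component rows + total."""
    return pd.read_csv(_DATA_DIR / "base_case_costs.csv", index_col="component")


def published_impacts() -> pd.DataFrame:
    """Printed base-case healthy-life-year table, disorder rows + total."""
    return pd.read_csv(_DATA_DIR / "base_case_impact.csv", index_col="disorder")


def published_sensitivity() -> pd.DataFrame:
    """Printed eight-scenario sensitivity matrix (USD / HLY / ratios)."""
    return pd.read_csv(_DATA_DIR / "sensitivity_analysis.csv", index_col="row")


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Finalised output of one projection run.

    ``cost_table``: per-year intervention/program/labor/total (integer rial);
    ``impact_table``: per-year per-disorder healthy life years gained;
    ``summary``: horizon totals, ratios in local/USD/Intl$, classification,
    per-capita cost.  Summary totals equal column sums of the detail tables
    bit-exactly (integer rial / stored float precision).
    """

    cost_table: pd.DataFrame
    impact_table: pd.DataFrame
    summary: dict

    def validate(self) -> None:
        cost_sum = int(self.cost_table["total_irr"].sum())
        if cost_sum != int(self.summary["total_cost_irr"]):
            raise SchemaError("summary total_cost_irr != cost table column sum")
        hly_sum = math.fsum(self.impact_table["healthy_ly"])
        if not math.isclose(hly_sum, self.summary["total_hly"],
                            rel_tol=0, abs_tol=1e-6):
            raise SchemaError("summary total_hly != impact table sum")


def write_report(report: RunReport, path: str | Path,
                 format: Literal["csv", "json", "text"] = "csv") -> None:
    """Serialise a report; re-reading reproduces every numeric field exactly.

    ``csv`` writes ``costs.csv`` + ``impact.csv`` + ``summary.json`` under
    ``path`` (a directory); ``json`` writes a single document; ``text``
    renders human-readable tables.
    """
    path = Path(path)
    try:
        if format == "csv":
            path.mkdir(parents=True, exist_ok=True)
            report.cost_table.to_csv(path / "costs.csv", index=False)
            report.impact_table.to_csv(path / "impact.csv", index=False)
            with open(path / "summary.json", "w", encoding="utf-8") as fh:
                json.dump(report.summary, fh, indent=2, sort_keys=True)
                fh.write("\n")
        elif format == "json":
            doc = {
                "costs": report.cost_table.to_dict(orient="list"),
                "impacts": report.impact_table.to_dict(orient="list"),
                "summary": report.summary,
            }
            path.parent.mkdir(parents=True, exist_ok=True)
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(doc, fh, indent=2, sort_keys=True)
                fh.write("\n")
        elif format == "text":
            path.parent.mkdir(parents=True, exist_ok=True)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(render_report_text(report))
        else:
            raise SchemaError(f"unknown report format {format!r}")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path, format: Literal["csv", "json"] = "csv") -> RunReport:
    """Inverse of :func:`write_report` for the machine-readable formats."""
    path = Path(path)
    if format == "csv":
        costs = pd.read_csv(path / "costs.csv")
        impacts = pd.read_csv(path / "impact.csv")
        with open(path / "summary.json", encoding="utf-8") as fh:
            summary = json.load(fh)
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        costs = pd.DataFrame(doc["costs"])
        impacts = pd.DataFrame(doc["impacts"])
        summary = doc["summary"]
    else:
        raise SchemaError(f"unknown report format {format!r}")
    return RunReport(cost_table=costs, impact_table=impacts, summary=summary)


def render_report_text(report: RunReport) -> str:
    lines = ["Projected costs (IRR)", "=" * 21,
             report.cost_table.to_string(index=False), "",
             "Healthy life years gained", "=" * 25]
    if len(report.impact_table):
        pivot = report.impact_table.pivot_table(
            index="disorder", columns="year", values="healthy_ly", aggfunc="sum")
        lines.append(pivot.to_string())
    else:
        lines.append("(empty)")
    lines += ["", "Summary", "=" * 7]
    for k in sorted(report.summary):
        lines.append(f"{k}: {report.summary[k]}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="mhscaleup",
        description="Cost-consequence projection of mental-health service scale-up",
    )
    sub = p.add_subparsers(dest="command", required=True)

    g = sub.add_parser("generate", help="write a seeded synthetic input bundle")
    g.add_argument("--seed", type=int, default=0)
    g.add_argument("--out", type=Path, required=True, help="output directory")

    pr = sub.add_parser("project", help="run one scenario end to end")
    pr.add_argument("--config", type=Path, required=True)
    pr.add_argument("--scenario", type=str, default=None,
                    help="named scenario (default: base case)")
    pr.add_argument("--seed", type=int, default=0, help="unused placeholder for parity")
    pr.add_argument("--out", type=Path, required=True)
    pr.add_argument("--format", choices=["csv", "json", "text"], default="csv")

    sc = sub.add_parser("scenarios", help="run all configured scenarios")
    sc.add_argument("--config", type=Path, required=True)
    sc.add_argument("--out", type=Path, default=None,
                    help="CSV path for the sensitivity matrix (default stdout)")

    rp = sub.add_parser("report", help="re-render a saved report as text")
    rp.add_argument("--in", dest="indir", type=Path, required=True)
    return p


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point; returns a process exit status."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:  # argparse prints usage itself
        return int(exc.code or 0)

    # imported here to keep schema definitions import-light and cycle-free
    from . import cea_scenarios, synthetic_data

    try:
        if args.command == "generate":
            paths = synthetic_data.write_bundle(args.out, seed=args.seed)
            print(f"wrote synthetic bundle: {paths['config']}")
        elif args.command == "project":
            cfg = load_config(args.config)
            bundle = load_bundle(cfg)
            spec = None
            if args.scenario is not None:
                matches = [s for s in cfg.scenarios if s.name == args.scenario]
                if not matches:
                    raise SchemaError(f"unknown scenario {args.scenario!r}")
                spec = matches[0]
            report = cea_scenarios.project(bundle, spec)
            write_report(report, args.out, args.format)
            print(f"cost per healthy life year (USD): "
                  f"{report.summary['cost_per_hly_usd']}")
        elif args.command == "scenarios":
            cfg = load_config(args.config)
            bundle = load_bundle(cfg)
            specs = cfg.scenarios or cea_scenarios.default_scenarios()
            _, matrix = cea_scenarios.run_all(bundle, specs)
            if args.out is not None:
                args.out.parent.mkdir(parents=True, exist_ok=True)
                matrix.to_csv(args.out)
                print(f"wrote sensitivity matrix: {args.out}")
            else:
                print(matrix.to_string())
        elif args.command == "report":
            report = read_report(args.indir, "csv")
            print(render_report_text(report))
    except (InputError, SchemaError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    return 0


def main() -> None:  # console-script shim
    sys.exit(cli_main())
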
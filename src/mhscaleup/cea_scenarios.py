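"""Cost-effectiveness ratios, GDP thresholds and the scenario engine.

The headline statistic is the cost per healthy life year gained (≡ cost per
DALY averted): horizon total cost divided by horizon total HLY, reported in
whole USD.  Ratios are classified against GDP-per-capita thresholds using
the WHO-CHOICE three-band convention — below 1×GDP per capita is *very
cost-effective*, between 1× and 3× is *cost-effective*, above 3× is *not
cost-effective*.

Sensitivity analysis runs eight deterministic scenarios: the base
front-loaded scale-up, the exponential and linear patterns, the lower and
upper epidemiological confidence bounds, and three coverage variants
(basic baseline 40→50%, intensive target 30→40%, basic target 70→60%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import caseload as _caseload
from . import costing as _costing
from . import impact as _impact
from .config_io import (
    EconomicSettings,
    InputBundle,
    RunReport,
    ScenarioSpec,
    SchemaError,
    round_half_up,
)
from .coverage import CoverageTrajectory, from_table, interpolate

#: pattern the base case uses; explicit coverage tables apply only here
BASE_PATTERN = "front_loaded"

CLASSIFICATIONS = ("very_cost_effective", "cost_effective", "not_cost_effective")


@dataclass
class CEResult:
    """Summary cost-effectiveness result for one scenario."""

    scenario: str
    total_cost_irr: int
    total_cost_usd: float
    total_cost_intl: float
    total_hly: float
    cost_per_hly_usd: int
    cost_per_hly_intl: int
    classification: str


def cost_per_hly(total_cost_usd: float, total_hly: float,
                 *, rounded: bool = True) -> float:
    """Cost per healthy life year gained, half-up to whole USD by default."""
    if total_hly <= 0:
        raise SchemaError("cost per HLY undefined: total_hly must be > 0")
    ratio = total_cost_usd / total_hly
    return float(round_half_up(ratio)) if rounded else ratio


def classify(ratio_usd: float, gdp_per_capita_usd: float) -> str:
    """WHO threshold bands; a ratio exactly at 1×GDP is assigned upward
    (cost_effective), as is one exactly at 3×GDP."""
    if gdp_per_capita_usd <= 0:
        raise SchemaError("GDP per capita must be positive")
    if ratio_usd < gdp_per_capita_usd:
        return "very_cost_effective"
    if ratio_usd <= 3 * gdp_per_capita_usd:
        return "cost_effective"
    return "not_cost_effective"


def default_scenarios() -> list[ScenarioSpec]:
    """The eight-run sensitivity set around the front-loaded base case."""
    ov = lambda **kw: {k: {"baseline_pct": v[0], "target_pct": v[1]}
                       for k, v in kw.items()}
    return [
        ScenarioSpec(name="base_front_loaded", pattern="front_loaded"),
        ScenarioSpec(name="exponential", pattern="exponential"),
        ScenarioSpec(name="linear", pattern="linear"),
        ScenarioSpec(name="epi_lower_CI", epi_bound="lower"),
        ScenarioSpec(name="epi_upper_CI", epi_bound="upper"),
        # basic baseline raised 40 → 50%
        ScenarioSpec(name="coverage_1",
                     coverage_overrides=ov(basic=(50.0, None))),
        # intensive target raised 30 → 40%
        ScenarioSpec(name="coverage_2",
                     coverage_overrides=ov(intensive=(None, 40.0))),
        # basic target lowered 70 → 60%
        ScenarioSpec(name="coverage_3",
                     coverage_overrides=ov(basic=(None, 60.0))),
    ]


def apply_scenario(bundle: InputBundle, spec: ScenarioSpec) -> InputBundle:
    """Derive the scenario's inputs from the base bundle.

    The epidemiology table is swapped to the chosen confidence bound and the
    tier-level coverage overrides are applied to intervention endpoints;
    everything else is untouched.  The base spec is an identity.
    """
    epi = bundle.epi
    if spec.epi_bound != "point":
        lo_hi = {"lower": ("prev_lo", "inc_lo"), "upper": ("prev_hi", "inc_hi")}
        prev_col, inc_col = lo_hi[spec.epi_bound]
        epi = epi.copy()
        epi["prevalence_per_1000"] = epi[prev_col]
        epi["incidence_per_1000"] = epi[inc_col]

    interventions = bundle.interventions
    if spec.coverage_overrides:
        interventions = []
        for iv in bundle.interventions:
            override = spec.coverage_overrides.get(iv.tier)
            if override is None:
                interventions.append(iv)
                continue
            changes = {}
            if override.baseline_pct is not None:
                changes["baseline_coverage_pct"] = override.baseline_pct
            if override.target_pct is not None:
                changes["target_coverage_pct"] = override.target_pct
            interventions.append(iv.model_copy(update=changes))

    # explicit published trajectories only describe the unmodified base case
    keep_table = (spec.pattern == BASE_PATTERN and not spec.coverage_overrides)
    if epi is bundle.epi and interventions is bundle.interventions and keep_table:
        return bundle
    config = bundle.config.model_copy(update={"interventions": interventions})
    return InputBundle(
        config=config,
        population=bundle.population,
        epi=epi,
        unit_costs=bundle.unit_costs,
        economics=bundle.economics,
        coverage_table=bundle.coverage_table if keep_table else None,
    )


def build_trajectories(bundle: InputBundle,
                       pattern: str = BASE_PATTERN
                       ) -> dict[str, CoverageTrajectory]:
    """Per-intervention trajectories: explicit table rows when supplied,
    otherwise pattern interpolation between the configured endpoints."""
    years = bundle.years
    n_steps = len(years) - 1
    out: dict[str, CoverageTrajectory] = {}
    for iv in bundle.interventions:
        if bundle.coverage_table and iv.id in bundle.coverage_table:
            out[iv.id] = from_table(bundle.coverage_table[iv.id],
                                    intervention=iv.id, horizon_years=years)
        else:
            out[iv.id] = interpolate(
                iv.baseline_coverage_pct, iv.target_coverage_pct, n_steps,
                pattern, intervention=iv.id, start_year=years[0])
    return out


def run_scenario(bundle: InputBundle, spec: ScenarioSpec
                 ) -> tuple[_costing.CostSeries, _impact.ImpactSeries, CEResult]:
    """Execute one scenario end to end: coverage → caseloads → impact/cost."""
    b = apply_scenario(bundle, spec)
    trajectories = build_trajectories(b, spec.pattern)
    loads = _caseload.build_series(b.population, b.epi, b.interventions,
                                   trajectories)
    impacts = _impact.build_impact(loads, b.disorders, b.interventions)
    pop_start = int(b.population.loc[
        b.population["year"] == b.years[0], "count"].sum())
    costs = _costing.build_costs(
        loads, b.unit_costs, b.config.program_costs, b.economics,
        base_year=b.years[0], n_provinces=b.config.n_provinces,
        population_start_total=pop_start)
    result = summarize(spec.name, costs, impacts, b.economics)
    return costs, impacts, result


def summarize(name: str, costs: _costing.CostSeries,
              impacts: _impact.ImpactSeries,
              economics: EconomicSettings) -> CEResult:
    total_irr = costs.total_irr
    total_usd = _costing.convert(total_irr, economics, "USD")
    total_intl = _costing.convert(total_irr, economics, "IntlD")
    total_hly = impacts.total()
    ratio_usd = cost_per_hly(total_usd, total_hly, rounded=False)
    ratio_intl = ratio_usd * economics.ppp_factor_intl_per_usd
    return CEResult(
        scenario=name,
        total_cost_irr=total_irr,
        total_cost_usd=total_usd,
        total_cost_intl=total_intl,
        total_hly=total_hly,
        cost_per_hly_usd=round_half_up(ratio_usd),
        cost_per_hly_intl=round_half_up(ratio_intl),
        classification=classify(ratio_usd, economics.gdp_per_capita_usd),
    )


def run_all(bundle: InputBundle, specs: list[ScenarioSpec]
            ) -> tuple[list[CEResult], pd.DataFrame]:
    """Run every scenario; emit results plus the sensitivity matrix
    (cost components, per-disorder impacts, totals, ratios — one column per
    scenario, whole USD)."""
    if not specs:
        raise SchemaError("scenario list must be non-empty")
    results: list[CEResult] = []
    columns: dict[str, dict[str, float]] = {}
    disorder_ids = [d.id for d in bundle.disorders]
    for spec in specs:
        try:
            costs, impacts, res = run_scenario(bundle, spec)
        except Exception as exc:
            raise SchemaError(f"scenario {spec.name!r} failed: {exc}") from exc
        results.append(res)
        econ = bundle.economics
        col: dict[str, float] = {}
        for comp in ("intervention", "program", "labor"):
            col[f"{comp}_costs_usd"] = round_half_up(_costing.convert(
                costs.component_total_irr(comp), econ, "USD"))
        col["total_costs_usd"] = round_half_up(_costing.convert(
            costs.total_irr, econ, "USD"))
        per_disorder = impacts.by_disorder()
        for d in disorder_ids:
            col[f"{d}_hly"] = per_disorder.get(d, 0.0)
        col["total_hly"] = impacts.total()
        col["cost_per_hly_usd"] = res.cost_per_hly_usd
        col["cost_per_hly_intl"] = res.cost_per_hly_intl
        columns[spec.name] = col
    matrix = pd.DataFrame(columns)
    matrix.index.name = "row"
    return results, matrix


def recompute_sensitivity(matrix: pd.DataFrame, *, gdp_per_capita_usd: float,
                          ppp_factor_intl_per_usd: float) -> pd.DataFrame:
    """Recompute summary rows of a sensitivity matrix from its own detail.

    For every scenario column: total HLY from the per-disorder rows, the
    cost-per-HLY ratio from the total-cost row, and the threshold
    classification.  Used both as an internal-consistency check on model
    output and to re-derive the published ratios from the published totals.
    """
    hly_rows = [r for r in matrix.index
                if r.endswith("_hly") and r != "total_hly"]
    out = {}
    for name in matrix.columns:
        col = matrix[name]
        total_hly = math.fsum(float(col[r]) for r in hly_rows)
        total_cost = float(col["total_costs_usd"])
        ratio = cost_per_hly(total_cost, total_hly)
        out[name] = {
            "total_hly": total_hly,
            "total_costs_usd": total_cost,
            "cost_per_hly_usd": ratio,
            "cost_per_hly_intl": float(round_half_up(
                ratio * ppp_factor_intl_per_usd)),
            "classification": classify(ratio, gdp_per_capita_usd),
        }
    res = pd.DataFrame(out)
    res.index.name = "row"
    return res


def project(bundle: InputBundle, spec: Optional[ScenarioSpec] = None) -> RunReport:
    """Run one scenario (default: base case) and package a RunReport."""
    if spec is None:
        spec = ScenarioSpec(name="base_front_loaded", pattern=BASE_PATTERN)
    costs, impacts, res = run_scenario(bundle, spec)
    summary = {
        "scenario": res.scenario,
        "total_cost_irr": res.total_cost_irr,
        "total_cost_usd": res.total_cost_usd,
        "total_cost_intl": res.total_cost_intl,
        "total_hly": res.total_hly,
        "cost_per_hly_usd": res.cost_per_hly_usd,
        "cost_per_hly_intl": res.cost_per_hly_intl,
        "classification": res.classification,
        "per_capita_usd": costs.per_capita_usd,
    }
    report = RunReport(cost_table=costs.table, impact_table=impacts.table,
                       summary=summary)
    report.validate()
    return report
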
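"""Seeded synthetic input bundles with the structure the analysis assumes.

The generator emulates the study conditions of the national scale-up
analysis: a population of 83 million split into 34 age/sex groups over a
2020–2030 horizon; per-1,000 prevalence and incidence rates with age/sex
gradients and confidence bounds for depression, anxiety, bipolar disorder
and epilepsy; per-case unit costs decomposed into commodity (drug/supply)
spend and cadre-level visit time priced at per-minute salaries; programme
overheads at national and provincial level; and an inflation series with
observed 2010–2019 national CPI rates extrapolated across the horizon by
their geometric mean.

Quantities the published analysis defers to tool internals — disability
weights and per-intervention effect sizes — are drawn from stated plausible
ranges and *recorded* in the bundle, so downstream tests can check recovery
against known truth.  Every draw is reproducible from ``(seed, parameters)``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .config_io import (
    AGE_BANDS,
    DISORDER_IDS,
    SEXES,
    DisorderSpec,
    EconomicSettings,
    InputBundle,
    InterventionSpec,
    ModelConfig,
    ProgramCostProfile,
    ScenarioSpec,
    SchemaError,
    UnitCostProfile,
    VisitCost,
    unit_cost_profiles_to_frame,
)
from .cea_scenarios import default_scenarios

# ---------------------------------------------------------------------------
# Study conditions (defaults)
# ---------------------------------------------------------------------------

START_YEAR = 2020
END_YEAR = 2030
BASE_TOTAL_POPULATION = 83_000_000
ANNUAL_GROWTH = 0.012
N_PROVINCES = 31

#: approximate national CPI inflation, 2010–2019 (fractions per year)
OBSERVED_INFLATION: dict[int, float] = {
    2010: 0.124, 2011: 0.215, 2012: 0.305, 2013: 0.347, 2014: 0.156,
    2015: 0.119, 2016: 0.090, 2017: 0.096, 2018: 0.312, 2019: 0.411,
}

#: disability-weight ranges per disorder (all inside the plausible 0.1–0.7 band)
DISABILITY_WEIGHT_RANGES: dict[str, tuple[float, float]] = {
    "depression": (0.30, 0.50),
    "anxiety": (0.15, 0.35),
    "bipolar": (0.40, 0.60),
    "epilepsy": (0.25, 0.45),
}
EFFECT_SIZE_RANGE = (0.2, 0.5)

#: plausibility window the generator promises for the population-weighted
#: adult (15+) prevalence per 1,000 of each disorder
ADULT_PREV_WINDOWS: dict[str, tuple[float, float]] = {
    "depression": (20.0, 80.0),
    "anxiety": (25.0, 90.0),
    "bipolar": (2.0, 15.0),
    "epilepsy": (2.0, 15.0),
}

# normalised adult age-profile templates (index = 17 age bands, rates /1000);
# depression/anxiety rise through adulthood then plateau or fade, the
# neurological and severe-mental profiles are flatter
_AGE_PROFILES: dict[str, list[float]] = {
    "depression": [2, 4, 12, 25, 34, 40, 45, 48, 50, 51, 50, 48, 46, 44, 42, 40, 38],
    "anxiety":    [5, 12, 28, 45, 55, 58, 57, 54, 50, 46, 42, 38, 34, 30, 27, 24, 22],
    "bipolar":    [0.2, 0.8, 3, 6, 8, 9, 9, 8.5, 8, 7.5, 7, 6.5, 6, 5.5, 5, 4.5, 4],
    "epilepsy":   [7, 6.5, 6, 6, 6, 6, 6, 6, 6.5, 6.5, 7, 7, 7.5, 7.5, 8, 8, 8.5],
}
#: female-to-male rate ratios
_SEX_RATIOS = {"depression": 1.5, "anxiety": 1.6, "bipolar": 1.0, "epilepsy": 0.95}

#: share of prevalent cases each tier targets (basic = moderate cases in
#: primary care; intensive = severe cases referred on); the two depression
#: intensive packages split the severe pool between first-episode and
#: maintenance care
ELIGIBLE_FRACTIONS = {"basic": 0.50, "intensive": 0.30, "intensive_split": 0.15}

BASIC_COVERAGE = (40.0, 70.0)      # baseline → target, percent
INTENSIVE_COVERAGE = (1.0, 30.0)

_INTERVENTION_LAYOUT: list[tuple[str, str, str, float]] = [
    # (id, disorder, tier, eligible_fraction)
    ("anxiety_basic", "anxiety", "basic", ELIGIBLE_FRACTIONS["basic"]),
    ("anxiety_intensive", "anxiety", "intensive", ELIGIBLE_FRACTIONS["intensive"]),
    ("depression_basic", "depression", "basic", ELIGIBLE_FRACTIONS["basic"]),
    ("depression_intensive_first_episode", "depression", "intensive",
     ELIGIBLE_FRACTIONS["intensive_split"]),
    ("depression_intensive_maintenance", "depression", "intensive",
     ELIGIBLE_FRACTIONS["intensive_split"]),
    ("bipolar_intensive", "bipolar", "intensive", ELIGIBLE_FRACTIONS["intensive"]),
    ("epilepsy_basic", "epilepsy", "basic", ELIGIBLE_FRACTIONS["basic"]),
]

_ADULT_BANDS = AGE_BANDS[3:]  # 15+

# base pyramid: young-adult-heavy national age structure, summing to 1
_PYRAMID = np.array([
    6.9, 6.2, 5.6, 5.5, 6.5, 8.5, 9.8, 9.2, 7.8, 6.4,
    5.8, 5.2, 4.6, 3.8, 3.0, 2.2, 3.0,
])
_PYRAMID = _PYRAMID / _PYRAMID.sum()


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by weight (largest remainder): sums
    to ``total`` exactly and is deterministic in (total, weights)."""
    shares = weights / weights.sum() * total
    base = np.floor(shares).astype(np.int64)
    short = int(total - base.sum())
    if short:
        order = np.argsort(-(shares - base), kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_population(seed: int, n_years: int = END_YEAR - START_YEAR + 1,
                    base_total: int = BASE_TOTAL_POPULATION, *,
                    start_year: int = START_YEAR,
                    growth_rate: float = ANNUAL_GROWTH) -> pd.DataFrame:
    """Smooth 34-group age/sex pyramid with small annual growth.

    The first-year counts sum to ``base_total`` exactly (largest-remainder
    allocation); each later year's total is ``base_total × (1+g)^t`` rounded
    to a whole person and allocated with the same seeded weights.
    """
    if base_total <= 0:
        raise SchemaError("base_total must be positive")
    if n_years < 1:
        raise SchemaError("n_years must be >= 1")
    rng = _rng(seed, 1)
    jitter = rng.lognormal(0.0, 0.04, size=len(AGE_BANDS))
    band_w = _PYRAMID * jitter
    female_share = rng.uniform(0.48, 0.50, size=len(AGE_BANDS))
    weights = np.concatenate([band_w * female_share, band_w * (1 - female_share)])
    rows = []
    for t in range(n_years):
        total_t = int(round(base_total * (1.0 + growth_rate) ** t))
        counts = _allocate(total_t, weights)
        i = 0
        for sex in SEXES:
            for band in AGE_BANDS:
                rows.append({"year": start_year + t, "sex": sex,
                             "age_band": band, "count": int(counts[i])})
                i += 1
    return pd.DataFrame(rows)


def make_epi(seed: int, disorders: Iterable[str] = DISORDER_IDS) -> pd.DataFrame:
    """Per-1,000 prevalence/incidence with age/sex gradients and CI bounds.

    Every cell satisfies 0 ≤ lo ≤ point ≤ hi < 1000; CI half-widths are
    5–15% of the point value.  Incidence is a seeded fraction of prevalence
    (annual onsets in a mostly-chronic pool).
    """
    disorders = list(disorders)
    if not disorders:
        raise SchemaError("disorder list must be non-empty")
    rng = _rng(seed, 2)
    rows = []
    for disorder in disorders:
        if disorder not in _AGE_PROFILES:
            raise SchemaError(f"unknown disorder {disorder!r}")
        profile = np.asarray(_AGE_PROFILES[disorder], dtype=float)
        sex_ratio = _SEX_RATIOS[disorder]
        level = rng.uniform(0.9, 1.1)  # disorder-level scaling
        inc_frac = rng.uniform(0.15, 0.35)
        for sex in SEXES:
            sex_mult = sex_ratio if sex == "female" else 1.0
            # normalise so the two-sex mean stays on the template level
            sex_mult *= 2.0 / (1.0 + sex_ratio)
            cell_jit = rng.lognormal(0.0, 0.05, size=len(AGE_BANDS))
            prev = np.minimum(profile * level * sex_mult * cell_jit, 999.0)
            half_lo = rng.uniform(0.05, 0.15, size=len(AGE_BANDS))
            half_hi = rng.uniform(0.05, 0.15, size=len(AGE_BANDS))
            inc = prev * inc_frac
            for i, band in enumerate(AGE_BANDS):
                rows.append({
                    "disorder": disorder, "sex": sex, "age_band": band,
                    "prevalence_per_1000": prev[i],
                    "prev_lo": prev[i] * (1 - half_lo[i]),
                    "prev_hi": min(prev[i] * (1 + half_hi[i]), 999.9),
                    "incidence_per_1000": inc[i],
                    "inc_lo": inc[i] * (1 - half_lo[i]),
                    "inc_hi": min(inc[i] * (1 + half_hi[i]), 999.9),
                })
    return pd.DataFrame(rows)


def make_disorders(seed: int,
                   disorders: Iterable[str] = DISORDER_IDS) -> list[DisorderSpec]:
    """Disability weights drawn from disorder-specific plausible ranges."""
    rng = _rng(seed, 3)
    out = []
    for d in disorders:
        lo, hi = DISABILITY_WEIGHT_RANGES[d]
        out.append(DisorderSpec(id=d, name=d.replace("_", " "),
                                disability_weight=float(rng.uniform(lo, hi))))
    return out


def make_interventions(seed: int) -> list[InterventionSpec]:
    """The seven-package layout with seeded effect sizes."""
    rng = _rng(seed, 4)
    out = []
    for iv_id, disorder, tier, elig in _INTERVENTION_LAYOUT:
        baseline, target = BASIC_COVERAGE if tier == "basic" else INTENSIVE_COVERAGE
        out.append(InterventionSpec(
            id=iv_id, disorder=disorder, tier=tier,
            eligible_fraction=elig,
            effect_size=float(rng.uniform(*EFFECT_SIZE_RANGE)),
            baseline_coverage_pct=baseline, target_coverage_pct=target,
        ))
    return out


def make_costs(seed: int, interventions: list[InterventionSpec]
               ) -> tuple[dict[str, UnitCostProfile], ProgramCostProfile]:
    """Per-case unit-cost profiles plus the programme overhead profile.

    Basic-tier care is a few primary-care contacts plus generic medication;
    intensive-tier care multiplies both commodity spend and staff minutes,
    so cost(intensive) > cost(basic) for every disorder by construction.
    Salaries are 2020 rial per minute by cadre.
    """
    if not interventions:
        raise SchemaError("intervention list must be non-empty")
    rng = _rng(seed, 5)
    salary = {  # IRR per minute, seeded around 2020 public-sector levels
        "community_health_worker": rng.uniform(1200, 2000),
        "general_practitioner": rng.uniform(2500, 4500),
        "psychologist": rng.uniform(2200, 4000),
        "psychiatrist": rng.uniform(6000, 10000),
        "social_worker": rng.uniform(1500, 2600),
    }
    profiles: dict[str, UnitCostProfile] = {}
    # one basic reference profile per disorder; intensive scales it up
    basic_ref: dict[str, tuple[float, list[VisitCost]]] = {}
    for disorder in dict.fromkeys(iv.disorder for iv in interventions):
        commodity = rng.uniform(400_000, 900_000)  # IRR per case-year
        visits = [
            VisitCost(cadre="community_health_worker",
                      minutes_per_case_year=rng.uniform(60, 120),
                      salary_per_minute_irr=salary["community_health_worker"]),
            VisitCost(cadre="general_practitioner",
                      minutes_per_case_year=rng.uniform(30, 60),
                      salary_per_minute_irr=salary["general_practitioner"]),
            VisitCost(cadre="psychologist",
                      minutes_per_case_year=rng.uniform(45, 90),
                      salary_per_minute_irr=salary["psychologist"]),
        ]
        basic_ref[disorder] = (commodity, visits)
    for iv in interventions:
        commodity, visits = basic_ref[iv.disorder]
        if iv.tier == "basic":
            profiles[iv.id] = UnitCostProfile(
                intervention=iv.id, commodity_cost_irr=commodity,
                visits=list(visits))
        else:
            mult = rng.uniform(2.0, 3.5)
            scaled = [VisitCost(cadre=v.cadre,
                                minutes_per_case_year=v.minutes_per_case_year * mult,
                                salary_per_minute_irr=v.salary_per_minute_irr)
                      for v in visits]
            scaled.append(VisitCost(
                cadre="psychiatrist",
                minutes_per_case_year=rng.uniform(60, 150),
                salary_per_minute_irr=salary["psychiatrist"]))
            scaled.append(VisitCost(
                cadre="social_worker",
                minutes_per_case_year=rng.uniform(60, 180),
                salary_per_minute_irr=salary["social_worker"]))
            profiles[iv.id] = UnitCostProfile(
                intervention=iv.id, commodity_cost_irr=commodity * mult,
                visits=scaled)
    program = ProgramCostProfile(
        management_national_irr=rng.uniform(8e9, 16e9),
        management_provincial_irr=rng.uniform(0.6e9, 1.4e9),
        supervision_irr=rng.uniform(0.3e9, 0.8e9),
        training_irr=rng.uniform(0.4e9, 1.0e9),
    )
    return profiles, program


def geometric_mean_extrapolation(observed: Mapping[int, float],
                                 horizon_years: Iterable[int]) -> dict[int, float]:
    """Extend an inflation series: every horizon year gets the geometric
    mean of the observed (1 + r) factors, minus one.  A constant observed
    series therefore extrapolates to the same constant."""
    factors = np.array([1.0 + r for r in observed.values()], dtype=float)
    if np.any(factors <= 0):
        raise SchemaError("observed inflation rates must exceed -1")
    g = float(np.exp(np.log(factors).mean()) - 1.0)
    return {int(y): g for y in horizon_years}


def make_economics(seed: int = 0, *,
                   observed_inflation: Optional[Mapping[int, float]] = None,
                   horizon_years: Iterable[int] = range(START_YEAR, END_YEAR + 1),
                   exchange_rate_irr_per_usd: float = 194_881.0,
                   ppp_factor_intl_per_usd: float = 9.63,
                   gdp_per_capita_usd: float = 5550.0) -> EconomicSettings:
    """Observed 2010–2019 inflation plus geometric-mean extrapolated horizon
    rates; June-2020 exchange rate, PPP factor and GDP per capita populated.

    The defaults are deterministic study conditions; ``seed`` is accepted
    for interface symmetry with the other generators.
    """
    observed = dict(observed_inflation if observed_inflation is not None
                    else OBSERVED_INFLATION)
    inflation = dict(observed)
    inflation.update(geometric_mean_extrapolation(observed, horizon_years))
    return EconomicSettings(
        inflation=inflation,
        exchange_rate_irr_per_usd=exchange_rate_irr_per_usd,
        ppp_factor_intl_per_usd=ppp_factor_intl_per_usd,
        gdp_per_capita_usd=gdp_per_capita_usd,
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def make_bundle(seed: int, *, base_total: int = BASE_TOTAL_POPULATION,
                scenarios: Optional[list[ScenarioSpec]] = None) -> InputBundle:
    """Generate a complete in-memory input bundle ready for projection."""
    disorders = make_disorders(seed)
    interventions = make_interventions(seed)
    profiles, program = make_costs(seed, interventions)
    economics = make_economics(seed)
    config = ModelConfig(
        horizon_start=START_YEAR, horizon_end=END_YEAR,
        n_provinces=N_PROVINCES,
        population_csv=Path("population.csv"), epi_csv=Path("epi.csv"),
        unit_costs_csv=Path("unit_costs.csv"),
        economics_csv=Path("economics.csv"),
        disorders=disorders, interventions=interventions,
        program_costs=program,
        exchange_rate_irr_per_usd=economics.exchange_rate_irr_per_usd,
        ppp_factor_intl_per_usd=economics.ppp_factor_intl_per_usd,
        gdp_per_capita_usd=economics.gdp_per_capita_usd,
        scenarios=scenarios if scenarios is not None else default_scenarios(),
    )
    return InputBundle(
        config=config,
        population=make_population(seed, base_total=base_total),
        epi=make_epi(seed, [d.id for d in disorders]),
        unit_costs=profiles,
        economics=economics,
    )


def write_bundle(outdir: str | Path, seed: int = 0, *,
                 base_total: int = BASE_TOTAL_POPULATION) -> dict[str, Path]:
    """Write a synthetic bundle (four CSV tables + config.yaml) to disk.

    The written config passes :func:`mhscaleup.config_io.load_config`
    validation and supports an end-to-end run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle(seed, base_total=base_total)
    paths = {
        "population": outdir / "population.csv",
        "epi": outdir / "epi.csv",
        "unit_costs": outdir / "unit_costs.csv",
        "economics": outdir / "economics.csv",
        "config": outdir / "config.yaml",
    }
    bundle.population.to_csv(paths["population"], index=False)
    bundle.epi.to_csv(paths["epi"], index=False)
    unit_cost_profiles_to_frame(bundle.unit_costs).to_csv(
        paths["unit_costs"], index=False)
    econ_rows = [{"year": y, "inflation_rate": r}
                 for y, r in sorted(bundle.economics.inflation.items())]
    pd.DataFrame(econ_rows).to_csv(paths["economics"], index=False)

    cfg = bundle.config
    doc = {
        "horizon_start": cfg.horizon_start,
        "horizon_end": cfg.horizon_end,
        "country_label": cfg.country_label,
        "currency_local": cfg.currency_local,
        "n_provinces": cfg.n_provinces,
        "population_csv": "population.csv",
        "epi_csv": "epi.csv",
        "unit_costs_csv": "unit_costs.csv",
        "economics_csv": "economics.csv",
        "exchange_rate_irr_per_usd": cfg.exchange_rate_irr_per_usd,
        "ppp_factor_intl_per_usd": cfg.ppp_factor_intl_per_usd,
        "gdp_per_capita_usd": cfg.gdp_per_capita_usd,
        "disorders": [d.model_dump() for d in cfg.disorders],
        "interventions": [iv.model_dump() for iv in cfg.interventions],
        "program_costs": cfg.program_costs.model_dump(),
        "scenarios": [s.model_dump() for s in cfg.scenarios],
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return paths
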
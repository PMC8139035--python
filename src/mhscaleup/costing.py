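"""Three-component costing with inflation and currency conversion.

Annual costs are booked in three rows, mirroring the programme's budget
structure:

* **intervention costs** — drugs and supplies (commodity spend) per treated
  case-year;
* **labor costs** — delivery-staff time: Σ over cadres of outpatient-visit
  minutes × per-minute salary, per treated case-year;
* **program costs** — national/provincial management, supervision visits and
  training, independent of caseload.

Unit costs are denominated in Iranian rial at the horizon-start price level
and inflated with the compound inflation series; conversion to USD and
PPP-adjusted international dollars happens only when reporting.  All cost
cells are integer rials (rounded half-up once per cell), which makes the
per-year and horizon conservation identities exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .caseload import CaseloadSeries
from .config_io import (
    EconomicSettings,
    ProgramCostProfile,
    SchemaError,
    UnitCostProfile,
    round_half_up,
)


def inflate(amount: float, base_year: int, target_year: int,
            inflation_series: Mapping[int, float]) -> float:
    """Compound ``amount`` forward: × Π (1 + r_y) over (base, target].

    Identity when the years are equal.  Deflating backwards divides by the
    same product.
    """
    if base_year == target_year:
        return amount
    lo, hi = sorted((base_year, target_year))
    factor = 1.0
    for year in range(lo + 1, hi + 1):
        if year not in inflation_series:
            raise SchemaError(f"inflation series missing year {year}")
        factor *= 1.0 + inflation_series[year]
    return amount * factor if target_year > base_year else amount / factor


def intervention_cost(treated_cases: int, profile: UnitCostProfile, year: int,
                      economics: EconomicSettings, base_year: int) -> int:
    """Commodity spend (rial) for one intervention-year, inflated."""
    unit = inflate(profile.commodity_cost_irr, base_year, year,
                   economics.inflation)
    return round_half_up(treated_cases * unit)


def labor_cost(treated_cases: int, profile: UnitCostProfile, year: int,
               economics: EconomicSettings, base_year: int) -> int:
    """Staff-time spend (rial): treated × Σ minutes × salary/min, inflated."""
    unit = inflate(profile.labor_cost_per_case_irr, base_year, year,
                   economics.inflation)
    return round_half_up(treated_cases * unit)


def program_cost(profile: ProgramCostProfile, year: int,
                 economics: EconomicSettings, base_year: int,
                 n_provinces: int) -> int:
    """Management + supervision + training overhead (rial) for one year."""
    if n_provinces < 1:
        raise SchemaError("n_provinces must be >= 1")
    annual = profile.annual_total_irr(n_provinces)
    return round_half_up(inflate(annual, base_year, year, economics.inflation))


@dataclass
class CostSeries:
    """Annual cost rows (integer rial) with exact conservation totals."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    base_year: int = 2020
    per_capita_usd: float | None = None

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.table["year"]]

    def component_total_irr(self, component: str) -> int:
        return int(self.table[f"{component}_irr"].sum())

    @property
    def total_irr(self) -> int:
        return int(self.table["total_irr"].sum())


def build_costs(
    caseloads: CaseloadSeries,
    profiles: Mapping[str, UnitCostProfile],
    program_profile: ProgramCostProfile,
    economics: EconomicSettings,
    *,
    base_year: int | None = None,
    n_provinces: int = 31,
    population_start_total: int | None = None,
) -> CostSeries:
    """Assemble the full cost series over the horizon.

    Per-year totals are formed by integer addition of the three component
    cells, so ``total = intervention + program + labor`` holds exactly, as
    does ``horizon total = Σ years``.  ``population_start_total`` (horizon-
    start population) enables the approximate per-capita USD figure.
    """
    years = sorted({int(y) for df in caseloads.frames.values()
                    for y in df["year"]})
    if not years:
        raise SchemaError("caseload series is empty")
    if base_year is None:
        base_year = years[0]
    rows = []
    for year in years:
        iv_total = 0
        lab_total = 0
        for iv_id, frame in caseloads.frames.items():
            if iv_id not in profiles:
                raise SchemaError(f"no unit-cost profile for {iv_id!r}")
            treated = int(frame.loc[frame["year"] == year,
                                    "treated_cases"].iloc[0])
            iv_total += intervention_cost(treated, profiles[iv_id], year,
                                          economics, base_year)
            lab_total += labor_cost(treated, profiles[iv_id], year,
                                    economics, base_year)
        prog = program_cost(program_profile, year, economics, base_year,
                            n_provinces)
        rows.append({
            "year": year,
            "intervention_irr": iv_total,
            "program_irr": prog,
            "labor_irr": lab_total,
            "total_irr": iv_total + prog + lab_total,
        })
    table = pd.DataFrame(rows)
    series = CostSeries(table=table, base_year=base_year)
    if population_start_total:
        total_usd = convert(series.total_irr, economics, "USD")
        series.per_capita_usd = total_usd / population_start_total
    return series


def convert(amount_local: float, economics: EconomicSettings,
            unit: Literal["USD", "IntlD"], *, year: int | None = None) -> float:
    """Convert rial to USD (divide by exchange rate) or Intl$ (× PPP factor).

    With ``year`` given and a per-year exchange series configured, that
    year's rate is used; otherwise the single fixed study rate applies.
    """
    rate = (economics.exchange_rate_for(year) if year is not None
            else economics.exchange_rate_irr_per_usd)
    if rate <= 0 or economics.ppp_factor_intl_per_usd <= 0:
        raise SchemaError("conversion factors must be positive")
    usd = amount_local / rate
    if unit == "USD":
        return usd
    if unit == "IntlD":
        return usd * economics.ppp_factor_intl_per_usd
    raise SchemaError(f"unknown currency unit {unit!r}")


def cost_table_usd(series: CostSeries, economics: EconomicSettings) -> pd.DataFrame:
    """Report-time USD view of a rial cost table (whole dollars, half-up)."""
    out = pd.DataFrame({"year": series.table["year"]})
    for comp in ("intervention", "program", "labor", "total"):
        out[f"{comp}_usd"] = [
            round_half_up(convert(v, economics, "USD"))
            for v in series.table[f"{comp}_irr"]
        ]
    return out
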
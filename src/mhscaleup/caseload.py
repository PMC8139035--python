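"""Treated caseloads: population × prevalence × eligibility × coverage.

Caseloads are prevalence-based: the number of cases eligible for an
intervention in a year is the prevalent pool times the intervention's
eligible fraction, and the treated count applies that year's coverage.
Prevalence rates are held at their input values across the horizon (no
treatment feedback); the health gain of scale-up is booked by the impact
module, not by shrinking the epidemiological pool.

Rounding convention: group-level products stay at full precision; counts
are rounded half-up to whole persons only at the (disorder | intervention,
year) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .config_io import (
    AGE_BANDS,
    SEXES,
    InterventionSpec,
    SchemaError,
    round_half_up,
)
from .coverage import CoverageTrajectory

#: epi column carrying the rate actually used; scenarios swap this in
RATE_COLUMN = "prevalence_per_1000"


@dataclass
class CaseloadSeries:
    """Per-intervention annual case counts.

    ``frames`` maps intervention id → DataFrame with columns ``year``,
    ``prevalent_cases``, ``eligible_cases``, ``treated_cases``,
    ``treated_above_baseline`` (all whole persons; treated ≤ eligible ≤
    prevalent in every row).
    """

    frames: dict[str, pd.DataFrame] = field(default_factory=dict)

    def frame(self, intervention: str) -> pd.DataFrame:
        return self.frames[intervention]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for iv, df in self.frames.items():
            part = df.copy()
            part.insert(0, "intervention", iv)
            parts.append(part)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["intervention", "year", "prevalent_cases", "eligible_cases",
                     "treated_cases", "treated_above_baseline"])


def prevalent_cases(pop: pd.DataFrame, epi: pd.DataFrame, disorder: str,
                    year: int, *, rate_column: str = RATE_COLUMN,
                    rounded: bool = True) -> float:
    """Prevalent cases of ``disorder`` in ``year``.

    Σ over the 34 age/sex groups of count(g) × rate(g)/1000, accumulated at
    full precision and rounded half-up once at the disorder-year level.
    """
    pop_y = pop[pop["year"] == year]
    if pop_y.empty:
        raise SchemaError(f"population table has no rows for year {year}")
    rates = epi[epi["disorder"] == disorder]
    if rates.empty:
        raise SchemaError(f"epi table has no rows for disorder {disorder!r}")
    rate_map = {(s, b): r for s, b, r in
                zip(rates["sex"], rates["age_band"], rates[rate_column])}
    missing = [(s, b) for s in SEXES for b in AGE_BANDS if (s, b) not in rate_map]
    if missing:
        raise SchemaError(
            f"epi table for {disorder!r} missing groups: {missing[:4]}...")
    terms = [
        float(cnt) * float(rate_map[(sex, band)]) / 1000.0
        for sex, band, cnt in zip(pop_y["sex"], pop_y["age_band"], pop_y["count"])
    ]
    total = math.fsum(terms)
    return round_half_up(total) if rounded else total


def treated_cases(prevalent: float, eligible_fraction: float,
                  coverage_pct: float, *, rounded: bool = True) -> float:
    """prevalent × eligible_fraction × coverage/100, rounded half-up."""
    if not 0 <= coverage_pct <= 100:
        raise SchemaError(f"coverage_pct out of range: {coverage_pct}")
    if not 0 < eligible_fraction <= 1:
        raise SchemaError(f"eligible_fraction out of range: {eligible_fraction}")
    value = prevalent * eligible_fraction * coverage_pct / 100.0
    return round_half_up(value) if rounded else value


def build_series(
    pop: pd.DataFrame,
    epi: pd.DataFrame,
    interventions: list[InterventionSpec],
    trajectories: Mapping[str, CoverageTrajectory],
    *,
    rate_column: str = RATE_COLUMN,
) -> CaseloadSeries:
    """Assemble the full caseload series over years × interventions.

    ``treated_above_baseline`` applies the intervention's baseline coverage
    to the same year's eligible pool and subtracts (floored at zero), so it
    is identically zero in the first horizon year, where the trajectory
    starts at baseline.
    """
    years = sorted(pop["year"].unique())
    series = CaseloadSeries()
    prevalent_cache: dict[tuple[str, int], int] = {}
    for iv in interventions:
        traj = trajectories.get(iv.id)
        if traj is None:
            raise SchemaError(f"no trajectory for intervention {iv.id!r}")
        if list(traj.years) != [int(y) for y in years]:
            raise SchemaError(
                f"trajectory horizon mismatch for {iv.id!r}: "
                f"{traj.years[0]}–{traj.years[-1]} vs {years[0]}–{years[-1]}")
        rows = []
        for year in years:
            key = (iv.disorder, int(year))
            if key not in prevalent_cache:
                prevalent_cache[key] = int(prevalent_cases(
                    pop, epi, iv.disorder, int(year), rate_column=rate_column))
            prev = prevalent_cache[key]
            eligible = round_half_up(prev * iv.eligible_fraction)
            treated = int(treated_cases(prev, iv.eligible_fraction,
                                        traj.percent_for(int(year))))
            at_baseline = int(treated_cases(prev, iv.eligible_fraction,
                                            iv.baseline_coverage_pct))
            rows.append({
                "year": int(year),
                "prevalent_cases": prev,
                "eligible_cases": eligible,
                "treated_cases": treated,
                "treated_above_baseline": max(0, treated - at_baseline),
            })
        series.frames[iv.id] = pd.DataFrame(rows)
    return series
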
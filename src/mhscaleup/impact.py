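"""Healthy life years gained from coverage scale-up.

Each treated case-year *above baseline coverage* averts
``disability_weight × effect_size`` of a year lived with disability, so

    HLY(d, t) = Σ_{i ∈ interventions(d)} treated_above_baseline(i, t)
                × DW(d) × effect_size(i)

Healthy life years gained are equivalent to DALYs averted under this
accounting.  A full year of averted disability is credited within the
calendar year of treatment (no half-year correction), sums are undiscounted
by default, and mortality-mediated gains are folded into the effect size
rather than modelled through life tables.  A discount-rate hook exists for
sensitivity use but defaults to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .caseload import CaseloadSeries
from .config_io import DisorderSpec, InterventionSpec, SchemaError


def hly_gained(treated_above_baseline: float, disability_weight: float,
               effect_size: float) -> float:
    """Healthy life years gained by one intervention in one year."""
    if treated_above_baseline < 0:
        raise SchemaError("treated_above_baseline must be >= 0")
    if not 0 <= disability_weight <= 1 or not 0 <= effect_size <= 1:
        raise SchemaError("disability_weight and effect_size must lie in [0, 1]")
    return treated_above_baseline * disability_weight * effect_size


@dataclass
class ImpactSeries:
    """Per-disorder annual healthy-life-year gains plus exact totals."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["disorder", "year", "healthy_ly"]))

    def by_disorder(self) -> dict[str, float]:
        return {
            str(d): math.fsum(grp["healthy_ly"])
            for d, grp in self.table.groupby("disorder", sort=False)
        }

    def by_year(self) -> dict[int, float]:
        return {
            int(y): math.fsum(grp["healthy_ly"])
            for y, grp in self.table.groupby("year", sort=True)
        }

    def total(self) -> float:
        return math.fsum(self.table["healthy_ly"])


def build_impact(
    caseloads: CaseloadSeries,
    disorders: list[DisorderSpec],
    interventions: list[InterventionSpec],
    *,
    discount_rate: float = 0.0,
) -> ImpactSeries:
    """Per-disorder yearly HLY sums over that disorder's interventions.

    With a non-zero ``discount_rate`` each year's gain is divided by
    ``(1 + r)**t`` (t = years since horizon start); the default of zero
    reproduces plain undiscounted sums.
    """
    dw = {d.id: d.disability_weight for d in disorders}
    for iv in interventions:
        if iv.disorder not in dw:
            raise SchemaError(
                f"intervention {iv.id!r} references unknown disorder "
                f"{iv.disorder!r}")
    acc: dict[tuple[str, int], float] = {}
    start_year = None
    for iv in interventions:
        frame = caseloads.frame(iv.id)
        if start_year is None and len(frame):
            start_year = int(frame["year"].min())
        for year, above in zip(frame["year"], frame["treated_above_baseline"]):
            gain = hly_gained(float(above), dw[iv.disorder], iv.effect_size)
            if discount_rate:
                gain /= (1.0 + discount_rate) ** (int(year) - start_year)
            key = (iv.disorder, int(year))
            acc[key] = acc.get(key, 0.0) + gain
    rows = [{"disorder": d, "year": y, "healthy_ly": v}
            for (d, y), v in sorted(acc.items())]
    return ImpactSeries(table=pd.DataFrame(
        rows, columns=["disorder", "year", "healthy_ly"]))


def summarize_impact(series: ImpactSeries) -> dict:
    """Exact totals: overall and per disorder (fsum; order-independent)."""
    return {"total_hly": series.total(), "by_disorder": series.by_disorder()}
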
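"""Independent brute-force implementations used as oracles.

Written directly from the accounting identities with plain Python loops
over (year × group × intervention); no pandas grouping, no shared code with
the package's pipeline beyond the documented rounding convention.
"""

import math


def round_half_up(x):
    return int(math.floor(x + 0.5))


def prevalent_by_disorder_year(pop_df, epi_df, disorder, year,
                               rate_column="prevalence_per_1000"):
    """Full-precision group-by-group accumulation (no rounding)."""
    rates = {}
    for _, r in epi_df[epi_df["disorder"] == disorder].iterrows():
        rates[(r["sex"], r["age_band"])] = float(r[rate_column])
    terms = []
    for _, r in pop_df[pop_df["year"] == year].iterrows():
        terms.append(float(r["count"]) * rates[(r["sex"], r["age_band"])] / 1000.0)
    return math.fsum(terms)


def caseload_oracle(pop_df, epi_df, interventions, trajectories):
    """Triple loop over year × group × intervention.

    Returns {intervention: {year: (prevalent, treated, above_baseline)}}
    using the documented rounding levels (half-up at the
    disorder/intervention-year level only).
    """
    years = sorted(set(int(y) for y in pop_df["year"]))
    out = {}
    for iv in interventions:
        traj = trajectories[iv.id]
        per_year = {}
        for year in years:
            exact = prevalent_by_disorder_year(pop_df, epi_df, iv.disorder, year)
            prevalent = round_half_up(exact)
            cov = traj.percent_for(year)
            treated = round_half_up(prevalent * iv.eligible_fraction * cov / 100.0)
            at_base = round_half_up(
                prevalent * iv.eligible_fraction * iv.baseline_coverage_pct / 100.0)
            per_year[year] = (prevalent, treated, max(0, treated - at_base))
        out[iv.id] = per_year
    return out


def impact_oracle(caseload_by_iv, disorders, interventions):
    """Independent double loop: {(disorder, year): healthy LYs}."""
    dw = {d.id: d.disability_weight for d in disorders}
    acc = {}
    for iv in interventions:
        for year, (_, _, above) in caseload_by_iv[iv.id].items():
            key = (iv.disorder, year)
            acc.setdefault(key, []).append(above * dw[iv.disorder] * iv.effect_size)
    return {k: math.fsum(v) for k, v in acc.items()}


def inflation_factor(inflation, base_year, year):
    f = 1.0
    for y in range(base_year + 1, year + 1):
        f *= 1.0 + inflation[y]
    return f


def cost_oracle(caseload_by_iv, profiles, program_profile, inflation,
                base_year, n_provinces):
    """Per-year component costs (integer rial), cadre-by-cadre."""
    years = sorted(next(iter(caseload_by_iv.values())).keys())
    rows = {}
    for year in years:
        f = inflation_factor(inflation, base_year, year)
        iv_cost = 0
        labor = 0
        for iv_id, per_year in caseload_by_iv.items():
            treated = per_year[year][1]
            prof = profiles[iv_id]
            iv_cost += round_half_up(treated * (prof.commodity_cost_irr * f))
            per_case = math.fsum(v.minutes_per_case_year * v.salary_per_minute_irr
                                 for v in prof.visits)
            labor += round_half_up(treated * (per_case * f))
        annual = (program_profile.management_national_irr
                  + n_provinces * (program_profile.management_provincial_irr
                                   + program_profile.supervision_irr
                                   + program_profile.training_irr))
        prog = round_half_up(annual * f)
        rows[year] = (iv_cost, prog, labor, iv_cost + prog + labor)
    return rows
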
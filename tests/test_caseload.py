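"""Caseload accounting: prevalence products, rounding levels, invariants."""

import math

import pandas as pd
import pytest

import mhscaleup as m
from mhscaleup.caseload import prevalent_cases, treated_cases
from mhscaleup.config_io import AGE_BANDS, SEXES, SchemaError

import oracles


def _single_group_inputs(pop_count, prevalence):
    """Population concentrated in one group; all other groups zero."""
    pop_rows, epi_rows = [], []
    for sex in SEXES:
        for band in AGE_BANDS:
            first = sex == "female" and band == "0-4"
            pop_rows.append({"year": 2020, "sex": sex, "age_band": band,
                             "count": pop_count if first else 0})
            rate = prevalence if first else 0.0
            epi_rows.append({"disorder": "depression", "sex": sex,
                             "age_band": band,
                             "prevalence_per_1000": rate,
                             "prev_lo": rate, "prev_hi": rate,
                             "incidence_per_1000": 0.0,
                             "inc_lo": 0.0, "inc_hi": 0.0})
    return pd.DataFrame(pop_rows), pd.DataFrame(epi_rows)


class TestPrevalentCases:
    def test_single_group_product(self):
        pop, epi = _single_group_inputs(100_000, 50.0)
        assert prevalent_cases(pop, epi, "depression", 2020) == 5_000

    def test_zero_prevalence_everywhere(self):
        pop, epi = _single_group_inputs(100_000, 0.0)
        assert prevalent_cases(pop, epi, "depression", 2020) == 0

    def test_missing_group_rejected(self):
        pop, epi = _single_group_inputs(1000, 10.0)
        epi = epi.iloc[:-1]
        with pytest.raises(SchemaError):
            prevalent_cases(pop, epi, "depression", 2020)

    def test_matches_group_accumulation_oracle(self, bundle):
        """Fixture depression 2020 equals a full-precision per-group sum
        rounded once at the disorder-year level."""
        exact = oracles.prevalent_by_disorder_year(
            bundle.population, bundle.epi, "depression", 2020)
        assert prevalent_cases(bundle.population, bundle.epi,
                               "depression", 2020) == oracles.round_half_up(exact)
        full = prevalent_cases(bundle.population, bundle.epi, "depression",
                               2020, rounded=False)
        assert full == pytest.approx(exact, abs=1e-6)


class TestTreatedCases:
    @pytest.mark.parametrize("prev,elig,cov,expected", [
        (10_000, 1.0, 40.0, 4_000),
        (10_000, 1.0, 0.0, 0),
        (5_000, 0.3, 12.6, 189),
    ])
    def test_direct_products(self, prev, elig, cov, expected):
        assert treated_cases(prev, elig, cov) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(SchemaError):
            treated_cases(100, 1.0, 101.0)
        with pytest.raises(SchemaError):
            treated_cases(100, 0.0, 50.0)


class TestBuildSeries:
    def test_invariants_hold_everywhere(self, caseloads):
        for iv_id, df in caseloads.frames.items():
            assert (df["treated_cases"] <= df["eligible_cases"]).all(), iv_id
            assert (df["eligible_cases"] <= df["prevalent_cases"]).all(), iv_id
            assert (df["treated_above_baseline"] >= 0).all()

    def test_first_year_above_baseline_is_zero(self, caseloads):
        for df in caseloads.frames.values():
            first = df.loc[df["year"] == df["year"].min()]
            assert (first["treated_above_baseline"] == 0).all()

    def test_flat_trajectories_give_zero_above_baseline(self, bundle):
        flat = {
            iv.id: m.interpolate(iv.baseline_coverage_pct,
                                 iv.baseline_coverage_pct,
                                 len(bundle.years) - 1, "linear",
                                 intervention=iv.id,
                                 start_year=bundle.years[0])
            for iv in bundle.interventions
        }
        series = m.build_series(bundle.population, bundle.epi,
                                bundle.interventions, flat)
        for df in series.frames.values():
            assert (df["treated_above_baseline"] == 0).all()

    def test_population_doubling_doubles_caseloads_pre_rounding(self, bundle):
        pop2 = bundle.population.copy()
        pop2["count"] *= 2
        before = prevalent_cases(bundle.population, bundle.epi, "anxiety",
                                 2025, rounded=False)
        after = prevalent_cases(pop2, bundle.epi, "anxiety", 2025,
                                rounded=False)
        assert after == pytest.approx(2 * before, rel=1e-12)

    def test_coverage_monotonicity(self, bundle):
        """Raising one year's coverage never lowers that year's treated count."""
        iv = bundle.interventions[0]
        base = m.interpolate(iv.baseline_coverage_pct, iv.target_coverage_pct,
                             len(bundle.years) - 1, "linear",
                             intervention=iv.id, start_year=bundle.years[0])
        bumped_pcts = list(base.percents)
        bumped_pcts[5] = min(100.0, bumped_pcts[5] + 4.0)
        bumped_pcts = [max(bumped_pcts[: i + 1]) for i in range(len(bumped_pcts))]
        bumped = m.from_table(dict(zip(base.years, bumped_pcts)),
                              intervention=iv.id)
        s1 = m.build_series(bundle.population, bundle.epi, [iv], {iv.id: base})
        s2 = m.build_series(bundle.population, bundle.epi, [iv], {iv.id: bumped})
        assert (s2.frame(iv.id)["treated_cases"]
                >= s1.frame(iv.id)["treated_cases"]).all()

    def test_horizon_mismatch_rejected(self, bundle):
        iv = bundle.interventions[0]
        short = m.interpolate(iv.baseline_coverage_pct, iv.target_coverage_pct,
                              3, "linear", intervention=iv.id,
                              start_year=bundle.years[0])
        with pytest.raises(SchemaError):
            m.build_series(bundle.population, bundle.epi, [iv], {iv.id: short})
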
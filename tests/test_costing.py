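"""Costing: inflation, component assembly, conservation, conversion."""

import math

import pytest

import mhscaleup as m
from mhscaleup.config_io import (
    EconomicSettings,
    ProgramCostProfile,
    SchemaError,
    UnitCostProfile,
    VisitCost,
)
from mhscaleup.costing import (
    intervention_cost,
    labor_cost,
    program_cost,
    cost_table_usd,
)

import oracles


def _econ(rate=0.0, years=range(2019, 2032)):
    return EconomicSettings(inflation={y: rate for y in years})


class TestInflate:
    def test_identity_when_years_equal(self):
        assert m.inflate(12345.0, 2025, 2025, {}) == 12345.0

    def test_compound_two_years_at_ten_percent(self):
        out = m.inflate(100.0, 2020, 2022, {2021: 0.10, 2022: 0.10})
        assert out == pytest.approx(121.0)

    def test_zero_series_is_identity_over_any_span(self):
        series = {y: 0.0 for y in range(2020, 2031)}
        assert m.inflate(777.0, 2020, 2030, series) == pytest.approx(777.0)

    def test_missing_year_rejected(self):
        with pytest.raises(SchemaError):
            m.inflate(1.0, 2020, 2025, {2021: 0.1})


class TestComponentCosts:
    def test_zero_treated_costs_nothing(self):
        prof = UnitCostProfile(intervention="x", commodity_cost_irr=50_000)
        assert intervention_cost(0, prof, 2025, _econ(), 2020) == 0

    def test_commodity_product_without_inflation(self):
        prof = UnitCostProfile(intervention="x", commodity_cost_irr=50_000)
        assert intervention_cost(1_000, prof, 2025, _econ(), 2020) == 50_000_000

    def test_single_cadre_labor_product(self):
        prof = UnitCostProfile(
            intervention="x", commodity_cost_irr=0,
            visits=[VisitCost(cadre="gp", minutes_per_case_year=30,
                              salary_per_minute_irr=2_000)])
        assert labor_cost(100, prof, 2025, _econ(), 2020) == 6_000_000

    def test_zero_minutes_everywhere_is_free(self):
        prof = UnitCostProfile(intervention="x", commodity_cost_irr=0)
        assert labor_cost(10_000, prof, 2030, _econ(), 2020) == 0

    def test_zero_program_profile_costs_nothing(self):
        assert program_cost(ProgramCostProfile(), 2025, _econ(), 2020, 31) == 0

    def test_constant_program_profile_flat_without_inflation(self):
        prof = ProgramCostProfile(management_national_irr=1e9,
                                  supervision_irr=1e7)
        vals = {y: program_cost(prof, y, _econ(), 2020, 31)
                for y in range(2020, 2031)}
        assert len(set(vals.values())) == 1


class TestBuildCosts:
    def test_matches_cadre_by_cadre_oracle(self, bundle, caseloads,
                                           trajectories, base_run):
        costs = base_run[0]
        loads = oracles.caseload_oracle(bundle.population, bundle.epi,
                                        bundle.interventions, trajectories)
        expected = oracles.cost_oracle(
            loads, bundle.unit_costs, bundle.config.program_costs,
            bundle.economics.inflation, bundle.years[0],
            bundle.config.n_provinces)
        for _, row in costs.table.iterrows():
            exp = expected[int(row["year"])]
            assert (row["intervention_irr"], row["program_irr"],
                    row["labor_irr"], row["total_irr"]) == exp

    def test_conservation_exact_integer_identities(self, base_run):
        costs = base_run[0]
        t = costs.table
        assert (t["total_irr"] == t["intervention_irr"] + t["program_irr"]
                + t["labor_irr"]).all()
        assert costs.total_irr == int(t["total_irr"].sum())
        assert costs.total_irr == (costs.component_total_irr("intervention")
                                   + costs.component_total_irr("program")
                                   + costs.component_total_irr("labor"))

    def test_homogeneity_in_unit_costs(self, bundle, caseloads):
        doubled = {}
        for iv_id, prof in bundle.unit_costs.items():
            doubled[iv_id] = UnitCostProfile(
                intervention=iv_id,
                commodity_cost_irr=prof.commodity_cost_irr * 2,
                visits=[VisitCost(cadre=v.cadre,
                                  minutes_per_case_year=v.minutes_per_case_year,
                                  salary_per_minute_irr=v.salary_per_minute_irr * 2)
                        for v in prof.visits])
        pp = bundle.config.program_costs
        pp2 = ProgramCostProfile(
            management_national_irr=pp.management_national_irr * 2,
            management_provincial_irr=pp.management_provincial_irr * 2,
            supervision_irr=pp.supervision_irr * 2,
            training_irr=pp.training_irr * 2)
        c1 = m.build_costs(caseloads, bundle.unit_costs, pp, bundle.economics,
                           n_provinces=bundle.config.n_provinces)
        c2 = m.build_costs(caseloads, doubled, pp2, bundle.economics,
                           n_provinces=bundle.config.n_provinces)
        # per-cell half-up rounding can differ by ±1 rial between the two runs
        n_cells = len(c1.table) * (2 * len(bundle.unit_costs) + 1)
        assert c2.total_irr == pytest.approx(2 * c1.total_irr, abs=n_cells)

    def test_zero_caseloads_leave_only_program_row(self, bundle):
        flat = {
            iv.id: m.interpolate(0, 0, len(bundle.years) - 1, "linear",
                                 intervention=iv.id, start_year=bundle.years[0])
            for iv in bundle.interventions
        }
        zero_elig = [iv.model_copy(update={"baseline_coverage_pct": 0.0,
                                           "target_coverage_pct": 0.0})
                     for iv in bundle.interventions]
        series = m.build_series(bundle.population, bundle.epi, zero_elig, flat)
        costs = m.build_costs(series, bundle.unit_costs,
                              bundle.config.program_costs, bundle.economics,
                              n_provinces=bundle.config.n_provinces)
        assert (costs.table["intervention_irr"] == 0).all()
        assert (costs.table["labor_irr"] == 0).all()
        assert (costs.table["total_irr"] == costs.table["program_irr"]).all()


class TestConvert:
    def test_default_rate_turns_194881_rial_into_one_dollar(self):
        econ = _econ()
        assert m.convert(194_881, econ, "USD") == pytest.approx(1.0)

    def test_unit_exchange_rate_is_identity(self):
        econ = EconomicSettings(inflation={}, exchange_rate_irr_per_usd=1.0)
        assert m.convert(42.0, econ, "USD") == 42.0

    def test_round_trip_within_one_minor_unit(self):
        econ = _econ()
        amount = 123_456_789
        usd = m.convert(amount, econ, "USD")
        assert usd * econ.exchange_rate_irr_per_usd == pytest.approx(amount, abs=1)

    def test_intl_dollars_apply_ppp_factor(self):
        econ = _econ()
        usd = m.convert(194_881, econ, "USD")
        intl = m.convert(194_881, econ, "IntlD")
        assert intl == pytest.approx(usd * econ.ppp_factor_intl_per_usd)

    def test_usd_view_of_cost_table_is_conserved_to_rounding(self, base_run):
        costs = base_run[0]
        usd = cost_table_usd(costs, _econ())
        resid = (usd["total_usd"] - usd["intervention_usd"] - usd["program_usd"]
                 - usd["labor_usd"]).abs()
        assert (resid <= 2).all()  # independent half-up rounding of 4 cells
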
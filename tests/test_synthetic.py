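"""Synthetic-data generator contracts: reproducibility, structure, ranges."""

import math

import numpy as np
import pandas as pd
import pytest

import mhscaleup as m
from mhscaleup.config_io import SchemaError
from mhscaleup.synthetic_data import (
    ADULT_PREV_WINDOWS,
    _ADULT_BANDS,
    geometric_mean_extrapolation,
    make_disorders,
    make_interventions,
)


class TestMakePopulation:
    def test_first_year_total_is_exact(self):
        pop = m.make_population(seed=1, base_total=83_000_000)
        assert pop.loc[pop["year"] == 2020, "count"].sum() == 83_000_000

    def test_same_seed_reproduces_table(self):
        a = m.make_population(seed=5)
        b = m.make_population(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_growth_keeps_totals_constant(self):
        pop = m.make_population(seed=2, growth_rate=0.0)
        totals = pop.groupby("year")["count"].sum()
        assert totals.nunique() == 1

    def test_34_groups_per_year(self):
        pop = m.make_population(seed=1, n_years=3)
        assert (pop.groupby("year").size() == 34).all()

    def test_nonpositive_total_rejected(self):
        with pytest.raises(SchemaError):
            m.make_population(seed=1, base_total=0)


class TestMakeEpi:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_ci_bounds_bracket_point_everywhere(self, seed):
        epi = m.make_epi(seed)
        assert (epi["prev_lo"] <= epi["prevalence_per_1000"]).all()
        assert (epi["prevalence_per_1000"] <= epi["prev_hi"]).all()
        assert (epi["inc_lo"] <= epi["incidence_per_1000"]).all()
        assert (epi["incidence_per_1000"] <= epi["inc_hi"]).all()
        assert (epi["prev_hi"] < 1000).all()
        assert (epi[["prev_lo", "inc_lo"]] >= 0).all().all()

    def test_single_disorder_has_34_rows(self):
        epi = m.make_epi(1, ["epilepsy"])
        assert len(epi) == 34

    def test_adult_prevalence_inside_declared_window(self):
        """Population-weighted adult prevalence recomputed from the emitted
        tables lands in the window the generator itself declares."""
        pop = m.make_population(seed=1)
        epi = m.make_epi(seed=1)
        pop20 = pop[(pop["year"] == 2020) & pop["age_band"].isin(_ADULT_BANDS)]
        for disorder, (lo, hi) in ADULT_PREV_WINDOWS.items():
            sub = epi[epi["disorder"] == disorder]
            rate = {(s, b): r for s, b, r in zip(
                sub["sex"], sub["age_band"], sub["prevalence_per_1000"])}
            weighted = math.fsum(
                c * rate[(s, b)] for s, b, c in zip(
                    pop20["sex"], pop20["age_band"], pop20["count"])
            ) / pop20["count"].sum()
            assert lo <= weighted <= hi, disorder

    def test_depression_higher_in_females(self):
        epi = m.make_epi(seed=1)
        dep = epi[epi["disorder"] == "depression"]
        f = dep[dep["sex"] == "female"]["prevalence_per_1000"].mean()
        mm = dep[dep["sex"] == "male"]["prevalence_per_1000"].mean()
        assert f > mm

    def test_empty_disorder_list_rejected(self):
        with pytest.raises(SchemaError):
            m.make_epi(1, [])


class TestMakeCosts:
    def test_intensive_costs_more_than_basic_per_disorder(self):
        ivs = make_interventions(seed=1)
        profiles, _ = m.make_costs(1, ivs)
        by_disorder = {}
        for iv in ivs:
            by_disorder.setdefault(iv.disorder, {})[iv.tier] = \
                profiles[iv.id].total_per_case_irr
        for disorder, tiers in by_disorder.items():
            if {"basic", "intensive"} <= tiers.keys():
                assert tiers["intensive"] > tiers["basic"], disorder

    def test_fixed_seed_reproduces_profiles(self):
        ivs = make_interventions(seed=2)
        p1, g1 = m.make_costs(2, ivs)
        p2, g2 = m.make_costs(2, ivs)
        assert {k: v.model_dump() for k, v in p1.items()} == \
            {k: v.model_dump() for k, v in p2.items()}
        assert g1 == g2

    def test_per_case_total_reconstructs_from_components(self):
        """commodity + Σ(minutes × salary/min) equals the declared total."""
        ivs = make_interventions(seed=3)
        profiles, _ = m.make_costs(3, ivs)
        for prof in profiles.values():
            recon = prof.commodity_cost_irr + math.fsum(
                v.minutes_per_case_year * v.salary_per_minute_irr
                for v in prof.visits)
            assert recon == pytest.approx(prof.total_per_case_irr, abs=1e-6)


class TestMakeEconomics:
    def test_defaults_match_study_settings(self):
        econ = m.make_economics()
        assert econ.exchange_rate_irr_per_usd == 194_881
        assert econ.gdp_per_capita_usd == 5550
        assert set(range(2010, 2031)) <= set(econ.inflation)

    def test_constant_observed_series_extrapolates_to_itself(self):
        observed = {y: 0.2 for y in range(2010, 2020)}
        ext = geometric_mean_extrapolation(observed, range(2020, 2031))
        assert all(r == pytest.approx(0.2) for r in ext.values())

    def test_rates_above_minus_one_enforced(self):
        with pytest.raises(Exception):
            m.make_economics(observed_inflation={2010: -1.5})


class TestBundle:
    def test_disability_weights_and_effects_in_declared_ranges(self):
        for d in make_disorders(seed=9):
            assert 0.1 <= d.disability_weight <= 0.7
        for iv in make_interventions(seed=9):
            assert 0.2 <= iv.effect_size <= 0.5

    def test_written_bundle_validates_and_projects(self, tmp_path):
        paths = m.write_bundle(tmp_path, seed=11)
        cfg = m.load_config(paths["config"])
        bundle = m.load_bundle(cfg)
        report = m.project(bundle)
        assert report.summary["total_cost_irr"] > 0
        assert report.summary["total_hly"] > 0
        assert np.isfinite(list(
            v for v in report.summary.values() if isinstance(v, (int, float))
        )).all()

    def test_bundle_reproducible_from_seed(self):
        b1 = m.make_bundle(4)
        b2 = m.make_bundle(4)
        pd.testing.assert_frame_equal(b1.population, b2.population)
        pd.testing.assert_frame_equal(b1.epi, b2.epi)
        assert b1.config.model_dump() == b2.config.model_dump()
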
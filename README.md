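# mhscaleup

Cost-consequence projection of scaling up a national socio-mental health
service package — basic (primary-care) and intensive (community mental
health centre) treatment for **anxiety, depression, bipolar disorder and
epilepsy** — over a 2020–2030 horizon, from the health-ministry provider
perspective.

The package is for health economists and mental-health programme planners
who need a transparent, testable implementation of the standard
coverage-scale-up accounting:

* **Caseloads.** Prevalent cases per disorder-year are
  `Σ_g population(g) × prevalence(g)/1000` over 34 age/sex groups
  (17 five-year bands × 2 sexes); treated cases apply the eligible fraction
  and the year's coverage:
  `treated = prevalent × eligible × coverage/100`.
* **Coverage scale-up.** Annual trajectories from baseline to target under
  four interpolation patterns (linear, front-loaded, S-shaped, exponential),
  or explicit published per-year rows.
* **Health impact.** Healthy life years gained (≡ DALYs averted):
  `HLY(d,t) = Σ_i treated_above_baseline(i,t) × DW(d) × e(i)` where `DW` is
  the disability weight and `e` the per-case-year effect size. First-year
  gains are zero by construction (coverage starts at baseline).
* **Costing.** Three components in local currency (integer rial):
  commodity spend (drugs/supplies) per treated case, cadre-level visit
  minutes × per-minute salaries (labor), and programme overheads
  (management/supervision/training), all compounded by an inflation series
  extrapolated from observed 2010–2019 rates; conversion to USD
  (÷ 194,881 IRR/USD) and PPP-adjusted Intl$ only at report time.
* **Cost-effectiveness.** `cost per HLY = total cost / total HLY`, classified
  against WHO GDP-per-capita thresholds (< 1×GDP very cost-effective,
  ≤ 3×GDP cost-effective), plus an eight-scenario sensitivity engine
  (patterns, epidemiological CI bounds, coverage variants).

A seeded synthetic-data module generates complete input bundles (83 M
population pyramid, per-1,000 rates with CI bounds, unit-cost profiles,
inflation series) so every stage is testable without external data.

## Worked example

```python
import mhscaleup as m

bundle = m.make_bundle(seed=1)               # full synthetic study conditions
results, matrix = m.run_all(bundle, m.default_scenarios())
base = results[0]
print(round(base.total_cost_usd), round(base.total_hly),
      base.cost_per_hly_usd, base.classification)
```

prints

```
984124846 1302428 756 very_cost_effective
```

i.e. this synthetic scale-up costs ≈ 984 M USD over 2020–2030, gains
≈ 1.30 M healthy life years, and each healthy life year costs 756 USD —
well below the 5,550 USD GDP-per-capita threshold, hence *very
cost-effective*. `matrix` is the eight-column sensitivity table
(cost components, per-disorder impacts, ratios per scenario).

The same pipeline runs from the shell:

```bash
mhscaleup generate --seed 1 --out bundle/          # write input CSVs + config
mhscaleup project --config bundle/config.yaml --out run/
mhscaleup scenarios --config bundle/config.yaml --out matrix.csv
mhscaleup report --in run/
```

The package also ships the published base-case projection tables for the
Iranian programme (coverage rows, annual costs, healthy-life-year table,
sensitivity matrix) as plain-CSV reference data, available through
`published_coverage()`, `published_costs()`, `published_impacts()` and
`published_sensitivity()`.

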
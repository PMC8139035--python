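# Methods

## Model

The package implements a deterministic, prevalence-based cost-consequence
projection of scaling up a package of mental-health interventions over a
fixed calendar horizon (default 2020–2030). For each intervention *i*
attached to disorder *d*:

```
prevalent(d, t)  = round½( Σ_g pop(g, t) · prev_d(g) / 1000 )
eligible(i, t)   = round½( prevalent(d, t) · f_i )
treated(i, t)    = round½( prevalent(d, t) · f_i · c_i(t) / 100 )
above(i, t)      = max(0, treated(i, t) − round½(prevalent · f_i · b_i / 100))
HLY(d, t)        = Σ_{i∈d} above(i, t) · DW_d · e_i
```

where `g` runs over 34 age/sex groups, `f_i` is the eligible fraction
(basic tier targets moderate cases, intensive tier severe cases),
`c_i(t)` the coverage trajectory, `b_i` the baseline coverage, `DW_d` the
disability weight and `e_i` the effect size (fraction of disability time
averted per treated case-year). `round½` is round-half-up to whole
persons, applied only at the (disorder | intervention, year) level;
group-level terms are accumulated at full precision with compensated
summation.

Costs have three components per year, each an integer rial amount rounded
half-up once per cell:

```
intervention(t) = Σ_i treated(i,t) · commodity_i · Π_{y≤t}(1+r_y)
labor(t)        = Σ_i treated(i,t) · (Σ_cadre min_i,cadre · wage_cadre) · Π(1+r_y)
program(t)      = (mgmt_national + P·(mgmt_prov + supervision + training)) · Π(1+r_y)
```

with `P` provinces (default 31) and `r_y` the inflation series. Because
every cell is an integer rial, `total = intervention + program + labor`
and `horizon total = Σ years` are exact integer identities. Conversion to
USD (fixed June-2020 rate, 194,881 IRR/USD) and Intl$ (× PPP factor)
happens only at report time; an optional per-year exchange series exists
but the fixed rate is the default, since the source analysis quotes both
an extrapolated series and the single rate without reconciling them.

The summary statistic is `cost per HLY = total cost(USD) / total HLY`,
rounded half-up to whole USD for reporting, classified against
GDP-per-capita thresholds with the WHO-CHOICE three-band convention
(< 1×GDP very cost-effective, 1–3×GDP cost-effective, > 3×GDP not
cost-effective; boundaries assigned upward). The analysis quotes only the
1×GDP rule while labelling its results "cost-effective"; the band scheme
satisfies both statements.

## Coverage patterns

Trajectories pin both endpoints exactly and are non-decreasing. Shapes,
as normalised progress `s(x)`, `x = t/N`:

| pattern | s(x) | increment shape |
|---|---|---|
| linear | `x` | constant |
| front_loaded | `x^p`, p = 0.5 (configurable) | non-increasing |
| s_shaped | `3x² − 2x³` | rises then falls |
| exponential | geometric `(g^x−1)/(g−1)`, `g = target/baseline`; `x²` when baseline = 0 | non-decreasing |

For the same endpoints, front_loaded ≥ linear ≥ exponential pointwise, so
front-loaded scale-up accrues the most treated case-years and the lowest
cost per HLY — the ordering the sensitivity analysis exhibits. The exact
closed form behind the published front-loaded rows is not recoverable from
the printed trajectories (two printed rows are exactly linear, the others
concave); published rows are therefore consumed verbatim via `from_table`,
which overrides any pattern, and no calibration to the original tool's
interpolation is attempted.

## Scenarios

Eight deterministic runs: base (front-loaded), exponential, linear,
lower/upper epidemiological confidence bounds (every prevalence and
incidence cell swapped to its bound), and three coverage variants —
basic baseline 40→50 % (`coverage_1`), intensive target 30→40 %
(`coverage_2`), basic target 70→60 % (`coverage_3`). Tier-level overrides
apply to every intervention of that tier across all disorders; unspecified
fields inherit from base. No ordering between the CI-bound ratios and the
base ratio is asserted: cost and impact scale together, so the ratio can
move either way.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the study inputs at the study
conditions: an 83 M, young-adult-heavy population in 17 five-year bands ×
2 sexes with ~1.2 %/yr growth; per-1,000 prevalence with age gradients
(depression/anxiety rising through adulthood then plateauing, higher in
females; bipolar and epilepsy flatter), CI half-widths 5–15 % of the
point value; seven interventions with the published coverage endpoints
(basic 40→70 %, intensive 1→30 %); per-case costs split into commodity
spend and cadre minutes priced at 2020 public-sector per-minute salaries,
with intensive tiers strictly costlier than basic by construction;
and observed 2010–2019 national CPI inflation (≈12–41 %/yr) extrapolated
to the horizon by its geometric mean (≈21 %/yr) — the simplest defensible
reading of "extrapolation", isolated in one function so a trend model can
be swapped in.

Disability weights and effect sizes are deferred to tool internals in the
source analysis, so the generator draws them from declared plausible
ranges (DW per disorder within 0.1–0.7; effects 0.2–0.5) and records the
truth in the bundle, enabling exact parameter-recovery tests. Passing
tests therefore demonstrate correctness of the *accounting*, not fidelity
of absolute impact levels to any real programme: the published absolute
HLY totals are reproduced as identities over the packaged published
tables, not predicted ab initio. Real-world features not emulated:
migration/fertility dynamics (population is exogenous), treatment feedback
on prevalence, remission/mortality transitions, private-sector provision.

## Numerical choices

* Money is integer rial end-to-end; conservation checks are exact.
  Rounding is half-up, once per finalised cell.
* Coverage percentages are full precision internally; one-decimal rounding
  is display-only.
* HLY totals use `math.fsum`, so grand total = Σ disorder totals = Σ year
  totals independent of summation order.
* A discount-rate hook exists on impact aggregation and defaults to 0
  (the source analysis reports undiscounted sums).
* Within-year convention: a full averted-disability year is credited per
  above-baseline treated case in its calendar year.
* Degenerate inputs: baseline = target gives a constant trajectory; zero
  caseloads leave only the programme cost row; a zero-HLY denominator is a
  reported error, never an infinity.

## Known rounding artifacts in the published tables

The packaged published cost table's component rows each sum to ±1 USD of
their printed totals (e.g. intervention annual cells sum to 382,120,920
vs the printed 382,120,919), while the printed annual *total* row and the
three printed component totals both sum exactly to 1,363,581,654. The
identity checks use the exactly-consistent rows; ratio recomputation uses
the printed scenario totals, under which all eight published ratios
(801, 1199, 959, 794, 807, 899, 724, 835 USD) reproduce exactly at
whole-USD rounding.

## Free parameters the source does not pin down

* **PPP factor** — the published Intl$ ratios imply ≈9.63 Intl$/USD while
  the quoted GDP pair implies ≈2.33; the conversion-tool settings are
  unrecoverable, so `ppp_factor_intl_per_usd` is a free input defaulting
  to 9.63 (matches the published Intl$ ratio column to ±2).
* **Per-capita denominator** — 1,363,581,654 USD / 83.0 M ≈ 16.43 vs the
  printed 16.42 (0.06 %); the exact denominator year is unstated, so this
  is treated as an approximate check (within 1 %).
* **Age-band boundaries** — the 17 bands are standard five-year bands with
  80+ terminal; the original extract's exact boundaries are unstated.

## Problem sizes

Tests and the acceptance script run the full study scale (83 M population,
34 groups, 7 interventions, 11 years, 8 scenarios); the whole pipeline is
a few hundred milliseconds per scenario, so no scaled-down mode is needed.
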
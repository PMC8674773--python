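# Methods

## Model

The quantity estimated is average per-capita daily vitamin D supply,
µg/person/day. It is an *availability* measure: national food supply per
head, not measured consumption, so it bounds intake from above (waste,
spoilage and within-country distribution are not modelled) while missing
supplements and — unless explicitly modelled — fortification.

For each country and year, every food-balance-sheet commodity's
per-capita supply (kg/year, converted to g/day with a 365-day year) is
multiplied by the average vitamin D content of its composition group
(µg/100 g) and summed. Content has two parts: vitamin D3, and
25-hydroxyvitamin D3 counted at `bioactivity_factor` (default 5) times
D3 potency. Pipelines can include or exclude the 25(OH)D term because
national composition databases disagree on it — the UK tables include
it, the USDA tables do not — and the difference materially shifts
estimates for countries with high animal-food supply. Period estimates
are the arithmetic mean and sample (n−1) SD across the years of the
period present in the data; missing years are tolerated and `n_years`
recorded; a single year gives SD 0.

### Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| days per year | d | 365 | common convention for FAO per-capita/day quantities; exposed as `fbs_io.DAYS_PER_YEAR` |
| bioactivity_factor | – | 5 | the factor applied to 25(OH)D3 in UK-style totals; a parameter so sensitivity analyses are possible |
| milk density | g/mL | 1.0 | converts milk supply mass to litres for µg/L fortification levels |
| band edges | µg/d | ≤1.5 … >10.0 | see Banding below |
| quartile interpolation | – | linear (type 7) | numpy default; configurable in `region_summary` |

## Fortification

A policy is (vehicle, level, coverage, start year, basis). Flour
increments are `g/day × coverage × level/1000`; all wheat and maize
supply is treated as flour available for fortification, with the
fortified fraction carried by `coverage`. Milk increments additionally
scale by `milk_product_share`, the share of FBS milk supply consumed as
the fluid products a policy actually covers. Increments are additive
across vehicles with no interaction, apply from the whole calendar year
of `start_year`, and zero level or coverage is an exact no-op.
Mandatory and voluntary policies are both applied as configured, with
the basis recorded; analyses here emphasise mandatory standards because
voluntary uptake is poorly quantified. Fortified cooking oils are
refused unless a retention factor is explicitly supplied: vitamin D
retention in heated oil is too variable to assume silently.

## Banding and summaries

Reported estimates are rounded half-up to one decimal (decimal
arithmetic, not float banker's rounding), and rounding happens only at
report/banding time, never inside computation. The six bands are read
as closed ranges on that one-decimal grid — ≤1.5, [1.6, 3.0],
[3.1, 5.5], [5.6, 7.5], [7.6, 10.0], >10.0 — so they tile the grid with
no gaps and per-band counts always sum to the number of countries.
Extremes report all tied countries (the packaged 2004–2013 reference has
a two-way tie at the minimum). Regional summaries use a hand-assigned
UN continental mapping shipped with the package, with special
administrative regions and former countries kept as separate rows.
Between-period deltas are classified by absolute magnitude into
<0.5, 0.5–0.99 and ≥1.0 µg/d.

## Concordance

`bland_altman` takes country pairs of survey-measured intake (food
sources only) and matched FBS supply (same years, same 25(OH)D
convention) and reports the mean difference (FBS − survey), its sample
SD, 95% limits of agreement (bias ± 1.96 SD), the per-country
difference range, and a proportional-bias p-value from an OLS
regression of differences on pair means. n ≥ 3 is required; when
differences have zero variance the regression is degenerate and the p
is NaN. Which agreement statistic a given published analysis used is
often unstated, so the proportional-bias slope test is computed and
labelled explicitly rather than matched to any particular printed p.

## Synthetic data

The generator emulates a FAOSTAT long-format CSV: one supply row per
country, year and commodity, with supplies drawn as
`mean × country_scale × (1 + CV·ε)`, ε standard normal, truncated at
zero (truncations counted). Default group means reflect a typical
national diet (plant staples carry the mass, animal foods the vitamin
D) and CVs of 5–15% give year-to-year variation of the order seen in
real period SDs. Ground truth for every option combination is computed
by an independent plain-arithmetic loop inside the generator, never by
the pipeline under test, so end-to-end recovery is exact (≈1e-15,
asserted at 1e-9 to leave room for the kg↔g CSV round-trip). What
synthetic tests do **not** show: realism of commodity correlations,
FAO's internal balancing, or real composition values — the shipped
composition table is illustrative (correct orders of magnitude only),
so reproducing published per-country tables from raw FBS inputs is not
claimed; the packaged reference estimates serve that role instead.

## Design choices

- **365-day year.** Leap years ignored; configurable.
- **Unmapped commodities contribute zero** vitamin D but are never
  silently dropped: a coverage report accounts for every gram.
- **SD across years.** The only repeated unit available per
  country/period; constant series give SD 0.
- **Bias sign convention.** FBS − survey, so the expected availability
  bias is positive.
- **Simulation check.** The planted-bias recovery test asserts the mean
  recovered bias over 200 seeded datasets (n = 10 pairs each) lies
  within 3σ/√n of the planted value — a bound loose enough to be
  deterministic-robust yet tight enough to catch sign or scale errors.
- **Problem sizes.** Synthetic runs use 5 countries × 4 years × 9
  commodity groups and 10 survey pairs × 200 seeds; construction is
  deterministic arithmetic, so larger sizes add nothing to the checks.

## Limitations

Supply ≠ intake: no waste/spoilage adjustment, no within-country
distribution, no supplements, no UV-irradiated mushrooms, no oil
fortification by default. Composition values are group averages; real
within-group heterogeneity (e.g. fatty vs white pelagic fish) and
country- or season-specific content differences are not modelled.
Old (≤2013) and new (≥2014) FBS series differ methodologically; the
package records the dialect but does not reconcile the series.
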
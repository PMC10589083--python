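# Methods

## The measurement model

The package treats a farm's most recent cropping cycle (≈ one year) on a
single sample parcel as the unit of observation. Two outputs are measured
per hectare of the parcel's combined land-and-water area
(`area = land_ha + pond_ha`):

- **Economic productivity**: the value of everything produced — sold
  output at the farm's own unit price, self-consumed output imputed at the
  same price — minus reported variable production costs, divided by area.
  Negative values are legitimate (costs can exceed value) and are never
  truncated.
- **Nutrient productivity**: the amount of each of seven nutrients
  contained in the edible portion of everything produced, divided by area
  and normalized by one adult's annual requirement (`RDA × 365`). The
  resulting unit, annual adult equivalents per hectare (AE ha⁻¹), reads as
  "number of adults this hectare could supply for a year with nutrient
  *n*".

Only production is measured. Who eats the nutrients — the producing
household, or buyers reached through markets — is outside the model, as is
any cooking-loss, bioavailability or retinol-conversion adjustment
(vitamin A concentrations are taken as retinol activity equivalents
directly from the composition table).

### Units and conventions

- Quantities are whole-product (as-produced) wet weights in kg. The
  edible-portion correction happens only inside the nutrient calculation;
  prices apply to whole product.
- Concentrations are stored per 100 g of edible portion (the
  food-composition-table convention) and scaled ×10 × EP internally to a
  per-kg whole-product density.
- Default daily RDAs: 9,200 kJ energy, 55 g protein, 1,000 mg calcium,
  13 mg iron, 10 mg zinc, 900 µg RAE vitamin A, and 2.5 for vitamin B12 in
  a configurable unit. The B12 unit is deliberately symbolic: the numeric
  default is kept as printed in the source constants, and the packaged
  composition table uses µg so table and RDA agree; a user supplying
  mg-based concentrations must set the RDA unit to mg. The loader warns
  when a terrestrial food declares positive B12, since B12 occurs only in
  animal-source foods.
- Monetary fields are US$; currency conversion is a preprocessing
  responsibility.

### Price imputation ladder

Unit prices are farm × food specific: `sales_value / quantity_sold` where
the farm sold, else the median observed price among sellers of that food
in the same upazila, else the sample-wide median among sellers, each step
flagged by provenance. A food produced somewhere but sold nowhere in the
sample has no defensible price and is a hard error. Similarly, a produced
food missing from the composition table is a hard error by default, with
an opt-in skip-and-warn mode — silent nutrient undercounting is the worst
failure mode of this kind of accounting.

### Typology and trimming

The aquatic dimension of the typology depends only on the presence of
prawn and shrimp among foods with positive production (every in-frame farm
produces some aquatic food); the terrestrial dimension on the presence of
rice versus any other terrestrial food ("vegetables and fruits", which
here pools vegetables, fruits, root crops and nuts/oilseeds). Prawn/shrimp
membership is a species flag carried on crustacean entries of the
composition table, not a hardcoded name list. Farming systems with 12 or
fewer farms are removed before any comparative analysis; on the packaged
721-farm distribution this removes 21 farms in four cells and leaves 700.
A farm with crustaceans but literally no finfish is classified by
crustacean presence alone and logged; the sampled population contains none
by construction. Reported percentages round half-up to integers, which
reproduces every printed percentage derivable from the published
distribution table.

### Regression

All eight models are OLS on an identical design matrix: 12 sub-category
yields in t ha⁻¹ (kg summed per sub-category, ÷ area ÷ 1000), the share of
aquatic production sold (a fraction in [0, 1]), 0/1 indicators for having
sold vegetables/fruits and rice, nine household controls (head age,
education, sex, household size, dependency ratio, off-farm income, travel
time to city, agricultural land ha and pond ha entered separately), an
intercept, and upazila dummies with one reference level dropped.
Significance marks: a p < 0.10, b p < 0.05, c p < 0.01. The "top-3" flag
marks the three food/market regressors with the largest absolute
coefficient among those significant at p < 0.10; ties break by smaller
p-value, then column order. That reading of "largest statistically
significant" is one of several defensible ones (magnitude vs t-statistic);
it is documented rather than guessed beyond.

Standard errors default to conventional homoskedastic OLS SEs — the
simplest reproducible reading — with HC1/HC2/HC3 heteroskedasticity-robust
options. The recovery analyses (below) use HC3: the synthetic data's error
variance scales with the yield regressors, which are right-skewed, and
under such leverage HC1 intervals are known to undercover while HC3 is the
standard remedy; a 40-replicate diagnostic measured ≈ 92.9% coverage of
nominal-95% HC1 intervals versus ≈ 95.0% for HC3.

## The synthetic-data generator

The generator emulates the study conditions so that the full pipeline is
testable without field data:

- 721 farms distributed over the 4 × 4 system grid at the published cell
  frequencies. Default assignment is deterministic largest-remainder
  ("exact"), which makes the default survey tabulate cell-for-cell and
  trim to exactly 700; a "multinomial" mode draws cells at the same
  probabilities for tests where sampling error is the point.
- Parcel areas lognormal with mean 0.78 ha; ponds take the whole parcel on
  non-integrated farms and a Beta(4,3) share otherwise.
- Each farm produces the finfish groups with probabilities 0.96 / 0.82 /
  0.83 (carp / other stocked / unstocked, at least one forced),
  crustaceans as dictated by its system, rice iff rice-integrated, and a
  random subset of the seven vegetables/fruits groups iff VF-integrated.
  Within a produced group, each food enters with a group-specific
  inclusion probability and the group's lognormal yield (kg ha⁻¹ of parcel
  area) is split across the included foods by a symmetric Dirichlet.
  Defaults give ≈ 9 aquatic products per farm and ≈ 3.5–4.5 horticultural
  products per producing farm.
- Shares sold are zero-inflated Beta per farm × food with group-level
  means 0.71 / 0.57 / 0.33 (aquatic / vegetables & fruits / rice); prices
  are mean-parameterized lognormal per farm × food; costs are
  (base + upazila offset + noise) × area.

**Ground truth.** Outcomes are never written directly; they emerge from
quantities through the same productivity equations the analyst runs. The
true coefficient of group *g*'s yield on each outcome is then a structural
constant: since inclusion and Dirichlet weights are symmetric within a
group, every food's expected weight is exactly 1/m, so

- nutrient outcomes: `β_gn = 1000 · mean_f∈g(density_fn) / (RDA_n · 365)`,
- economic outcome: `β_g = 1000 · mean_f∈g(price_f)`,

and the farm-level deviation of the realized food mix from its expectation
is an exogenous, mean-zero error. Price log-noise and cost noise add
further error to the economic outcome, and upazila cost offsets give it
true fixed effects (the nutrient outcomes have true fixed effects of
zero; the dummies are still estimated). This is why OLS on generated data
is unbiased for the recorded `β_true`, which parameter-recovery tests
verify at n = 700 (coverage, pooled standardized bias) and across
n = 700 → 7,000 (shrinking pooled RMSE).

Two deliberate simplifications keep the ground truth well-defined: prawn
and shrimp share one nutrient/price profile (otherwise the pooled
crustacean coefficient would depend on the FP/FS/FPS farm mix rather than
being a single constant), and the "noise scale" of the survey is
controlled through the Dirichlet concentration, price sigma and cost sigma
rather than an additive outcome noise, which a structural generator cannot
inject.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial/salinity structure (systems are
independent of upazila), measurement error and attrition, any true effect
of market orientation or household covariates on productivity (their true
coefficients are zero), price–quantity correlation, within-group
composition differences across systems, and seasonality. Recovery results
certify the pipeline's statistical correctness under its own model, not
the field accuracy of any coefficient.

**Calibration provenance.** Distributional defaults not fixed by the
conditions above (yield means, price means, cost level, covariate
distributions) were chosen once for plausibility against the magnitudes
the source study reports (per-system economic productivity roughly
US\$1,200–4,400 ha⁻¹; energy productivity of order tens of AE ha⁻¹) and
are not test oracles; the packaged composition values are likewise
illustrative, synthetic stand-ins scaled to the Bangladesh
food-composition literature, not reproductions of any published table.

## Numerical choices

- Half-up integer rounding for reported percentages.
- Validation tolerances: `quantity_sold ≤ quantity` allows 1e-9 slack for
  round-tripped floats; decomposition identities are asserted at 1e-9
  relative.
- The design matrix is rank-checked (with suspect columns named via
  pivoted QR) only when n > p; degenerate tiny inputs fail at fit time
  with a clear error instead.
- Randomness: one master seed keys a Philox counter-based stream; farm *i*
  draws from jump *i + 1*, so extending a survey never perturbs existing
  farms, and identical (config, seed) pairs are byte-identical on disk.
- Problem sizes in the shipped analyses — 10,000 farms for
  condition checks, 50–200 replicates at n = 700 for recovery, six
  replicates per sample size for the consistency check — were chosen so
  the whole suite runs comfortably on a single CPU while keeping
  Monte-Carlo error well inside the asserted margins.

## Known limitations

- Whether per-hectare denominators should include homestead land beyond
  pond + agricultural land is unresolved in the source material; this
  package uses pond + agricultural land.
- Whether the original analysis imputed prices for non-sellers is not
  documented; the upazila-then-sample median ladder is this package's
  choice.
- The AE formula's verbal description ("divide by the amount that would
  equal one daily AE and multiply by 365") is read as division by
  `RDA × 365`; the alternative reading (multiplication) produces
  person-day units at odds with the stated magnitudes.
- Species-level (rather than 12-group) regressions, survey weighting,
  panel linkage and causal identification are out of scope.
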
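# nutriprod

Supply-side measurement of **economic productivity** (US\$ ha⁻¹) and
**nutrient productivity** (annual adult equivalents ha⁻¹, AE ha⁻¹) for
integrated aquaculture–agriculture (IAA) farming systems, built for
farm-survey microdata of the kind collected from smallholder aquaculture
households in southern Bangladesh. It is aimed at researchers in
nutrition-sensitive agriculture who want to compare farming systems not by
biomass or income alone but by how many people's annual nutrient
requirements one hectare of land and water can supply.

## What it computes

**Farming-system typology.** Each farm is cross-classified by its aquatic
combination — fish only (F), fish + prawn (FP), fish + prawn + shrimp
(FPS), fish + shrimp (FS) — and its terrestrial integration (none / rice /
vegetables & fruits / both). Systems with ≤ 12 farms are dropped from the
analysis sample.

**Economic productivity.** With farm-reported unit prices
`p = sales value / quantity sold` (median-imputed from upazila, then
sample, for produced-but-unsold foods):

```
econ = ( Σ_foods  q_f · p_f  −  production costs ) / area
```

where `area` is agricultural land + pond in hectares, and self-consumed
output is valued at the same unit price as sold output.

**Nutrient productivity.** For each of seven nutrients (energy kJ, protein
g, calcium mg, iron mg, zinc mg, vitamin A µg RAE, vitamin B12) with
edible portion `EP`, concentration `c` per 100 g edible, and daily adult
requirement `RDA`:

```
AE_n = Σ_foods q_f · EP_f · 10 · c_fn  /  ( area · RDA_n · 365 )
```

i.e. the number of adults whose full-year requirement of nutrient *n* the
farm covers per hectare. Default RDAs: 9,200 kJ, 55 g protein, 1,000 mg
calcium, 13 mg iron, 10 mg zinc, 900 µg RAE vitamin A and 2.5 vitamin B12
(configurable unit, µg by default).

**Regression design.** Eight OLS models (economic + 7 nutrient outcomes)
on one design matrix: the 12 food-group yields in t ha⁻¹ (carp, other
stocked fish, unstocked fish, crustaceans, rice, leafy vegetables, vitamin
A-rich vegetables, other vegetables, root crops, vitamin A-rich fruits,
other fruits, nuts/oilseeds), market-orientation indicators, nine
household controls and upazila (subdistrict) fixed effects, with
significance marks (a/b/c for p < 0.10/0.05/0.01) and the three largest
significant food/market coefficients flagged per model.

**Synthetic surveys.** Because the underlying field data cannot be
bundled, a structural generator produces survey rounds with the study's
statistical shape (721 farms at the observed system frequencies, 0.78 ha
mean parcel, ~9 aquatic products per farm, shares sold ≈ 71/57/33% for
aquatic foods / vegetables & fruits / rice) and records the implied true
yield coefficients, so every stage is testable end-to-end.

## Worked example

```
python analysis/01_simulate_survey.py --seed 1
python analysis/02_farming_system_typology.py --seed 1
```

prints, among other lines:

```
aquatic        F   FP  FPS  FS  total
terrestrial
none         184   32  135  52    403
rice          16   33   29   8     86
vf            68   31   12   1    112
rice_vf       16   69   35   0    120
total        284  165  211  61    721

fish only: 39% of farms
non-integrated: 56%
prawn systems integrated with agriculture: 81%

trimming cells with <= 12 farms leaves 700 farms
```

— the 4 × 4 sample distribution (here simulated at the published cell
frequencies), the rounded descriptive percentages, and the analysis sample
after the small-cell trim. Continuing with

```
python analysis/03_productivity_by_system.py --seed 1
python analysis/04_regression_table.py --seed 1
python analysis/05_parameter_recovery.py --seed 1 --reps 50
```

computes per-system productivity tables (e.g. `mean economic
productivity: 4295 US$/ha`, `mean vitamin B12 productivity: 36.8 AE/ha`),
the eight-model regression table (on this simulated round, micronutrient
outcomes load on unstocked fish and leafy vegetables while economic
productivity loads on crustaceans and carps), and a recovery study
reporting, e.g., `95% CI coverage of food-group coefficients: 96.0%` —
the refitted confidence intervals contain the generator's structural truth
at close to the nominal rate. All tables land under `results/`.

The same steps are available as a console tool:
`nutriprod {validate,simulate,classify,productivity,regress,report,run-all}`.

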
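# habshift

Habitat-suitability change analysis with boosted regression trees, on
synthetic data with known ground truth.

The pipeline mirrors a full species-distribution-modelling workflow:

1. **synthetic** — daily climate cubes (seasonal cycle, latitudinal
   gradient, warming trend, stochastic weather), land-use class-fraction
   stacks (14 classes, sum-to-one, bounded annual drift), a sea mask,
   and a species presence-probability map drawn from a known logistic
   suitability model (`TruthSpec`), so every downstream stage can be
   tested against ground truth.
2. **bioclim** — the 19 BIOCLIM variables, a configurable registry of
   threshold extremes (day counts ND and longest runs LP), and absolute
   humidity, averaged over sliding 31-year climatological windows and
   assembled with target-year land-use fractions into a
   `PredictorStack`.
3. **sampling** — probability-map binarization (presence at p >= 0.5)
   and four pseudo-absence strategies: random, land-use-composition
   stratified ("sampled"), buffered (absences only where p = 0), and
   sampled+buffered, with a 75% presence fallback when presences are
   scarce.
4. **brt** — gradient-boosted trees (Bernoulli loss, bag fraction 0.5)
   with cross-validated tree-count selection, an adaptive tuning loop
   (start lr=0.15 / tree complexity 5; tc bounded to [3, 10]; stop when
   the CV-optimal tree count lands in [1200, 2000]), predictor
   contributions, pairwise interaction sizes, partial-dependence
   response curves, iterative simplification, and gridded prediction.
5. **ensemble** — the 4 background x 4 predictor-selection cross
   product (16 setups), unweighted ensemble quantiles of the
   habitat-suitability-area (HSA) change, and best-model selection.
6. **evaluation** — TSS, AUC and Cohen's kappa with spatial-sorting-bias
   removal by point-wise distance sampling, Brier skill score, the
   composite OMS, the area of applicability (AoA), and
   SCORE = sqrt(OMS^2 + AoA^2)/sqrt(2).
7. **attribution** — constant-land-use (CLU) vs varying-land-use (VLU)
   projections against a reference year, an eight-category per-cell
   change classification, HSA time series, and climate-vs-land-use
   change summaries.
8. **importance** — the per-grid-box most important predictor (MIP) and
   most important predictor for change (MIPC) from contribution,
   interaction, and response-range terms, with category-level summaries.

## CLI

The stages chain through a run directory:

```bash
habshift simulate --grid -5,5,35,45,0.25 --years 1970:2020 --seed 1 --out run/
habshift bioclim  --target-year 2000 --target-year 2020 --out run/
habshift sample   --method random --year 2000 --n-presence 500 --out run/
habshift ensemble --reference-year 2000 --year 2010 --year 2020 \
                  --n-presence 500 --seed 1 --out run/
habshift attribute --year 2020 --out run/
habshift mip       --year 2020 --group climate --out run/
habshift report    --out run/
```

`simulate` writes climate/land-use/species NetCDF inputs plus the truth
spec; `ensemble` writes per-setup skills (`skills.csv`), HSA quantile
series, and the pickled ensemble; `attribute`/`mip`/`report` produce the
change-category, attribution, and importance tables.

## Layout

```
src/habshift/
  grid.py        regular lon/lat grids (cell-center registration)
  synthetic.py   climate / land-use / species-map generators, TruthSpec
  bioclim.py     BIO1-19, extreme variables, AHUM, climatological stacks
  stack.py       PredictorStack container
  sampling.py    binarization + 4 background-selection methods
  brt.py         boosted-tree engine, tuning loop, diagnostics
  ensemble.py    16-setup ensemble, predictor selection, best model
  evaluation.py  TSS/AUC/kappa/BSS, SSB removal, OMS, AoA, SCORE
  attribution.py REF/CLU/VLU scenarios, change categories, HSA series
  importance.py  MIP / MIPC and summaries
  io.py          NetCDF/CSV/YAML persistence
  workflow.py    run-directory stages
  cli.py         click CLI
tests/           pytest suite; tests/test_acceptance.py holds the
                 acceptance criteria
scripts/acceptance.py   acceptance report generator
```
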
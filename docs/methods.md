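# Methods

## Problem and approach

`snakerisk` implements a presence-only, multi-species habitat-suitability
workflow for mapping relative snakebite-envenoming risk. The input is a
stack of environmental raster layers, occurrence records for several
medically relevant snake species, and a set of settlement points. Per
species, an ensemble of five presence/background suitability models is
fitted and evaluated; the per-species ensemble surfaces are then multiplied
cellwise into a single risk surface, which is classified and overlaid with
settlements to count villages at moderate and high risk and to measure
suitable area.

The multiplicative combination encodes the assumption that risk to people
is highest where *several* venomous species find suitable habitat
simultaneously: the product is bounded by its smallest factor, so a cell
unsuitable for all but one species scores low even if that one species is
certain to occur.

## Base learners

All five methods share one contract: given a design matrix of predictor
values at presence and background points, produce a suitability score in
[0, 1], deterministically for a fixed seed.

| method | realization | key defaults |
|---|---|---|
| GLM | logistic regression, linear + quadratic terms, unpenalized | — |
| GAM | penalized-spline logistic additive model (B-splines) | 4 df, cubic, per term |
| GBM | gradient-boosted classification trees | 500 trees, learning rate 0.05, depth 3 |
| RF | random forest, probability votes | 500 trees, depth ≤ 6, balanced-subsample class weights |
| MAXENT | L1-penalized logistic regression on linear + quadratic + hinge features, penalty by 5-fold CV | 3 hinge knots/variable, C grid 10⁻²…10² |

Notes on the choices:

- **MaxEnt as penalized logistic regression.** The maximum-entropy
  presence/background model is statistically equivalent to an
  L1-regularized logistic regression on the same feature expansion
  (linear, quadratic and hinge transforms), with the regularization path
  playing the role of MaxEnt's feature-class penalties. We implement that
  equivalence directly rather than shelling out to the original software.
- **Class weighting.** For GLM, GAM and MAXENT the background sample is
  down-weighted so its total weight equals the total presence weight;
  otherwise the ~100:1 prevalence dominates the intercept and compresses
  the fitted probabilities toward zero.
- **RF regularization.** With on the order of 10² presences against 10⁴
  background points, fully grown trees memorize the presence cells and the
  majority class swamps the vote; held-out AUC is materially better with
  depth-limited trees and balanced-subsample class weights, so those are
  the defaults (overridable).
- **GBM budget.** Boosting defaults use 500 trees at learning rate 0.05 —
  the same total shrinkage budget as the often-quoted 2000 × 0.01, at a
  quarter of the fitting cost; on the synthetic study conditions the two
  settings are statistically indistinguishable.
- **GAM degenerate data.** On perfectly separable training data the
  unpenalized IRLS fit diverges; the fitter falls back to a
  ridge-stabilized logistic fit on the same spline basis. Spline bases are
  undefined outside the training range, so prediction inputs are clamped
  to it (constant extrapolation).

## Evaluation

Models are calibrated on a stratified random 80% of presences and
background and evaluated on the held-out 20%.

- **AUC** is computed in Mann–Whitney form (ties count ½).
- **TSS** = sensitivity + specificity − 1, reported at its maximizing
  threshold. Candidate thresholds are midpoints between consecutive
  distinct observed scores (plus sentinels beyond both extremes); ties in
  the objective (within 10⁻¹² — exact-tie detection is not float-stable)
  break toward the lowest threshold. A presence scoring exactly at the
  threshold counts as predicted-suitable; this closed-on-the-presence-side
  convention is used by every thresholding operation in the package.
- **Continuous Boyce index**: 101 moving windows of width 10% of the
  landscape-prediction range; per window, F = (presence fraction) /
  (landscape fraction); windows with zero landscape mass are dropped; the
  index is the Spearman correlation of F against the window midpoint. The
  window count and width follow the established continuous-Boyce
  convention. The reference distribution is the model evaluated over the
  whole landscape when available, else the background sample (itself a
  uniform sample of the landscape).
- **Permutation variable importance**: 1 − |Pearson r| between predictions
  on the original matrix and on the matrix with one column permuted,
  averaged over 10 permutations — the convention used by the biomod2
  ensemble platform. Ensemble-level importance permutes inputs of the
  equal-weight mean predictor; for speed it is evaluated on a random
  subsample of 500 design-matrix rows (configurable), which is ample for a
  correlation estimate.

**A structural note on attainable scores.** Because presences are sampled
with probability proportional to suitability (not thresholded on it), even
the *true* suitability surface cannot reach AUC ≈ 1: its AUC is bounded
near 1 − prevalence/2. At the default prevalence (~0.28) the truth scores
AUC ≈ 0.82–0.86 and Boyce ≈ 0.91–0.97. Fitted-model AUCs around 0.8 on the
synthetic conditions therefore indicate near-ceiling performance, not
mediocre models. The Boyce curve needs a few hundred held-out presences to
stabilize; with only dozens of test points it is noisy by construction.

## Ensemble and risk surface

The per-species ensemble is the unweighted mean of the five method
surfaces (a TSS-weighted mean is available via configuration). The risk
surface is the raw cellwise product of the per-species ensembles, kept on
its natural [0, 1] scale; a min–max rescaled copy is available for display
only. Binary suitable/unsuitable maps use the maxSSS threshold (the
threshold maximizing sensitivity + specificity on the held-out data).

Three-class risk maps (not at risk / moderate / high) use two explicit
thresholds with closed upper intervals (value ≥ t_high ⇒ high). Per
species the defaults are t_suitable = the ensemble's maxSSS threshold and
t_high = the midpoint between t_suitable and the maximum observed
suitability; for the multi-species product, whose scale shrinks with the
number of factors, both thresholds are explicit configuration keys
(defaults 0.05 and 0.25) and are recorded in the run manifest.

## Exposure tabulation

Villages take the class of the cell containing them, under a half-open
membership rule (closed on a cell's left and bottom edges) so no point
ever belongs to two cells; points outside the extent or on nodata cells
are dropped and counted. Suitable area is the number of suitable cells
times cell area; the synthetic CRS is projected equal-area with 1 km²
cells, and for geographic grids a per-row cos(latitude) scaling is
applied. The per-species "suitable area" uses the binary maxSSS map;
counting any-risk cells of the class map instead is a configuration
choice.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies on,
not the geography:

- **Layers**: Gaussian white noise smoothed to a requested autocorrelation
  length (default 10 cells), standardized; inter-layer correlation induced
  by mixing with a shared field (default pairwise target 0.3), which keeps
  all variance inflation factors well below the screening cutoff of 5 —
  matching the low-collinearity predictor sets typical of screened
  climate/vegetation/topography/footprint stacks.
- **Species**: known logistic-linear suitability in a small subset of
  layers. The default study species uses two drivers with a 2:1 strength
  ratio (coefficients 4 and 2 on standardized layers) and intercept −3,
  i.e. a sharp response at moderate prevalence (~0.28) — strong enough
  that truth recovery is meaningful, rare enough that discrimination
  metrics have headroom. The four-species pipeline default mirrors a
  configuration where three species share one dominant climatic driver
  and the fourth responds to a different one, with presence record counts
  of 89, 68, 54 and 37.
- **Presences**: cells drawn with probability proportional to true
  suitability, points at cell centres; optional one-per-cell
  deduplication (off by default). **Villages**: uniform over the valid
  extent (default 1,850 — a 1:100 scale-down of a national gazetteer's
  185,000, keeping counting statistics meaningful at desk scale).

Not emulated: realistic marginal distributions of climate variables,
anisotropy, gradients and coastlines, spatial sampling bias in occurrence
records, and clustered (non-uniform) settlement patterns. Passing tests
therefore demonstrate that the machinery recovers known structure under
the model's own assumptions, not that any particular real-world map is
correct.

## Default problem sizes

Screening uses a random sample of up to 10,000 cells for the VIF solves.
The recovery experiments run on a 200×200 grid with 7 layers, 100
presences and 10,000 background points over 10 seeds; the end-to-end
pipeline default is a 150×150 grid with four species and all five methods.
These sizes keep a full run on one CPU in the minutes range while leaving
every estimate comfortably stable.

## Numerical conventions and degenerate inputs

- Exactly collinear predictors report VIF = ∞ rather than raising;
  constant predictor columns are dropped with a warning before fitting.
- Constant model predictions make permutation importance undefined; it is
  reported as 0 with a warning.
- A constant landscape-prediction vector makes the Boyce index undefined
  (zero range); fewer than 3 usable windows raises an error.
- All generators and fitters are pure functions of (arguments, seed);
  per-stage pipeline seeds are derived as blake2b(master_seed, stage,
  species), so adding a species never perturbs another's results.

## Known limitations

- No spatially blocked cross-validation; the 80/20 split ignores spatial
  autocorrelation, which inflates held-out scores on strongly
  autocorrelated landscapes (a property shared with the workflow this
  package operationalizes).
- One background sample and one split per species (no replicates), though
  both are seed-controlled and configurable.
- The risk product has no probabilistic interpretation as encounter
  probability; it is a relative index.
- Geographic-CRS support is limited to cos(latitude) area scaling; no
  reprojection or resampling is provided.
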
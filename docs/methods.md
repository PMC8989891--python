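# Methods

## Model

The core model is a gradient-boosted ensemble of shallow regression trees for
binary presence/absence data under Bernoulli (binomial deviance) loss. With
labels y ∈ {0,1} and additive log-odds F(x):

- initialisation: F₀ = log(p̄/(1−p̄)), the training prevalence log-odds;
- at each stage, a regression tree of depth ≤ `tree_complexity` is fitted by
  exhaustive variance-reduction splitting to the pointwise gradient z = y − p
  on a without-replacement subsample of `bag_fraction` of the rows;
- terminal-node values are replaced by a single Newton step
  γ = Σ_node(y−p) / Σ_node p(1−p) (denominator guarded at 1e−12);
- the tree's contribution is shrunk by `learning_rate` and added to F.

Single-tree fitting is delegated to `sklearn.tree.DecisionTreeRegressor`; the
boosting recursion, Newton updates, tree-count selection, relative influence
and partial dependence are implemented in this package, and the whole
recursion is verified against a literal straight-line transcription of the
algorithm on small instances (agreement to 1e−10).

**Tree-count selection.** Stratified k-fold cross-validation (default 10
folds) grows each fold's model in increments of `step_size` trees and records
the mean held-out deviance per candidate count; growth stops early when the
minimum has not improved for `patience` increments, and the count at the
minimum is used to refit on all rows. This mirrors the staged
cross-validation procedure popular in ecological BRT work.

**Categorical predictors** (soil class) are handled by per-stage target-mean
ordering: each level is encoded by the mean boosting residual of its bagged
rows before the tree is fitted. For the squared-error criterion this yields
the same optimal binary partition as an exhaustive subset search, at linear
cost. A level unseen in a stage's bag is mapped to the heaviest (most
frequent) level's encoding at prediction time, i.e. it is routed with the
bulk of the training weight; occurrences are logged.

**Determinism.** All randomness (fold assignment, per-stage bags, per-stage
tree tie-breaking, ensemble splits, pseudo-absence draws) derives from one
master seed through `numpy.random.SeedSequence.spawn`, so a fixed seed
reproduces every output bit-for-bit. Equal-gain split ties are resolved by
the seeded tree learner rather than a variable-index rule; test fixtures that
compare against the straight-line oracle are constructed with strictly unique
best splits so this choice is unobservable there.

**Relative influence** of a covariate is the sum, over all splits using it in
the selected trees, of the squared-error improvement
w·imp(parent) − w_L·imp(left) − w_R·imp(right), normalised to sum to 100.
**Partial dependence** is computed, by default, by sweeping the target
covariate over a grid while all other continuous covariates sit at their
training means and categoricals at their modes (an averaged-over-training-rows
mode is available). **AUC** uses the exact Mann–Whitney rank statistic with
midranks for ties.

## Pipeline assumptions and parameters

- Grid: regular geographic grid, EPSG:4326, half-open cell intervals so a
  point on a shared edge belongs to exactly one cell; default resolution
  0.05°.
- Pseudo-absence envelope: temperature outside [5.8, 28.4] °C **or**
  precipitation outside [400, 1900] mm. The OR reading is the default because
  requiring both (cold *and* dry, say) leaves almost no eligible background;
  an `logic="and"` flag provides the stricter reading. Absences are sampled
  uniformly without replacement, disjoint from presences, one per presence by
  default.
- BRT defaults: learning_rate 0.01, tree_complexity 5, bag_fraction 0.75,
  10 folds, step_size 50, max_trees 1000, min_obs_in_node 10 — conventional
  values in the ecological BRT literature; the demo and tests use faster
  settings (rate 0.05, depth 2–3, max 75–200 trees) chosen so a full run
  completes in seconds while remaining in the regime where cross-validation
  has something to choose.
- Ensemble: 30 members by default, independent label-stratified 50/50
  train/test resplits per member; a with-replacement row bootstrap is
  available behind `bootstrap_rows=True` since "bootstrapped" admits either
  reading. The uncertainty map uses the population SD (ddof 0): the ensemble
  is the whole population of fitted members. Raster prediction streams in row
  tiles; output is independent of tile size (tested).
- Marginal land: threshold 0.5 inclusive (ties suitable; configurable);
  allowed classes are woody savannas, savannas, closed shrublands, open
  shrublands, grasslands — "shrublands" expanded to both IGBP shrubland
  classes, matching the five-class composition reporting. Areas use the exact
  spherical formula with R = 6371.0088 km; a `flat_count_ha` mode (e.g.
  2 500 ha per nominal 5 × 5 km cell) is provided because published accounts
  often do not state their convention.
- Bioenergy: defaults are *derived*, not sourced — yields 954.22 and
  1695.61 L ha⁻¹ yr⁻¹ back-calculated from published 50%-utilization volumes
  over 1311.85 Mha, and 0.73 / 2.92 kg CO₂e L⁻¹ back-solved from the published
  abatement ranges; with these, all twelve published volume/abatement/
  goal-share figures are reproduced after two-decimal rounding. Rounding is
  round-half-even and applied only at report time.

## Synthetic data: what it emulates, what it does not

The generator produces nine covariate layers (vapour pressure, temperature,
solar radiation, precipitation, soil water, soil class, soil depth,
elevation, slope) as Gaussian-smoothed white noise affinely rescaled into
field-realistic ranges, with per-layer smoothness σ in cells. Temperature
carries a monotone north–south gradient so the climatic envelope partitions
the map spatially; a border ring of NoData plays the ocean; the default grid
spans 22° of latitude so spherical cell areas vary materially. The true
suitability surface is the inverse-logit of a weighted sum of standardised
covariates (optional quadratic terms), default weights temperature 2.5 and
precipitation 1.0 — a climate-dominated truth whose signal is identifiable
through the envelope-based background design. Occurrence records (default
1923, drawn with replacement so gridding has duplicates to collapse) are
sampled proportionally to suitability and jittered within cells. Land cover
is a rank-transform of one smoothed field sliced at the cumulative class
probabilities, giving spatially clumped classes with near-exact requested
fractions. Generation fails loudly if fewer than 1% of valid cells satisfy
the pseudo-absence envelope.

What it does **not** emulate: the marginal distributions, cross-correlations
and anisotropies of real climate/soil/terrain products; spatial sampling bias
of real occurrence archives (roads, herbaria, country effects); coordinate
error; non-climatic range limits (dispersal, biotic interactions, land-use
history). Passing tests therefore demonstrate that the machinery is correct
and that planted effects of stated size are recoverable under clean
conditions — not that any real-world suitability map or AUC is right.

**Identifiability caveat.** Because pseudo-absences are defined by the
temperature/precipitation envelope, those two covariates acquire influence
from the sampling design itself. Planted-effect *rank recovery* is therefore
tested in two regimes: end-to-end with the planted weights on the envelope
axes (where the design reinforces the truth), and at the estimator level with
the strong weight on a non-envelope covariate (vapour pressure) against a
uniform background, where recovery is attributable to the model alone. The
estimator-level check uses weights 3.5/2.0, smoothness σ = 4 cells, a
150 × 150 grid and 300 presence records with 150 depth-2 trees; under these
conditions the correct ranking is recovered in at least 28 of 30 seeded
replicates.

## Numerical choices and degenerate inputs

- Probabilities are clipped to [1e−12, 1−1e−12] inside deviance computations;
  predictions themselves are exact inverse-logits and lie strictly in (0,1).
- A model with zero trees predicts the prevalence; relative influence is an
  error when no split exists.
- Empty marginal rasters tabulate to an all-zero table with percentages
  reported as 0 and a warning, not an error.
- Cell assignment uses floor on (coordinate − origin)/resolution; points
  outside the grid and cells with NoData in any covariate are dropped with
  logged counts.
- Area accounting accumulates per (zone, class) with a fixed iteration order,
  so zone totals equal the grand total exactly and the result is independent
  of raster processing order.

## Known limitations

- No spatial cross-validation: fold assignment is stratified by label only,
  so spatial autocorrelation inflates held-out AUC here exactly as it does in
  much of the SDM literature.
- The envelope treats each climate axis as independently disqualifying; a
  joint (AND) reading is available but untested against real data.
- No support for monotonicity constraints, interaction statistics, or losses
  other than Bernoulli deviance.
- Political/continental borders are not shipped; zonal accounting expects a
  user-supplied integer zone raster with a name table.
- ASCII-grid I/O is exact for the synthetic workflow but makes no attempt at
  GeoTIFF compatibility, compression, or very large rasters.
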
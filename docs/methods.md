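# Methods

## The model

Somatic point mutations do not accumulate uniformly along the genome: at
the megabase scale, regional mutation density in a tumour, precancerous
lesion or normal clone correlates strongly with the chromatin
organisation of the tissue the sample came from (heterochromatic,
late-replicating regions accumulate more mutations; open, active
chromatin fewer).  `chromorigin` exploits this to predict the tissue- or
cell-of-origin (TOO/COO): among a compendium of ChIP-seq chromatin-mark
tracks from many tissues and cell types, the track that best explains a
sample's regional mutation density landscape points to its origin.

Formally, for a sample with mutation counts `y_i` over retained 1-Mb
autosomal windows `i = 1..N` and a windows × features matrix `X` of
per-window ChIP-seq read counts (one column per mark × tissue
combination), we regress `y` on `X` with a gradient-boosted tree ensemble
(squared-error objective) and rank features by how much they contribute
to the fit:

1. **Screening.** Fit the boosted model in each of 10 cross-validation
   training splits; each feature's screening importance is its
   *total gain* (summed loss reduction over all splits using it),
   averaged over folds.  The top 20 features by screening importance are
   kept.
2. **Backward elimination.** Refit on the surviving features using the
   full data, drop the feature with the smallest gain, and repeat until
   one feature survives.  Rank 1 is the survivor — the chromatin track
   whose per-window profile is most similar to the mutation landscape.
3. **Origin assignment.** The predicted TOO/COO is the tissue/cell type
   of the rank-1 feature, looked up in the feature metadata.

Tree ensembles are invariant to monotone transforms of individual
columns, so raw read counts are used as features without library-size
normalisation (an optional per-column total-count scaling exists).
Counts enter the regression untransformed by default; a `log1p` target
option is provided.

### Boosting hyperparameters

| parameter       | default | allowed grid                                | notes |
|-----------------|---------|---------------------------------------------|-------|
| `learning_rate` | 0.5     | 0.05, 0.1, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0 | shrinkage per boosting round |
| `n_estimators`  | 20      | any ≥ 1                                     | boosting rounds per fit; no early stopping |
| `gamma`         | 0       | 0, 0.5, 1, 2                                | minimum loss reduction to split |
| `max_depth`     | 6       | 1, 3, 6, 8                                  | per-tree depth |
| `cv_folds`      | 10      | any ≥ 2                                     | screening-stage CV |

Off-grid values are rejected unless an explicit override flag
(`allow_any` / `--allow-any-params`) is set; the grids keep runs
comparable to the reference configuration.

### Interpretation points

Three details of the ranking procedure are underdetermined in the
literature this design follows, and are fixed here as explicit choices:

- **Importance metric** is total gain (not split count or cover): the
  regression-relevant choice; recorded in `ImportanceVector.metric`.
- **Elimination-stage fits** use the full data without CV (the CV
  averaging applies to the screening stage); a per-step CV switch
  (`eliminate_with_cv`) exists but multiplies cost by the fold count.
- **Ties**, including features with zero importance (never split on),
  are eliminated by ascending feature id, zero-importance features
  necessarily before any positive-importance feature.  A deterministic
  tie rule is required for reproducibility.

Inside the elimination stage, surviving features are kept in ascending-id
column order, so every step's fit and RNG stream is reproducible from the
step index alone.

### Seeds

One user-facing integer seed drives everything.  Derived seeds are
produced by a splitmix64-style mix of the seed with context tokens
(stage name, fold, repeat index, subset size, iteration); all derived
seeds are below 2^31.  Repeat runs (`repeat_predictions`) use consecutive
base seeds; per-iteration subset seeds are derived from (seed, size,
iteration) so extending a sweep never perturbs existing iterations.

## Random-forest baseline

The comparison ranker is a bagged regression forest with classical
Breiman permutation importance: for each tree (bootstrap sampled with
replacement), the importance of feature *m* is the increase in mean
squared error on the tree's out-of-bag rows when column *m* is permuted
within them (permuted minus untouched, so positive = informative),
averaged over trees.  Ranking then proceeds exactly as in the boosted
method: screen to the top 20 by importance, backward-eliminate with
per-step refits, assign the origin from the rank-1 feature.

The bagging loop is explicit — one `DecisionTreeRegressor` per tree with
known bootstrap indices — because per-tree OOB permutation importance
requires the per-tree bag.  Trees follow the classical regression-forest
settings mtry = p/3 and minimum leaf size 5.  `n_trees` defaults to 1000;
the test suite and the acceptance script run reduced forests (documented
below).  Trees whose bootstrap covers every row (possible only at tiny N)
are skipped for importance with a warning.  No attempt is made to match
any particular forest implementation bit-for-bit; comparisons with the
boosted ranker are statistical.

## Windows, counting, filtering

- **Windows**: autosomes tiled from position 0 in 1-Mb steps (trailing
  partial tile dropped); a window is removed when more than
  `excluded_fraction_max` (default 0.5) of its bases fall in the merged
  exclusion intervals (centromeres, telomeres, poorly mappable regions).
  No exclusion list is bundled — the user supplies a BED, the simulator
  writes a toy one.  The retained count N is therefore data-dependent.
  Coordinates are 0-based half-open internally (BED convention); VCF
  positions are converted by subtracting 1.
- **Mutation counting**: point position only (SNV position / indel
  start); variants outside retained windows or on unknown chromosomes
  are dropped and counted, not errors.
- **ChIP-seq read counting**: each read interval is assigned to the
  window containing its midpoint, so boundary-straddling reads are
  counted exactly once.
- **Density** is mutations per retained window (= per Mb at the default
  width).  Hypermutator handling is an explicit density filter
  (`filter_by_density`), not a hard-coded threshold; clone-level
  analyses can draw density-stratified samples
  (`stratified_density_sample`, bins of width 0.25 by default in the
  published design).

## Region subsets and enhancer-constrained subsets

`subset_accuracy` measures how often the prediction from a random subset
of windows matches the full-region prediction (computed with the same
ranker, parameters and seed — the ranker seed is fixed across iterations
and only the subset draw varies, so the full-size subset reproduces the
reference exactly).  Enhancer-constrained subsets first draw
`round_half_up(proportion × n_total)` windows from the
enhancer-containing stratum (windows overlapping ≥ 1 bp of any enhancer
interval — full containment is not required), then fill from the
remaining windows; a shortfall in either stratum is filled from the
other.  The quota arithmetic is checked exhaustively on small universes.

## The simulator

`simulate_chromatin` plants the structure the method assumes: each
tissue gets a standard-normal latent per-window profile; feature `k` of
tissue `t` is `sqrt(ρ)·latent_t + sqrt(1−ρ)·noise`, rendered as
negative-binomial read counts through a log link (mean 500 reads/window,
log-scale spread 0.5, NB size 10).  `simulate_mutations` draws
`y_i ~ Poisson(μ_i)` with `μ ∝ exp(b·z + ε)`, `z` the standardized driver
latent, `ε ~ N(0, 0.3²)`, normalised so mean density equals
`baseline_density` exactly in expectation.

Defaults are the reference study conditions: 2128 windows (across 22 toy
autosomes), 8 tissues × 8 features, within-tissue correlation ρ = 0.9,
effect size b = −1.0 (negative: mutation depletion in active chromatin;
tree rankers are sign-agnostic), baseline density 1.0 — the
normal-clone regime; stem cells sit near 0.1 and tumours above 5, and
the low-density acceptance checks run at 0.1.  The noise scale 0.3 and
the chromatin read-count parameters are the package's own choices of a
realistic regime; they were fixed once when the generator was written.

The simulator reproduces *only* the density–chromatin coupling: it has
no mutational signatures, no replication-timing gradient, and no spatial
autocorrelation along the genome.  Passing the recovery tests therefore
shows the ranking machinery identifies a planted driver under count
noise at realistic densities — not that real tumours are predicted at
the published accuracies, which depend on controlled-access cohorts.

## Problem sizes in the test suite and acceptance script

All stochastic checks are sized to run on a single CPU in minutes:

- boosted-ranker recovery: 40 simulation seeds per density;
- forest comparison: reduced forests (`n_trees = 200`), with the seed
  budget concentrated where the paired boost-vs-forest comparison is made
  (16 paired seeds at density 0.1, 6 at density 1.0; one full-size forest
  ranking costs ~200 × 20 tree fits at N = 2128);
- subset sweep: sizes {100, 300, 500, 700, 1000, 2000} × 20 iterations;
- enhancer-proportion contrast: 100-region subsets × 20 iterations;
- `scripts/acceptance.py` uses 12 boost seeds, 4 forest seeds at
  `n_trees = 150`, and 10 subset iterations per condition.

Directional comparisons at these sizes are coarse (granularity 1/16 for
the low-density forest rate) but the underlying effects are large;
rates, not per-seed outcomes, are compared.

## Known limitations

- In this synthetic family the forest baseline is at least as accurate
  as the boosted ranker at sparse density (the acceptance script reports
  both recovery rates at baseline density 0.1): the bagged forest's
  averaging is robust to sparse-count noise, while the 20-round,
  learning-rate-0.5 boosted fits are sensitive to it.  Reported
  sparse-data advantages of boosted rankers on real cohorts arise from
  data structure this generator does not emulate, and the corresponding
  directional test is expected to fail under these conditions.

- The retained-window count of any real run depends on the user's
  exclusion BED; no blacklist is shipped.
- GRCh37 coordinates are assumed; no liftover is performed.
- No mutation-signature stratification; origin prediction uses total
  regional density only.
- The forest baseline is a faithful Breiman-importance ranker, not a
  re-implementation of any specific R pipeline; agreement is expected at
  the level of rankings, not importance values.
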
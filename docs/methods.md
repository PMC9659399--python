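# Methods

## Expression space

An expression is a point in a blendshape rig: 149 rendered dimensions, each
weighted by a fraction of maximal activation in [0, 1].  Only 46 *core*
units are free to vary; the rig is driven as
`rig = clip(C · core, 0, 1)` with a nonnegative 149×46 coupling matrix `C`.
The production rig's anatomical coupling is proprietary to the rendering
pipeline, so the default map partitions the 149 rig dimensions into 46
contiguous groups (11 of four dimensions, 35 of three), each driven
identically by its core unit with coefficient 1.0.  This preserves the
46-independent / 149-rendered structure without inventing anatomy; a real
rig loads through the same versioned file format (`CoreMap.load`).

Dissimilarity is cosine distance, `CD = 1 − cosθ`.  On the nonnegative
orthant it lies in [0, 1], is zero exactly for positively collinear
expressions (so overall intensity is ignored), and is well behaved in high
dimension.  Distances are computed on the 46-dimensional core
representation by default — the space the algorithm actually searches;
coupled rig dimensions would count each core unit several times.  PCA, by
contrast, operates on the expanded 149-dimensional rig by default (the
space in which cohorts are usually described), with a `representation`
switch in both places.

Each core unit carries a FACS label (action-unit number and name) from a
packaged table; units 28–45 are left/right variants of bilateral actions.
The per-emotion category means shipped as a fixture are hand-authored so
that each emotion's five most activated units are its characteristic action
units (happy: AU 12, 13, 6, 7, 1; fear: 5, 1, 2, 20, 4; angry: 4, 10, 11,
9, 16; sad: 15, 11, 17, 20, 7), with ranked weights 0.8–0.4, bilateral
variants at 0.75× their primary unit, and a 0.03 baseline elsewhere.  The
shared units (AU4 fear/angry, AU20 fear/sad, AU7 happy/sad, AU11 angry/sad)
give the synthetic categories the fear/sad-style overlap real cohorts show.

## The evolution loop

One session = 1 initialization trial + 10 evolved generations + a final
single choice (trial 11).  Initialization draws 10 expressions with each
core unit independently active with probability 0.3 and active weights
uniform on [0, 1] — sparse, diverse starting faces.  Each trial the
observer returns a selected subset (≥1) and a flagged best match.  Breeding:

- **elitism** — the flagged best match is copied unchanged into slot 0
  (the minimal mechanism by which the best-match flag influences evolution);
- **crossover** — for each remaining slot, two parents are drawn uniformly
  with replacement from the selected set and combined per core unit by
  uniform crossover (a `blend` convex-combination operator and a `none`
  mutate-clone operator are available but non-default);
- **mutation** — each core weight is perturbed with probability 0.6 by
  Gaussian noise with sd `0.35 · 0.8^g` at generation `g`, then clipped to
  [0, 1].

The annealed mutation schedule is the package's own design choice: with a
budget of ~110 candidate evaluations in a 46-dimensional space, a constant
mutation scale either keeps the population too noisy to converge or too
cold to reach the target; a geometric anneal gives broad early exploration
and fine late refinement, reproducing the empirical signature of the
interactive procedure — rapid early movement, then constant selected-face
variance from about the seventh trial.  All three parameters are exposed in
`GAConfig`.

### Convergence diagnostics

`convergence_profile` records, per trial, the mean pairwise CD among the
observer-selected candidates (their *dispersion*).  The plateau is the
first generation after which the dispersion change between every later pair
of consecutive generations stays below 5% of the profile's maximum
dispersion.  Denominating by the profile scale rather than by the previous
value is deliberate: near the converged floor the dispersion is a small
fluctuating quantity and ratio-to-previous changes are O(1) noise, so a
rule based on them would never fire (`rel_to="previous"` is available).
Single-selection trials (the final pick) have zero dispersion by
construction; they are flagged in the profile and excluded from the plateau
rule because a forced single choice carries no dispersion information.

## Simulated observers and cohorts

An observer holds a latent target expression and scores each candidate as
`−CD(candidate, target) + N(0, σ_d)`; it selects the top k = 3 scores
(a below-threshold rule is available) and flags the top scorer.  Decision
noise defaults to σ_d = 0.02, comparable to late-session score spreads, so
early selections are near-deterministic and late ones somewhat noisy.  An
all-zero candidate (possible at initialization) is treated as maximally
distant — it expresses nothing of the target.

A synthetic cohort draws, for each of N participants × 4 emotions, a latent
target `clip(category_mean + N(0, σ_b))` with σ_b = 0.15 per core unit by
default, runs one full session per cell, and keeps the preferred
expressions.  The defaults (N = 24, σ_b = 0.15) produce cohorts whose
within-category scatter is dominated by the injected subject variance
rather than GA noise, and whose categories are separable but adjacent —
the qualitative regime reported for human cohorts.

What the generator deliberately does *not* model: semantic or conceptual
idiosyncrasy (targets are pure geometric jitters of a shared mean),
heavier-tailed subject variation, learning or fatigue across trials, and
any rendering step.  Passing tests therefore show that the *analysis
machinery* behaves correctly under a known generative model, not that human
data will show any particular effect size.

## Noise thresholds and exceedance

The GA is stochastic, so two evolutions toward the *same* target still
differ.  `simulate_noise` evolves `n_iter` (default 500) independent
sessions toward a fixed target — the cohort's own per-emotion centroid,
i.e. the "average" expression — and takes the arithmetic mean of all
pairwise CDs among the finals as the *noise threshold* (a percentile rule,
e.g. `p95`, is available but non-default since the mean is the quantity the
analysis is defined on).  The exceedance fraction is the share of observed
between-participant pairwise CDs strictly above their emotion's threshold;
the pooled value counts every observed pair against its own emotion's
threshold.  With default settings the thresholds sit near 0.28 CD.  A
cohort generated with σ_b = 0 is the same process as the null and pools to
an exceedance near one half (slightly below, as CD distributions are
right-skewed); exceedance rises monotonically with σ_b.

## Category structure

PCA is computed on centered, unscaled weights — every dimension already
shares the [0, 1] activation unit, and correlation-mode scaling would
inflate near-constant units (a `standardize` flag exists).  The Gaussian
mixture uses k = 4 full-covariance components (k fixed to the emotion
count), 10 seeded restarts keeping the best likelihood, and `reg_covar`
regularization escalated and flagged if a component degenerates.  Clusters
map to emotions by the bipartite assignment maximizing the total diagonal
count (Hungarian algorithm), which keeps the mapping a bijection even when
one cluster absorbs two labels — exactly the fear/sad overlap case a
majority vote mishandles.  Confusion rows are fractions of each true label,
so rows sum to 1.

Fingerprints are per-emotion column means and population SDs (ddof = 0 —
the cohort is described in full, not sampled; a `ddof` switch exists) of
the core weights, with top-5 peak and top-5 variability rankings labeled by
action unit.  `mean_sd` is in weight-fraction units; ×100 gives the
"percent of maximal motion" reading.  The SVM check uses a linear kernel,
C = 1, stratified 5-fold cross-validation (folds reduced and flagged if a
class is smaller), reporting out-of-fold overall accuracy, per-class
recall, and fold-wise dispersion.

## Recognition analysis

Simulated perceivers label every stimulus with probability
`softmax(−CD(stimulus, own preferred of e) / τ)` over the four emotions,
τ = 0.05 by default — chosen to put overall accuracy near 0.7–0.8, the
range typical of forced-choice expression categorization, while leaving
headroom for a similarity gradient.

For the binned analysis, each trial's CD is measured against the
perceiver's *own* preferred expression of the stimulus's *true* category.
Bins are per-perceiver equal-count quantiles of those CDs, collapsed across
emotions (quantile bins guarantee occupancy; a rank-based construction
makes the binning invariant to any monotone transform of CD).  Ties and
remainders resolve deterministically: stable argsort by trial order, lower
bins take the extra trials.

The permutation null swaps whole four-emotion preferred-expression sets
across perceivers (per-emotion independent swapping is an option),
recomputes the binning, and pools accuracy per bin; 10,000 permutations by
default.  Because a permutation only re-indexes which preferred set each
perceiver uses, per-bin counts are precomputed for every (owner, perceiver)
pair once, making each permutation O(perceivers).  The highest-CD bin is
tested one-sided (lower tail — the effect of interest is an accuracy drop
far from the preferred expression); other bins two-sided; all p-values use
the +1 correction.  Accuracies live on a lattice, so ties with the null are
possible: the default counts ties fully (valid, slightly conservative),
and `tie_break="random"` assigns the observed value's rank among ties
uniformly at random, which makes the one-sided p exactly discrete-uniform
under the exchangeable null — the form used for calibration checks.

## Reproducibility and problem sizes

Every stochastic stage receives a child seed derived from the global seed
and a stable stage label (CRC-32 of the label into a `SeedSequence` spawn
key), so adding a stage never perturbs earlier stages.  Pipeline outputs
embed the configuration hash (output paths excluded) and seed.

Default analysis sizes follow the procedure the package models: 10
candidates, 10 generations, 500 noise iterations, 10,000 permutations, 4
bins, 10 principal components.  The test suite and the acceptance script
use smaller cohorts (8–40 participants), 60–100 noise iterations and a few
hundred permutations — sizes at which every statistic here is already
stable to within the tolerances asserted, as the Monte-Carlo checks in the
suite verify.

## Known limitations

- The default core-to-rig coupling is a structural stand-in, not the
  production rig's anatomy; rig-space analyses with the default map are
  block-duplications of core-space ones.
- The GA search is sample-starved by design (110 evaluations, 46
  dimensions), so evolved expressions approach but do not reach their
  targets; the noise-threshold analysis quantifies precisely this.
- Simulated observers are distance-plus-noise agents; effects that depend
  on perceptual nonlinearity, attention or semantics are out of scope.
- The permutation test's block swap assumes perceivers are exchangeable;
  cohorts with structured subgroups would need a stratified swap.
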
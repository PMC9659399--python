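# evoface

Tools for studying *preferred facial expressions* — the particular
configuration of facial features each person believes best depicts an
emotion — and for asking how individual differences in those expressions
shape emotion-recognition performance.

The experimental paradigm it models is interactive stimulus evolution: a
photorealistic avatar face is posed by a 149-dimensional blendshape rig
(46 of those dimensions move independently; the rest are driven through a
coupling map), and a genetic algorithm (GA) evolves candidate expressions
under an observer's selections.  On each trial the observer sees 10
candidate faces, selects those resembling the target emotion (happy, fear,
angry or sad) and flags the single best match; selections are bred into the
next generation by uniform crossover and annealed Gaussian mutation, with
the best match preserved unchanged.  After 10 evolved generations the
observer picks one face — their preferred expression for that emotion.

`evoface` replaces human participants with parameterized simulated
observers (latent target expression + top-k selection + decision noise), so
the whole analysis stack is testable offline:

- **blendspace** — expression vectors, the 46→149 core-to-rig coupling,
  FACS action-unit labels, and cosine distance
  `CD(a, b) = 1 − a·b / (‖a‖‖b‖)`, the dissimilarity metric used throughout.
- **ga_engine** — the generational evolution loop and convergence
  diagnostics (per-trial dispersion of selected candidates, plateau rule).
- **observers** — simulated participants and synthetic-cohort generation:
  per-participant latent targets are Gaussian jitters of per-emotion
  category means.
- **noise_sim** — GA stochastic-noise thresholds: the mean pairwise CD among
  expressions evolved repeatedly toward the *same* target, and the
  exceedance fraction of observed between-participant CDs above it.
- **category_stats** — PCA of the cohort, 4-component Gaussian-mixture
  clustering with a cluster↔emotion confusion matrix, per-emotion
  blendshape fingerprints (mean/SD per core unit, AU-labeled rankings), and
  cross-validated SVM prediction of emotion from blendshape weights.
- **recognition** — simulated forced-choice recognition trials, per-perceiver
  CD-quantile binning of accuracy, and a permutation test that swaps whole
  preferred-expression sets across perceivers to control for the shared
  central tendency.

## Worked example

Run the full pipeline on a small synthetic cohort (32 participants × 4
emotions, 100 noise-simulation iterations per emotion, 2,000 permutations):

```sh
cat > config.yaml <<EOF
seed: 0
cohort:
  n_participants: 32
analysis:
  n_iter: 100
  n_perm: 2000
  n_perceivers: 8
EOF
evoface run-all --config config.yaml --out-dir out
```

This takes a few seconds and prints a JSON summary.  Key numbers from that
run and what they mean:

- `noise.pooled_exceedance: 0.749` — 75% of between-participant expression
  pairs differ by more than the GA's own stochastic noise (per-emotion
  thresholds ≈ 0.28 CD), i.e. most of the simulated cohort's heterogeneity
  comes from the injected between-subject variation, not the algorithm.
- `category.gmm_diagonal: [1.0, 1.0, 1.0, 1.0]` — the Gaussian mixture on
  the first 10 principal components (56% of variance here) recovers all
  four emotion categories perfectly at this separation.
- `category.svm_overall: 1.0` — a cross-validated linear SVM predicts the
  targeted emotion from the 46 core blendshape weights.
- `recognition.observed: [0.887, 0.812, 0.676, 0.422]` with
  `p_values: [0.001, 0.001, 0.787, 0.0005]` — recognition accuracy falls as
  the test stimulus gets farther (in CD) from the perceiver's own preferred
  expression, and the far-bin drop is significant against the
  preferred-expression-swap null (one-sided p ≈ 0.0005).

Every subcommand is also available separately (`evoface --help`):
`simulate-session`, `generate-cohort`, `noise-sim`, `cluster`,
`fingerprints`, `recognition-sim`, `permtest`.

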
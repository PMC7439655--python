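# Methods

## Model and procedure

The package evaluates unsupervised pre-training as a weight-initialization
scheme for binary disease classifiers on samples × features tables. The
procedure has four stages.

**Preprocessing.** Columns whose non-missing values contain at most one
distinct value are removed (an all-missing column counts as constant:
zero distinct values). Remaining missing cells are imputed per column —
arithmetic mean by default, constant zero or the modal value as
alternatives; the modal fill resolves ties to the smallest value. When
several cohorts are combined, tables are restricted to the set-intersection
of their feature names in lexicographic order (the protocol never states an
order; a canonical one is required for cross-cohort concatenation and
determinism). Class downsampling is a seeded uniform draw without
replacement that preserves row order. One-vs-rest labeling maps the class
of interest to 1 and all others to 0. The stage order is fixed and
idempotent: re-running the pipeline on its own output changes nothing.
Imputation is fitted on the whole table by default (protocol-faithful); a
fold-safe mode fits only on each training fold (`cross_validate(...,
imputation=...)`) for users who want to exclude that leakage path.

**Autoencoder pre-training.** Encoder f (parameters θe) and decoder g (θd)
are symmetric stacks of dense layers; hidden layers use ReLU. The
reconstruction output layer is linear: the inputs are z-scored (signed), so
a ReLU output could not represent them and reconstruction error would be
bounded away from zero. Three variants share one objective family:

* basic: J = MSE(X, g(f(X)))
* denoising: J = MSE(X, g(f(X̃))); X̃ zeroes each input unit independently
  with probability `corruption_rate` (default 0.10). Corruption is plain
  Bernoulli masking without inverted-dropout rescaling, exists only during
  AE training, and the loss always compares against the clean X.
* sparse: J = MSE + λ·Ω(θe), with Ω the L1 norm over all encoder
  parameters (weights and biases) and λ = 10⁻⁵ by default.

AEs train for 300 epochs with minibatch Adam at batch size 100.

**Assembly.** The classifier imports AE weights under five strategies:
encoder only; full AE; encoder plus a freshly initialized decoder of
identical shape (a parameter-count-matched control separating the value of
pre-trained decoder weights from depth); no imported block (baseline); and
an untrained AE of the same shape (baseline). Imported values are copied
bit-for-bit. The head appended after the imported block is batch
normalization, Dense(64, ReLU), Dense(32, ReLU), Dense(1, sigmoid). The
head widths are not fixed by the protocol; 64 and 32 are the package
defaults, below the default latent size of 128, and configurable. Batch
normalization sits immediately after the imported block, before the first
head layer's affine map. Under approach "fixed" every imported parameter is
flagged non-trainable and the optimizer never touches it (hence bitwise
equality after any amount of training); under "fine_tune" all layers train.
The decision rule calls a sample positive when the sigmoid output is ≥ 0.5;
the tie at exactly 0.5 resolves to positive.

**Training and evaluation.** Classifiers train with Adam on binary
cross-entropy, 500 epochs at batch size 100 by default. Evaluation is
stratified k-fold cross-validation (default k = 10): per fold, the AE is
pre-trained on the fold's training portion (default; a whole-matrix option
mirrors the imputation switch), assembled, trained, and scored on the
validation portion every epoch; the epoch with the highest validation F1
(earliest on ties) supplies the fold's model and report. Summaries are
per-metric mean ± SD over folds (sample SD). The held-out workflow splits
off a stratified test fraction, cross-validates on the remainder, retrains
one final model on all training rows for the configured epochs (final
weights, no test-driven selection) and scores the test set once.

## Metrics

Accuracy, precision, recall and F1 are reported as percentages, MCC on
[−1, 1], all computed from the confusion matrix at the 0.5 threshold. Any
zero denominator (no predicted positives, one-class truth, ...) defines the
affected metric as 0 rather than raising — the conventional choice, and the
one consistent with all-zero rows appearing in degenerate configurations.
ROC and precision-recall curves sweep every distinct predicted probability
(no fixed grid); AUC integrates the ROC by the trapezoid rule. For
one-class inputs the curves are undefined and reported empty with AUC 0.

## Synthetic data

The generator emulates the statistical shape the analysis assumes rather
than any particular cohort: each sample's latent vector is Gaussian around
its class centroid (unit latent noise); centroids sit at the vertices of a
regular simplex with pairwise distance `class_separation` (in latent-noise
SDs), randomly rotated; a fixed random linear map lifts latents to feature
space, plus independent Gaussian observation noise of SD `noise_sd`.
Columns are then z-scored (default) or min-max scaled to [−1, 1]
(`scaled_unit`, the image-feature-like regime). A chosen number of constant
columns is mixed in at random positions, and a chosen fraction of
non-constant cells is masked as missing. Because the signal is linear of
rank `latent_rank`, an AE with latent width ≥ `latent_rank` can in
principle reconstruct the signal almost noiselessly — which is what makes
"the AE captures the essential structure" testable.

What the generator does **not** emulate: count distributions, library-size
or batch effects, gene–gene correlation beyond the low-rank factor,
nonlinear class boundaries, label noise, or the heavy, structured
acquisition noise of real assays. Tests passing on this generator show the
pipeline's mechanics are correct under its stated assumptions; they are not
evidence about any real cohort. One consequence is worth stating plainly:
on this clean, linearly separable generator with per-epoch best-F1
selection, the bare-head baseline trains well, so the *benefit* of AE
initialization over no-AE initialization is small or absent at desk scale —
the reproduction script reports both sides of that comparison rather than
asserting a direction. The benefit is expected to emerge in
noise-dominated, hard-to-optimize regimes, which is exactly where the
approach is motivated.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹. Single-threaded runs are
  bit-reproducible; the test suite asserts this for pre-training and
  cross-validation.
* Dense weights use Glorot-uniform initialization, zero biases. Batch
  normalization uses momentum 0.99 and ε = 10⁻³, biased batch variance,
  running statistics at inference.
* Adam uses β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷. The classifier's learning rate
  is 10⁻³. The AE pre-training default is 3·10⁻³: at desk-scale sample
  counts (hundreds of rows → two or three minibatches per epoch) the fixed
  300-epoch budget gives only a few hundred optimizer steps, and a
  convergence study on noiseless rank-4 data across eight seeds showed
  10⁻³ stalling between 0.2% and 5% of data variance while 3·10⁻³ reached
  ≤ 0.14% on every seed. Both rates are configurable.
* Binary cross-entropy clips probabilities to [10⁻⁷, 1 − 10⁻⁷] for
  numerical safety only.
* Deeper encoders (n = 2, 3 layers) interpolate hidden widths geometrically
  between the input width and the latent size — a convention; the protocol
  names the depths but not the intermediate sizes.
* The held-out test fraction defaults to 0.33 with ceiling rounding of the
  test share (the standard library splitter's convention); "one third" of
  569 samples is thus exactly 381 train / 188 test.
* Grid sweeps execute cells in lexicographic coordinate order, persist each
  cell as JSON keyed by a stable cell id, skip completed cells on re-run,
  and record per-cell failures without aborting the sweep.

## Problem sizes used by the test suite and reproduction script

Chosen as the package's own desk-scale conditions: reconstruction sanity
uses 200 × 100 noiseless rank-4 data (latent 8, 300 epochs); pipeline
recovery uses 300 samples × 500 features (rank 4, separation 6, 5% missing,
3 constant columns), 5-fold CV with the default 300/500 epoch budgets; the
initialization comparison uses 300 × 500 at separation 3 over five seeds
with 3-fold CV, AE 150 / classifier 200 epochs; determinism repeats run at
reduced size since bitwise reproducibility is scale-independent. Unit tests
use much smaller instances throughout.

## Known limitations

* The NN core is plain numpy: correct and reproducible, but not fast on
  large cohorts; the design targets method evaluation, not production
  inference.
* Imputation and AE pre-training default to the protocol-faithful
  whole-data scope in single-table runs; users studying generalization
  should prefer the fold-safe switches.
* MCC/precision/recall zero-denominator conventions make degenerate
  configurations comparable but slightly optimistic-looking in accuracy
  terms; always read them alongside the curves.
* Multi-class problems are handled only as one-vs-rest binary tasks; no
  softmax head, no ensembling across tasks.
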
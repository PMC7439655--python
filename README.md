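# aeinit

Autoencoder pre-training as a **weight-initialization method** for deep
binary disease classifiers on high-dimensional feature tables — bulk RNA-Seq
gene-expression matrices and image-derived feature sets alike.

## The problem

Disease-detection tasks on molecular data typically offer a few hundred to a
few thousand samples described by 10²–10⁴ features, with missing entries,
zero-information (constant) columns, and substantial acquisition noise.
Plain deep networks overfit badly in this regime. One remedy is to first
train an autoencoder (AE) to reconstruct the unlabeled feature table, then
copy its learned weights into the first layers of a supervised classifier —
the low-dimensional latent code captures the essential structure and
discards part of the noise before any label is seen.

`aeinit` implements that pipeline end to end for one-vs-rest binary disease
classification, for researchers who want to evaluate initialization
strategies under a controlled, fully reproducible protocol: a synthetic data
generator with a known latent manifold, the preprocessing rules, three AE
variants, the weight-import strategies and trainability approaches, the
stratified cross-validation protocol with its metric suite, and the
configuration sweeps — all deterministic given a seed, all runnable on one
CPU.

## The method

An autoencoder with encoder `f` (parameters θe) and decoder `g` (θd) is
trained to minimize reconstruction error:

* **Basic AE**  J(θ; X) = MSE(X, g(f(X)))
* **Denoising AE**  J(θ; X) = MSE(X, g(f(X̃))), where X̃ zeroes each input
  unit independently with probability 0.10 (training only)
* **Sparse AE**  J(θ; X) = MSE(X, g(f(X))) + λ·‖θe‖₁ with λ = 10⁻⁵

AEs train for 300 epochs (Adam, batch 100). The trained weights are then
imported into a classifier under one of two **strategies** — (1) encoder
layers only, or (2) the complete AE — and trained under one of two
**approaches** — (A) imported weights frozen, or (B) fine-tuned. Controls:
a bare head with no imported block, a random-weight AE of the same shape,
and an encoder plus a freshly randomized decoder (identical parameter count
to the full import, isolating pre-training from topological complexity).

The classification head is always batch-normalization → Dense(64, ReLU) →
Dense(32, ReLU) → Dense(1, sigmoid); probability ≥ 0.5 is called positive.
Classifiers train 500 epochs (Adam, binary cross-entropy, batch 100) and are
evaluated by stratified 10-fold cross-validation, selecting each fold's best
epoch by validation F1 and reporting accuracy, MCC, precision, recall, F1
(as mean ± SD over folds) plus ROC and precision-recall curves. A held-out
workflow splits off a stratified one-third test set scored exactly once.

Preprocessing follows the protocol's fixed order: remove columns with a
single distinct non-missing value → impute missing cells (column mean by
default; zero or modal value as alternatives) → intersect feature names
across cohorts → seeded class downsampling → one-vs-rest labeling.

The neural-network core (dense layers, batch-norm, Adam, backprop) is
implemented in numpy inside the package and verified against finite
differences; single-threaded runs are bit-reproducible.

## Worked example

```sh
aeinit simulate --n-classes 2 --samples-per-class 40,40 --n-features 60 \
    --latent-rank 3 --class-separation 6 --missing-fraction 0.05 \
    --n-constant-columns 2 --seed 4 --out sim.tsv
aeinit preprocess sim.tsv --strategy mean --positive-class class1 --out prep.tsv
aeinit evaluate prep.tsv --latent-dim 8 --folds 2 --epochs 30 --ae-epochs 30
```

prints

```
wrote 80 samples x 60 features to sim.tsv
removed 2 constant column(s); kept 80 samples x 58 features
loss         0.48 ±0.09
accuracy    97.50 ±3.54
mcc          0.95 ±0.07
precision   95.45 ±6.43
recall     100.00 ±0.00
f1          97.62 ±3.37
auc          0.97 ±0.04
```

The generator planted a rank-3 latent manifold with well-separated classes
(separation 6 latent-noise SDs) plus 5% missing cells and two constant
columns; preprocessing removed exactly those two columns and imputed the
rest; a basic AE (latent 8) was pre-trained per fold, its encoder imported
and fine-tuned, and 2-fold cross-validation recovered the class structure
almost perfectly (mean F1 97.6 ± 3.4, MCC 0.95). Sweeps over AE kinds,
import strategies, approaches, latent sizes and imputation strategies run
via `aeinit sweep` with a YAML grid, and `aeinit report` ranks the cells.

The same functionality is available as a library:

```python
from aeinit import (SyntheticSpec, generate_dataset, preprocess, AEConfig,
                    AssemblySpec, TrainConfig, cross_validate)

m, _ = preprocess(generate_dataset(SyntheticSpec(seed=4)), positive_class="class1")
_, summary = cross_validate(
    m, AEConfig(kind="basic", input_dim=m.n_features, encoder_layer_sizes=[128]),
    AssemblySpec(strategy="encoder_only", approach="fine_tune"),
    TrainConfig(folds=10, seed=4))
```

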
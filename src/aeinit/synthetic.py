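"""Synthetic feature-table generator.

Emulates the statistical shape of the study inputs: high-dimensional tabular
data (hundreds to tens of thousands of feature columns) whose class structure
lives on a low-dimensional latent manifold, with z-score-like continuous
values, a controllable fraction of missing cells, a controllable number of
constant (zero-information) columns, and an alternative image-feature-like
regime with values min-max scaled to [-1, 1].

The generative model is Gaussian-on-a-linear-manifold: each sample's latent
vector is drawn from an isotropic Gaussian around its class centroid (unit
latent noise), mapped to feature space by a fixed random linear map, plus
independent Gaussian observation noise. ``class_separation`` is the pairwise
distance between class centroids in units of the latent noise SD, so an
autoencoder whose bottleneck is at least ``latent_rank`` wide can in
principle reconstruct the signal almost noiselessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

VALUE_REGIMES = ("zscore", "scaled_unit")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``samples_per_class`` must have ``n_classes`` entries; ``latent_rank``
    may not exceed the number of non-constant feature columns.
    """

    n_classes: int = 2
    samples_per_class: list[int] = field(default_factory=lambda: [100, 100])
    n_features: int = 200
    latent_rank: int = 4
    class_separation: float = 6.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    n_constant_columns: int = 0
    value_regime: str = "zscore"
    seed: int = 0
    class_names: list[str] | None = None

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError(
                f"samples_per_class has {len(self.samples_per_class)} entries "
                f"for n_classes={self.n_classes}"
            )
        if any(s < 1 for s in self.samples_per_class):
            raise ValueError("samples_per_class entries must be positive")
        if self.n_features < 1 or self.latent_rank < 1:
            raise ValueError("n_features and latent_rank must be positive")
        if self.n_constant_columns < 0:
            raise ValueError("n_constant_columns must be non-negative")
        if self.latent_rank > self.n_features - self.n_constant_columns:
            raise ValueError(
                "latent_rank exceeds the number of non-constant feature columns"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.value_regime not in VALUE_REGIMES:
            raise ValueError(f"value_regime must be one of {VALUE_REGIMES}")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names must have n_classes entries")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))

    def labels(self) -> list[str]:
        names = self.class_names or [f"class{i}" for i in range(self.n_classes)]
        return [names[i] for i, c in enumerate(self.samples_per_class) for _ in range(c)]


def _class_centroids(k: int, rank: int, separation: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Latent centroids with pairwise distance = separation (exactly when a
    regular simplex with k vertices fits in `rank` dimensions, i.e.
    k - 1 <= rank; approximately otherwise)."""
    if k == 1 or separation == 0:
        return np.zeros((k, rank))
    if k - 1 <= rank:
        # regular simplex: identity corners recentred, edge length sqrt(2)
        corners = np.eye(k) - 1.0 / k
        # orthonormal basis of the (k-1)-dim simplex plane, embedded in rank dims
        q, _ = np.linalg.qr(corners.T[:, : k - 1])
        verts = corners @ q  # k x (k-1)
        verts = verts / np.sqrt(2.0) * separation
        embed = np.zeros((k, rank))
        embed[:, : k - 1] = verts
        # random rotation so no feature-space direction is privileged
        rot, _ = np.linalg.qr(rng.standard_normal((rank, rank)))
        return embed @ rot
    # more classes than simplex room: random directions with matched RMS distance
    verts = rng.standard_normal((k, rank))
    verts -= verts.mean(axis=0)
    d = np.sqrt(np.mean([np.sum((verts[i] - verts[j]) ** 2)
                         for i in range(k) for j in range(i + 1, k)]))
    return verts / d * separation


def generate_dataset(spec: SyntheticSpec,
                     feature_names: list[str] | None = None) -> ExpressionMatrix:
    """Draw one labeled feature table from the latent-manifold model.

    Identical ``spec`` (including seed) gives byte-identical serialized
    output. Exactly ``n_constant_columns`` columns hold a single repeated
    value; in expectation ``missing_fraction`` of the non-constant cells are
    missing; constant and label columns never contain missing cells.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_signal = spec.n_features - spec.n_constant_columns

    centroids = _class_centroids(spec.n_classes, spec.latent_rank,
                                 spec.class_separation, rng)
    class_idx = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    latent = centroids[class_idx] + rng.standard_normal((n, spec.latent_rank))

    # fixed linear map latent -> features, unit-ish output variance
    loadings = rng.standard_normal((spec.latent_rank, n_signal)) / np.sqrt(spec.latent_rank)
    signal = latent @ loadings + spec.noise_sd * rng.standard_normal((n, n_signal))

    if spec.value_regime == "zscore":
        sd = signal.std(axis=0)
        sd[sd == 0] = 1.0
        signal = (signal - signal.mean(axis=0)) / sd
    else:  # scaled_unit: min-max to [-1, 1] per column
        lo, hi = signal.min(axis=0), signal.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        signal = 2.0 * (signal - lo) / span - 1.0

    # scatter the constant columns among the signal columns
    const_positions = np.sort(rng.choice(spec.n_features, size=spec.n_constant_columns,
                                         replace=False))
    const_values = np.round(rng.standard_normal(spec.n_constant_columns), 4)

    grid = np.empty((n, spec.n_features))
    is_const = np.zeros(spec.n_features, dtype=bool)
    is_const[const_positions] = True
    grid[:, ~is_const] = signal
    grid[:, is_const] = np.broadcast_to(const_values, (n, spec.n_constant_columns))

    if spec.missing_fraction > 0:
        mask = rng.random((n, n_signal)) < spec.missing_fraction
        sig = grid[:, ~is_const]
        sig[mask] = np.nan
        grid[:, ~is_const] = sig

    if feature_names is None:
        width = max(4, len(str(spec.n_features)))
        feature_names = [f"g{i:0{width}d}" for i in range(spec.n_features)]
    elif len(feature_names) != spec.n_features:
        raise ValueError("feature_names length must equal n_features")

    sample_ids = [f"s{i:04d}" for i in range(n)]
    frame = pd.DataFrame(grid, index=sample_ids, columns=feature_names)
    labels = pd.Series(spec.labels(), index=sample_ids, name="Label")
    return ExpressionMatrix(frame, labels)


def generate_multidataset(specs: list[SyntheticSpec],
                          shared_feature_fraction: float = 1.0) -> list[ExpressionMatrix]:
    """Generate several tables whose feature-name universes overlap.

    A shared pool of ``round(shared_feature_fraction * min(n_features))``
    names appears in every table; the rest of each table's names are unique
    to it, so every pairwise overlap equals the shared pool. Exercises the
    multi-cohort feature-intersection stage.
    """
    if not specs:
        raise ValueError("specs list is empty")
    if not 0.0 < shared_feature_fraction <= 1.0:
        raise ValueError("shared_feature_fraction must be in (0, 1]")
    regimes = {s.value_regime for s in specs}
    if len(regimes) > 1:
        raise ValueError("all specs must use the same value_regime")

    n_shared = int(round(shared_feature_fraction * min(s.n_features for s in specs)))
    n_shared = max(1, n_shared)
    width = max(4, len(str(max(s.n_features for s in specs))))
    shared = [f"g{i:0{width}d}" for i in range(n_shared)]

    out = []
    for d, spec in enumerate(specs):
        unique = [f"d{d}_g{i:0{width}d}" for i in range(spec.n_features - n_shared)]
        names = shared + unique
        # interleave deterministically so shared names are not all leading
        rng = np.random.default_rng(spec.seed + 7919 * d)
        order = rng.permutation(len(names))
        out.append(generate_dataset(spec, feature_names=[names[i] for i in order]))
    return out
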
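"""Data-preparation pipeline for expression-style feature tables.

Stages, in their fixed order: removal of constant (zero-information) columns,
per-column imputation of missing values, feature-name intersection across
cohorts, seeded class downsampling, and one-vs-rest binary labeling. Each
stage is a pure function on :class:`~aeinit.matrix.ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

IMPUTATION_STRATEGIES = ("mean", "constant_zero", "most_frequent")


def remove_constant_columns(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop every column whose non-missing values hold at most one distinct
    value (an all-missing column counts as constant). Surviving column order
    is preserved.
    """
    if m.n_samples == 0 or m.n_features == 0:
        raise ValueError("matrix is empty")
    nunique = m.data.nunique(dropna=True)
    removed = nunique.index[nunique <= 1].tolist()
    if len(removed) == m.n_features:
        raise ValueError("all columns are constant: resulting matrix would be empty")
    kept = m.data.drop(columns=removed)
    return ExpressionMatrix(kept, m.labels), removed


@dataclass
class ImputationModel:
    """Per-feature fill values fitted under one strategy.

    mean: arithmetic mean of the non-missing entries per column.
    constant_zero: 0 for every column.
    most_frequent: modal non-missing value per column (smallest on ties).
    """

    strategy: str
    fill: pd.Series

    def __post_init__(self) -> None:
        if self.strategy not in IMPUTATION_STRATEGIES:
            raise ValueError(f"strategy must be one of {IMPUTATION_STRATEGIES}")
        if self.strategy == "constant_zero" and (self.fill != 0).any():
            raise ValueError("constant_zero model must fill with 0 everywhere")


def fit_imputer(m: ExpressionMatrix, strategy: str = "mean") -> ImputationModel:
    """Fit one fill value per feature; every column needs at least one
    non-missing entry (guaranteed after :func:`remove_constant_columns`)."""
    if strategy not in IMPUTATION_STRATEGIES:
        raise ValueError(f"strategy must be one of {IMPUTATION_STRATEGIES}")
    empty = m.data.columns[m.data.isna().all()]
    if len(empty):
        raise ValueError(f"column(s) with no non-missing values: {empty.tolist()[:5]}")
    if strategy == "mean":
        fill = m.data.mean()
    elif strategy == "constant_zero":
        fill = pd.Series(0.0, index=m.data.columns)
    else:  # most_frequent; pandas mode sorts, so ties resolve to the smallest
        fill = m.data.mode().iloc[0]
    return ImputationModel(strategy, fill)


def apply_imputer(m: ExpressionMatrix, model: ImputationModel) -> ExpressionMatrix:
    """Replace every missing cell by its feature's fill value; non-missing
    cells pass through unchanged."""
    missing = [c for c in m.feature_names if c not in model.fill.index]
    if missing:
        raise ValueError(f"feature(s) absent from imputation model: {missing[:5]}")
    return ExpressionMatrix(m.data.fillna(model.fill[m.feature_names]), m.labels)


def impute(m: ExpressionMatrix, strategy: str = "mean") -> ExpressionMatrix:
    """Fit-and-apply convenience (whole-matrix fit, the protocol default)."""
    return apply_imputer(m, fit_imputer(m, strategy))


def intersect_features(ms: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common feature set, in one canonical
    (lexicographic) order shared by all outputs; rows are untouched."""
    if len(ms) < 2:
        raise ValueError("need at least two matrices to intersect")
    common: set[str] = set(ms[0].feature_names)
    for m in ms[1:]:
        common &= set(m.feature_names)
    if not common:
        raise ValueError("feature intersection is empty")
    order = sorted(common)
    return [ExpressionMatrix(m.data[order], m.labels) for m in ms]


def downsample_class(m: ExpressionMatrix, class_tag, keep, seed: int) -> ExpressionMatrix:
    """Keep a uniform seeded subset of one class's rows.

    ``keep`` is an absolute count (int) or a fraction in (0, 1] (float).
    All other rows are retained; relative row order is preserved.
    """
    if m.labels is None:
        raise ValueError("matrix has no labels")
    mask = (m.labels == class_tag).to_numpy()
    size = int(mask.sum())
    if size == 0:
        raise ValueError(f"class {class_tag!r} not present")
    if isinstance(keep, float):
        if not 0.0 < keep <= 1.0:
            raise ValueError("fractional keep must be in (0, 1]")
        n_keep = int(round(keep * size))
    else:
        n_keep = int(keep)
    if n_keep > size:
        raise ValueError(f"keep={n_keep} exceeds class size {size}")
    rng = np.random.default_rng(seed)
    class_positions = np.flatnonzero(mask)
    chosen = rng.choice(class_positions, size=n_keep, replace=False)
    drop = np.setdiff1d(class_positions, chosen)
    keep_mask = np.ones(m.n_samples, dtype=bool)
    keep_mask[drop] = False
    return ExpressionMatrix(m.data.iloc[keep_mask], m.labels.iloc[keep_mask])


def label_one_vs_rest(m: ExpressionMatrix, positive_class) -> ExpressionMatrix:
    """Binarize labels: 1 for the class of interest, 0 for every other."""
    if m.labels is None:
        raise ValueError("matrix has no labels")
    if not (m.labels == positive_class).any():
        raise ValueError(f"class {positive_class!r} not present among labels")
    binary = (m.labels == positive_class).astype(int)
    return ExpressionMatrix(m.data.copy(), binary)


def preprocess(m: ExpressionMatrix, strategy: str = "mean",
               positive_class=None, downsample: dict | None = None,
               seed: int = 0) -> tuple[ExpressionMatrix, dict]:
    """Run the fixed pipeline on one table and report what it did.

    Order: constant-column removal -> imputation -> downsampling (per class)
    -> one-vs-rest labeling. Returns the processed matrix and a report with
    the removed-column count and names.
    """
    out, removed = remove_constant_columns(m)
    out = impute(out, strategy)
    if downsample:
        for tag, keep in downsample.items():
            out = downsample_class(out, tag, keep, seed)
    if positive_class is not None:
        out = label_one_vs_rest(out, positive_class)
    report = {"n_removed_columns": len(removed), "removed_columns": removed,
              "imputation": strategy, "n_samples": out.n_samples,
              "n_features": out.n_features}
    return out, report
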
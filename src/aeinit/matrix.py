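"""Samples x features expression container and its delimited-text dialect.

The on-disk dialect is a TSV with a header row of feature names, one row per
sample, the first column holding the sample identifier, missing cells written
as ``NA`` (``Null``, ``NaN`` and the empty string are also recognized on
read), and an optional trailing ``Label`` column tagging each sample's class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Tokens recognized as missing on read; ``NA`` is written on serialization.
MISSING_TOKENS = ("NA", "Null", "NaN", "nan", "null", "")

LABEL_COLUMN = "Label"


@dataclass
class ExpressionMatrix:
    """Named samples x named features numeric grid with missing-aware cells.

    Parameters
    ----------
    data
        DataFrame of float values; index = sample identifiers, columns =
        feature names. Missing cells are ``NaN``.
    labels
        Optional per-sample class tags, aligned with ``data.index``.
    """

    data: pd.DataFrame
    labels: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if LABEL_COLUMN in self.data.columns:
            raise ValueError(
                f"{LABEL_COLUMN!r} is reserved for labels and may not be a feature"
            )
        self.data = self.data.astype(float)
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.data.index)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        """Float array view (samples x features); missing cells are NaN."""
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def with_labels(self, labels: pd.Series) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), pd.Series(labels, index=self.data.index))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read the TSV dialect; a ``Label`` column, if present, becomes labels."""
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
        labels = None
        if LABEL_COLUMN in frame.columns:
            labels = frame.pop(LABEL_COLUMN)
        return cls(frame, labels)

    def to_tsv(self, path: str | Path) -> None:
        """Write the TSV dialect; missing cells serialize as ``NA``."""
        out = self.data.copy()
        if self.labels is not None:
            out[LABEL_COLUMN] = self.labels
        out.to_csv(path, sep="\t", na_rep="NA")
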
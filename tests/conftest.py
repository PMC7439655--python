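import numpy as np
import pandas as pd
import pytest

from aeinit import ExpressionMatrix, SyntheticSpec, generate_dataset


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Hand-written 4-sample table: one constant column, one all-missing
    column, scattered missing cells. Expected preprocessing outputs are
    hand-computed in the tests that use it."""
    frame = pd.DataFrame(
        {
            "gA": [1.0, np.nan, 3.0, 2.0],   # mean 2, mode 1
            "gB": [5.0, 5.0, 5.0, 5.0],      # constant -> removed
            "gC": [np.nan] * 4,              # all-missing -> removed
            "gD": [1.0, 1.0, 2.0, np.nan],   # mean 4/3, mode 1
            "gE": [0.5, -0.5, 0.5, 0.5],     # complete
        },
        index=["s0", "s1", "s2", "s3"],
    )
    labels = pd.Series(["pos", "neg", "pos", "neg"], index=frame.index)
    return ExpressionMatrix(frame, labels)


@pytest.fixture
def small_labeled() -> ExpressionMatrix:
    """Well-separated two-class table, no missing cells: quick training food."""
    spec = SyntheticSpec(n_classes=2, samples_per_class=[40, 40], n_features=30,
                         latent_rank=3, class_separation=6.0, seed=5)
    m = generate_dataset(spec)
    return m.with_labels((m.labels == "class1").astype(int))
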
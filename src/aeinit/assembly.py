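"""Assembly of the binary classifier from a pre-trained autoencoder.

Import strategies
-----------------
* ``encoder_only`` — copy the trained encoder layers (strategy 1).
* ``full_ae`` — copy encoder and decoder (strategy 2).
* ``encoder_plus_random_decoder`` — copy the encoder and append a freshly
  initialized decoder of identical shape: a control with exactly the same
  parameter count as ``full_ae``, isolating the value of the pre-trained
  decoder weights from raw topological complexity.
* ``none`` — no imported block: the bare head network (baseline).
* ``random_ae`` — a full AE of the same shape with untrained weights
  (baseline that matches depth but not pre-training).

Training approaches
-------------------
* ``fixed`` — imported layers are frozen during supervised training.
* ``fine_tune`` — every layer trains.

The classification head appended after the imported block is always:
batch normalization, two ReLU dense layers (defaults 64 and 32 units), and a
single sigmoid output unit. A sample is called positive when its predicted
probability is at least 0.5.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autoencoders import AEParams, build_ae
from .nn import BatchNorm, Dense, ReLU, Sequential, Sigmoid

STRATEGIES = ("encoder_only", "full_ae", "encoder_plus_random_decoder",
              "none", "random_ae")
APPROACHES = ("fixed", "fine_tune")

DECISION_THRESHOLD = 0.5


@dataclass
class AssemblySpec:
    """The (strategy, approach) choice governing weight import and
    trainability, plus the head widths and the head-initialization seed."""

    strategy: str = "encoder_only"
    approach: str = "fine_tune"
    head_layer_sizes: tuple[int, int] = (64, 32)
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.strategy == "none" and self.approach != "fine_tune":
            raise ValueError("strategy 'none' has no imported weights to fix; "
                             "approach must be 'fine_tune'")
        if len(self.head_layer_sizes) != 2 or any(s < 1 for s in self.head_layer_sizes):
            raise ValueError("head_layer_sizes must be two positive integers")


@dataclass
class ClassifierModel:
    """Assembled network plus provenance.

    ``network`` is the full stack (imported block, then head); ``n_imported``
    counts the leading layers that came from the AE, whose trainability
    encodes the approach.
    """

    network: Sequential
    n_imported: int
    spec: AssemblySpec
    provenance: dict = field(default_factory=dict)

    @property
    def imported_layers(self) -> list:
        return self.network.layers[: self.n_imported]

    def imported_state(self) -> dict[str, np.ndarray]:
        """Current values of the imported parameters (copy)."""
        return {f"{i}:{p.name}": p.value.copy()
                for i, p in enumerate(p for layer in self.imported_layers
                                      for p in layer.params())}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-sample positive-class probability, in (0, 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"X must be 2-D with {self.input_dim} columns")
        return self.network.predict(X).ravel()

    @property
    def input_dim(self) -> int:
        for layer in self.network.layers:
            if isinstance(layer, Dense):
                return layer.n_in
        raise RuntimeError("network has no dense layer")


def binary_call(prob: np.ndarray, threshold: float = DECISION_THRESHOLD) -> np.ndarray:
    """Decision rule: probability below the threshold is negative; at or
    above it, positive (ties at exactly 0.5 resolve to positive)."""
    return (np.asarray(prob) >= threshold).astype(int)


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample probability and binary call."""
    prob = model.predict_proba(X)
    return prob, binary_call(prob)


def _cloned_layers(seq: Sequential) -> list:
    """Deep copies so the classifier never aliases the AE's tensors."""
    return [copy.deepcopy(layer) for layer in seq.layers]


def assemble(ae: AEParams | None, spec: AssemblySpec,
             input_dim: int | None = None) -> ClassifierModel:
    """Build the classifier per the import strategy and approach.

    Imported parameter values equal the AE's bit-for-bit at assembly time.
    The head (batch norm, two ReLU dense layers, sigmoid unit) is initialized
    from ``spec.seed``. For strategy ``none`` the AE may be omitted, in which
    case ``input_dim`` is required.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.strategy == "none":
        if ae is None and input_dim is None:
            raise ValueError("strategy 'none' needs input_dim when no AE is given")
        width = ae.config.input_dim if ae is not None else int(input_dim)
        imported: list = []
    elif ae is None:
        raise ValueError(f"strategy {spec.strategy!r} requires a pre-trained AE")
    elif spec.strategy == "encoder_only":
        imported = _cloned_layers(ae.encoder)
        width = ae.config.latent_dim
    elif spec.strategy == "full_ae":
        imported = _cloned_layers(ae.encoder) + _cloned_layers(ae.decoder)
        width = ae.config.input_dim
    elif spec.strategy == "encoder_plus_random_decoder":
        fresh = build_ae(_reseeded(ae, spec.seed + 1))
        imported = _cloned_layers(ae.encoder) + _cloned_layers(fresh.decoder)
        width = ae.config.input_dim
    else:  # random_ae: same shape, untrained weights
        fresh = build_ae(_reseeded(ae, spec.seed + 1))
        imported = _cloned_layers(fresh.encoder) + _cloned_layers(fresh.decoder)
        width = ae.config.input_dim

    h1, h2 = spec.head_layer_sizes
    head = [BatchNorm(width, name="head_bn"),
            Dense(width, h1, rng, name="head0"), ReLU(),
            Dense(h1, h2, rng, name="head1"), ReLU(),
            Dense(h2, 1, rng, name="head_out"), Sigmoid()]
    network = Sequential(imported + head)

    frozen = spec.approach == "fixed"
    for layer in imported:
        layer.set_trainable(not frozen)

    provenance = {"strategy": spec.strategy, "approach": spec.approach,
                  "head_layer_sizes": list(spec.head_layer_sizes), "seed": spec.seed}
    if ae is not None:
        provenance["ae_config"] = dict(ae.config.__dict__)
    return ClassifierModel(network, len(imported), spec, provenance)


def _reseeded(ae: AEParams, seed: int):
    cfg = copy.deepcopy(ae.config)
    cfg.seed = int(seed) % (2 ** 31)
    return cfg
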
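"""Autoencoder variants and their unsupervised pre-training.

Three variants share one symmetric architecture (encoder mirrored by a
decoder; ReLU hidden units, linear reconstruction output) and are trained to
minimize mean squared reconstruction error:

* ``basic`` — plain reconstruction, J = MSE(X, g(f(X))).
* ``denoising`` — each input unit is independently zeroed with probability
  ``corruption_rate`` during training only; the loss always compares the
  reconstruction of the corrupted input against the clean input,
  J = MSE(X, g(f(X~))).
* ``sparse`` — adds an L1 penalty on the encoder parameters,
  J = MSE(X, g(f(X))) + lambda * sum|theta_e|.

The trained encoder/decoder parameter sets are what the classifier assembly
stage imports as a weight initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Dense, ReLU, Sequential, minibatches, mse_loss

AE_KINDS = ("basic", "denoising", "sparse")


@dataclass
class AEConfig:
    """Architecture and training hyperparameters of one autoencoder.

    ``encoder_layer_sizes`` lists the encoder's dense widths; its last entry
    is the latent (bottleneck) dimension. The decoder mirrors these sizes in
    reverse, ending at ``input_dim``. Defaults follow the study protocol:
    latent 128, 300 training epochs at batch size 100, Adam; corruption rate
    0.10 for the denoising variant; L1 weight 1e-5 for the sparse variant.
    """

    kind: str = "basic"
    input_dim: int = 0
    encoder_layer_sizes: list[int] = field(default_factory=lambda: [128])
    corruption_rate: float = 0.10
    sparsity_lambda: float = 1e-5
    epochs: int = 300
    batch_size: int = 100
    learning_rate: float = 3e-3
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in AE_KINDS:
            raise ValueError(f"kind must be one of {AE_KINDS}")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if not self.encoder_layer_sizes:
            raise ValueError("encoder_layer_sizes must be non-empty")
        if any(s < 1 for s in self.encoder_layer_sizes):
            raise ValueError("encoder layer sizes must be positive")
        if not 0.0 <= self.corruption_rate < 1.0:
            raise ValueError("corruption_rate must be in [0, 1)")
        if self.sparsity_lambda < 0:
            raise ValueError("sparsity_lambda must be non-negative")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size positive")

    @property
    def latent_dim(self) -> int:
        return self.encoder_layer_sizes[-1]

    @property
    def decoder_layer_sizes(self) -> list[int]:
        return list(reversed(self.encoder_layer_sizes[:-1])) + [self.input_dim]


def geometric_layer_sizes(input_dim: int, latent_dim: int, n_layers: int) -> list[int]:
    """Encoder widths geometrically interpolated from input_dim to latent_dim.

    Convention for the deeper encoders (n = 2, 3 layers): intermediate widths
    are rounded geometric means between the input and the bottleneck.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be positive")
    ratio = (latent_dim / input_dim) ** (1.0 / n_layers)
    sizes = [max(1, int(round(input_dim * ratio ** i))) for i in range(1, n_layers)]
    return sizes + [latent_dim]


@dataclass
class AEParams:
    """A (possibly trained) autoencoder: config, encoder f, decoder g, and
    the per-epoch training-loss history."""

    config: AEConfig
    encoder: Sequential
    decoder: Sequential
    history: list[float] = field(default_factory=list)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """g(f(X)) with corruption disabled and batch statistics frozen."""
        return self.decoder.predict(self.encoder.predict(X))

    def n_params(self) -> int:
        return self.encoder.n_params() + self.decoder.n_params()

    # -- persistence (config as JSON + arrays as npz) ----------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {**{f"enc/{k}": v for k, v in self.encoder.state().items()},
                 **{f"dec/{k}": v for k, v in self.decoder.state().items()}}
        np.savez(path.with_suffix(".npz"), **state)
        meta = {"config": self.config.__dict__, "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AEParams":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = AEConfig(**meta["config"])
        ae = build_ae(config)
        with np.load(path.with_suffix(".npz")) as archive:
            ae.encoder.load_state({k[4:]: archive[k] for k in archive.files
                                   if k.startswith("enc/")})
            ae.decoder.load_state({k[4:]: archive[k] for k in archive.files
                                   if k.startswith("dec/")})
        ae.history = list(meta["history"])
        return ae


def _dense_stack(sizes_in: list[int], sizes_out: list[int], rng, prefix: str,
                 final_linear: bool) -> Sequential:
    layers: list = []
    n = len(sizes_out)
    for i, (a, b) in enumerate(zip(sizes_in, sizes_out)):
        layers.append(Dense(a, b, rng, name=f"{prefix}{i}"))
        if not (final_linear and i == n - 1):
            layers.append(ReLU())
    return Sequential(layers)


def build_ae(config: AEConfig) -> AEParams:
    """Construct an untrained AE with seed-deterministic Glorot weights.

    Hidden layers use ReLU; the final reconstruction layer is linear so that
    z-scored (signed) inputs are representable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    enc_in = [config.input_dim] + config.encoder_layer_sizes[:-1]
    encoder = _dense_stack(enc_in, config.encoder_layer_sizes, rng, "enc",
                           final_linear=False)
    dec_sizes = config.decoder_layer_sizes
    dec_in = [config.latent_dim] + dec_sizes[:-1]
    decoder = _dense_stack(dec_in, dec_sizes, rng, "dec", final_linear=True)
    return AEParams(config, encoder, decoder)


def corrupt(X: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli input corruption: each cell independently zeroed with
    probability ``rate`` (no rescaling)."""
    if rate == 0:
        return X
    return X * (rng.random(X.shape) >= rate)


def _encoder_l1(ae: AEParams) -> float:
    return float(sum(np.abs(p.value).sum() for p in ae.encoder.params()))


def _training_step(ae: AEParams, x_in: np.ndarray, x_target: np.ndarray,
                   optimizer: Adam) -> float:
    """One gradient step of the reconstruction objective.

    ``x_in`` may be a corrupted copy of ``x_target``; the loss is always
    measured against the clean target. Returns the batch objective value
    (MSE plus the L1 term for the sparse variant).
    """
    recon = ae.decoder.forward(ae.encoder.forward(x_in, training=True), training=True)
    loss, grad = mse_loss(recon, x_target)
    ae.encoder.backward(ae.decoder.backward(grad))
    lam = ae.config.sparsity_lambda if ae.config.kind == "sparse" else 0.0
    if lam:
        loss += lam * _encoder_l1(ae)
        for p in ae.encoder.params():
            p.grad += lam * np.sign(p.value)
    optimizer.step()
    return loss


def pretrain(ae: AEParams, X: np.ndarray) -> AEParams:
    """Train the AE in place to minimize reconstruction error on X.

    X must be fully imputed (no missing cells) with ``input_dim`` columns.
    Runs ``config.epochs`` epochs of minibatch Adam; appends the per-epoch
    mean training objective to ``ae.history`` and returns ``ae``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ae.config.input_dim:
        raise ValueError(f"X must be 2-D with {ae.config.input_dim} columns")
    if np.isnan(X).any():
        raise ValueError("X contains missing cells; impute before pre-training")
    cfg = ae.config
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = Adam(ae.encoder.params() + ae.decoder.params(), lr=cfg.learning_rate)
    for _ in range(cfg.epochs):
        losses, counts = [], []
        for idx in minibatches(X.shape[0], cfg.batch_size, rng):
            xb = X[idx]
            x_in = corrupt(xb, cfg.corruption_rate, rng) if cfg.kind == "denoising" else xb
            losses.append(_training_step(ae, x_in, xb, optimizer))
            counts.append(len(idx))
        ae.history.append(float(np.average(losses, weights=counts)))
    return ae


def reconstruction_loss(ae: AEParams, X: np.ndarray) -> float:
    """Mean squared error between X and its reconstruction g(f(X)), with
    corruption disabled (evaluation semantics)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ae.config.input_dim:
        raise ValueError(f"X must be 2-D with {ae.config.input_dim} columns")
    loss, _ = mse_loss(ae.reconstruct(X), X)
    return loss
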
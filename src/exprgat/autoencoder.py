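"""Unsupervised embedding: attention encoder + fully connected decoder.

The attention layer acts as the encoder of an autoencoder; a four-layer
fully connected decoder maps the n x (p*h) embedding back to the input
feature space through widths p*h/2, m/4, m/2, m (ReLU on the first
three layers, linear output).  The whole model is trained on all
samples by mean-squared reconstruction error — no labels, no splits —
and the trained encoder's embedding is what downstream clustering
consumes.

The printed loss is the MSE averaged over all n*m matrix entries
rather than a bare sum of squares: the minimizer is identical and the
scale is invariant to data size, which keeps one learning rate usable
across problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix
from .gat import GATEncoder
from .graph import AdjacencyMatrix
from .optim import Adam

__all__ = [
    "DecoderParams",
    "AEConfig",
    "decoder_widths",
    "init_decoder",
    "decoder_forward",
    "reconstruction_loss",
    "train_autoencoder",
    "TrainedAutoencoder",
]


def decoder_widths(ph: int, m: int) -> list[int]:
    """Output widths of the four decoder layers: ph/2, m/4, m/2, m.

    Floor division for odd/indivisible sizes, floored at width 1.
    """
    return [max(1, ph // 2), max(1, m // 4), max(1, m // 2), m]


@dataclass
class DecoderParams:
    """Four (weight, bias) layers; ReLU after the first three."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.layers) != 4:
            raise ValueError("decoder has exactly four layers")
        for W, b in self.layers:
            if W.shape[0] != b.shape[0]:
                raise ValueError("layer weight/bias width mismatch")

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in self.layers:
            out.extend([W, b])
        return out


@dataclass
class AEConfig:
    lr: float = 0.001
    weight_decay: float = 0.0
    epochs: int = 500
    seed: int = 0


def init_decoder(ph: int, m: int, seed: int) -> DecoderParams:
    """Xavier-normal initialization of the four decoder layers."""
    rng = np.random.default_rng(seed)
    widths = decoder_widths(ph, m)
    layers = []
    fan_in = ph
    for w in widths:
        W = rng.normal(0.0, np.sqrt(2.0 / (fan_in + w)), size=(w, fan_in))
        b = np.zeros(w)
        layers.append((W, b))
        fan_in = w
    return DecoderParams(layers=layers)


def decoder_forward(Z, params: DecoderParams, need_cache: bool = False):
    """Reconstruction Y = L4(relu(L3(relu(L2(relu(L1(Z)))))))."""
    Zv = Z.values if hasattr(Z, "values") else np.asarray(Z, dtype=float)
    if Zv.shape[1] != params.layers[0][0].shape[1]:
        raise ValueError("embedding width does not match decoder input")
    acts = [Zv]
    pre = []
    h = Zv
    for li, (W, b) in enumerate(params.layers):
        z = h @ W.T + b
        pre.append(z)
        h = np.maximum(z, 0.0) if li < 3 else z  # final layer linear
        acts.append(h)
    return (h, (acts, pre)) if need_cache else h


def _decoder_backward(dY: np.ndarray, params: DecoderParams, cache) -> tuple[list[np.ndarray], np.ndarray]:
    acts, pre = cache
    grads: list[np.ndarray] = []
    d = dY
    for li in range(3, -1, -1):
        W, _ = params.layers[li]
        if li < 3:
            d = d * (pre[li] > 0)
        dW = d.T @ acts[li]
        db = d.sum(axis=0)
        grads[:0] = [dW, db]
        d = d @ W
    return grads, d  # d is now dL/dZ


def reconstruction_loss(X_target, Y) -> float:
    """Mean squared error between input features and reconstruction."""
    Xv = X_target.values if hasattr(X_target, "values") else np.asarray(X_target, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    if Xv.shape != Yv.shape:
        raise ValueError(f"shape mismatch: {Xv.shape} vs {Yv.shape}")
    return float(np.mean((Xv - Yv) ** 2))


class TrainedAutoencoder:
    def __init__(self, encoder: GATEncoder, decoder: DecoderParams, history: dict):
        self.encoder = encoder
        self.decoder = decoder
        self.history = history

    def embed(self, X, A):
        return self.encoder.embed(X, A)

    def reconstruct(self, X, A) -> np.ndarray:
        Xv = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
        Av = A.values if hasattr(A, "values") else np.asarray(A, dtype=float)
        return decoder_forward(self.encoder.forward(Xv, Av), self.decoder)


def train_autoencoder(
    X: FeatureMatrix,
    A: AdjacencyMatrix,
    gat=None,
    config: AEConfig | None = None,
) -> TrainedAutoencoder:
    """Minimize reconstruction MSE over all samples; fully unsupervised.

    Deterministic given ``config.seed``; aborts on non-finite loss.
    """
    from .classifier import GATConfig  # avoid import cycle at module load

    gat = gat or GATConfig()
    config = config or AEConfig()
    Xv, Av = X.values, A.values
    n, m = Xv.shape

    encoder = GATEncoder.initialize(
        m, gat.embed_size, gat.heads, seed=config.seed,
        slope=gat.slope, activation=gat.activation,
    )
    decoder = init_decoder(encoder.out_dim, m, seed=config.seed + 1)
    params = encoder.parameters() + decoder.parameters()
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    history = {"loss": []}
    for epoch in range(config.epochs):
        Z, enc_cache = encoder.forward(Xv, Av, need_cache=True)
        Y, dec_cache = decoder_forward(Z, decoder, need_cache=True)
        loss = float(np.mean((Xv - Y) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"autoencoder diverged at epoch {epoch}")
        history["loss"].append(loss)

        dY = 2.0 * (Y - Xv) / (n * m)
        dec_grads, dZ = _decoder_backward(dY, decoder, dec_cache)
        enc_grads = encoder.backward(dZ, Xv, Av, enc_cache)
        opt.step(enc_grads + dec_grads)

    return TrainedAutoencoder(encoder, decoder, history)
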
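"""Multi-head masked graph-attention embedding layer.

The layer embeds each sample as an attention-weighted combination of
its graph neighbors' projected feature vectors.  For a single head with
projection W (p x m) and attention vector a (2p), the unnormalized
attention a sample i receives from neighbor j is

    c_ij = a^T [W x_i || W x_j]

which decomposes as c_ij = s_i + t_j with s = (X W^T) a[:p] and
t = (X W^T) a[p:], so the full score matrix is rank-one-structured and
never requires materializing concatenated pairs.  Scores pass through
LeakyReLU, are masked to the adjacency support (non-neighbors set to
-inf so the softmax renormalizes exactly over N_i), and softmaxed per
row into coefficients alpha.  The head output is sigma(alpha @ X W^T);
head outputs are concatenated across the h heads.

Training is by explicit reverse-mode differentiation of this forward
pass (see ``GATEncoder.backward``); a finite-difference check in the
test suite validates the gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import AdjacencyMatrix

__all__ = [
    "HeadParams",
    "EmbeddingMatrix",
    "init_heads",
    "raw_attention_scores",
    "masked_attention",
    "head_embedding",
    "multi_head_embed",
    "GATEncoder",
    "ACTIVATIONS",
    "save_encoder",
    "load_encoder",
]


# ---------------------------------------------------------------------------
# activations


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


def _identity(x):
    return x


def _one(x):
    return np.ones_like(x)


#: name -> (function, derivative wrt pre-activation)
ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "relu": (_relu, _relu_grad),
    "identity": (_identity, _one),
}


def resolve_activation(activation):
    """Accept an activation name or a callable; return (f, df or None)."""
    if callable(activation):
        return activation, None
    try:
        return ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None


def leaky_relu(x, slope: float):
    return np.where(x > 0, x, slope * x)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class HeadParams:
    """Learnable parameters of one attention head."""

    W: np.ndarray  # p x m projection
    a: np.ndarray  # 2p attention vector: first p weights the target, last p the neighbor

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float).reshape(-1)
        p, _ = self.W.shape
        if self.a.shape[0] != 2 * p:
            raise ValueError(f"attention vector length {self.a.shape[0]} != 2p = {2 * p}")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.a))):
            raise ValueError("non-finite head parameters")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "HeadParams":
        return HeadParams(W=self.W.copy(), a=self.a.copy())


@dataclass
class EmbeddingMatrix:
    """n x (p*h) concatenated multi-head embedding."""

    values: np.ndarray
    head_count: int
    per_head_size: int
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.head_count * self.per_head_size:
            raise ValueError("embedding width != head_count * per_head_size")

    def head_block(self, k: int) -> np.ndarray:
        p = self.per_head_size
        return self.values[:, k * p : (k + 1) * p]


def init_heads(m: int, p: int, h: int, seed: int) -> list[HeadParams]:
    """Initialize h independent heads with Xavier-normal draws.

    W entries ~ N(0, 2/(m+p)); a entries ~ N(0, 2/(2p+1)), the Xavier
    variance for a 2p -> 1 map.  Deterministic given the seed.
    """
    if m < 1 or p < 1 or h < 1:
        raise ValueError("dimensions m, p, h must all be >= 1")
    rng = np.random.default_rng(seed)
    heads = []
    for _ in range(h):
        W = rng.normal(0.0, np.sqrt(2.0 / (m + p)), size=(p, m))
        a = rng.normal(0.0, np.sqrt(2.0 / (2 * p + 1)), size=2 * p)
        heads.append(HeadParams(W=W, a=a))
    return heads


# ---------------------------------------------------------------------------
# forward operations


def raw_attention_scores(X, params: HeadParams) -> np.ndarray:
    """Unnormalized pairwise scores c_ij = a^T [W x_i || W x_j]."""
    V = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    if V.shape[1] != params.m:
        raise ValueError(f"feature width {V.shape[1]} != W width {params.m}")
    H = V @ params.W.T  # n x p
    p = params.p
    s = H @ params.a[:p]   # target-side contribution
    t = H @ params.a[p:]   # neighbor-side contribution
    return s[:, None] + t[None, :]


def masked_attention(c: np.ndarray, A: AdjacencyMatrix | np.ndarray, slope: float = 0.2) -> np.ndarray:
    """Row-softmax of LeakyReLU(scores) restricted to the graph support.

    Non-neighbor entries are sent to -inf before the softmax so that
    each row is an exact probability distribution over N_i; they come
    out exactly zero.
    """
    Av = A.values if hasattr(A, "values") else np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=float)
    if c.shape != Av.shape:
        raise ValueError("score and adjacency shapes differ")
    if np.any(Av.sum(axis=1) == 0):
        raise ValueError("adjacency row with no neighbors: softmax undefined")
    E = leaky_relu(c, slope)
    E = np.where(Av > 0, E, -np.inf)
    E = E - E.max(axis=1, keepdims=True)  # stable: every row has a finite max
    expE = np.exp(E)
    return expE / expE.sum(axis=1, keepdims=True)


def head_embedding(X, params: HeadParams, alpha: np.ndarray, activation="elu") -> np.ndarray:
    """One head's output: sigma(alpha @ (X W^T))."""
    V = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    if V.shape[1] != params.m:
        raise ValueError("feature width mismatch")
    f, _ = resolve_activation(activation)
    H = V @ params.W.T
    return f(alpha @ H)


def multi_head_embed(
    X,
    A: AdjacencyMatrix | np.ndarray,
    heads: list[HeadParams],
    slope: float = 0.2,
    activation="elu",
) -> EmbeddingMatrix:
    """Concatenate all heads' outputs into the n x (p*h) embedding."""
    if not heads:
        raise ValueError("empty head list")
    sample_ids = getattr(X, "sample_ids", None)
    blocks = []
    for params in heads:
        c = raw_attention_scores(X, params)
        alpha = masked_attention(c, A, slope)
        blocks.append(head_embedding(X, params, alpha, activation))
    Z = np.concatenate(blocks, axis=1)
    return EmbeddingMatrix(
        values=Z,
        head_count=len(heads),
        per_head_size=heads[0].p,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


# ---------------------------------------------------------------------------
# trainable encoder with explicit backward


class GATEncoder:
    """The multi-head attention layer as a trainable module.

    Holds the head parameters and implements the forward pass with
    cached intermediates plus the exact reverse-mode gradient of the
    embedding with respect to every W and a.
    """

    def __init__(self, heads: list[HeadParams], slope: float = 0.2, activation: str = "elu"):
        if not heads:
            raise ValueError("empty head list")
        if callable(activation):
            raise TypeError("trainable encoder needs a named activation with a known derivative")
        self.heads = heads
        self.slope = slope
        self.activation = activation

    @classmethod
    def initialize(cls, m: int, p: int, h: int, seed: int, slope: float = 0.2, activation: str = "elu"):
        return cls(init_heads(m, p, h, seed), slope=slope, activation=activation)

    @property
    def h(self) -> int:
        return len(self.heads)

    @property
    def p(self) -> int:
        return self.heads[0].p

    @property
    def out_dim(self) -> int:
        return self.h * self.p

    def parameters(self) -> list[np.ndarray]:
        out = []
        for hp in self.heads:
            out.extend([hp.W, hp.a])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        for k, hp in enumerate(self.heads):
            hp.W = params[2 * k].copy()
            hp.a = params[2 * k + 1].copy()

    def forward(self, Xv: np.ndarray, Av: np.ndarray, need_cache: bool = False):
        """Return the n x (p*h) embedding; optionally cache intermediates."""
        f, _ = ACTIVATIONS[self.activation]
        blocks, caches = [], []
        for hp in self.heads:
            H = Xv @ hp.W.T
            p = hp.p
            s = H @ hp.a[:p]
            t = H @ hp.a[p:]
            C = s[:, None] + t[None, :]
            E = leaky_relu(C, self.slope)
            E = np.where(Av > 0, E, -np.inf)
            Es = E - E.max(axis=1, keepdims=True)
            expE = np.exp(Es)
            alpha = expE / expE.sum(axis=1, keepdims=True)
            Mpre = alpha @ H
            blocks.append(f(Mpre))
            if need_cache:
                caches.append((H, C, alpha, Mpre))
        Z = np.concatenate(blocks, axis=1)
        return (Z, caches) if need_cache else Z

    def attention(self, Xv: np.ndarray, Av: np.ndarray) -> list[np.ndarray]:
        """Per-head attention coefficient matrices on given inputs."""
        out = []
        for hp in self.heads:
            c = raw_attention_scores(Xv, hp)
            out.append(masked_attention(c, Av, self.slope))
        return out

    def embed(self, X, A) -> EmbeddingMatrix:
        """Container-level forward (accepts FeatureMatrix/AdjacencyMatrix)."""
        return multi_head_embed(X, A, self.heads, self.slope, self.activation)

    def backward(self, dZ: np.ndarray, Xv: np.ndarray, Av: np.ndarray, caches) -> list[np.ndarray]:
        """Gradients [dW_0, da_0, dW_1, da_1, ...] for a given dL/dZ."""
        _, df = ACTIVATIONS[self.activation]
        grads = []
        for k, hp in enumerate(self.heads):
            H, C, alpha, Mpre = caches[k]
            p = hp.p
            dO = dZ[:, k * p : (k + 1) * p]
            dM = dO * df(Mpre)
            dalpha = dM @ H.T
            dH = alpha.T @ dM
            # softmax backward per row; zero off-support because alpha is 0 there
            rowdot = np.sum(alpha * dalpha, axis=1, keepdims=True)
            dE = alpha * (dalpha - rowdot)
            dC = dE * np.where(C > 0, 1.0, self.slope)
            ds = dC.sum(axis=1)
            dt = dC.sum(axis=0)
            dH = dH + ds[:, None] * hp.a[None, :p] + dt[:, None] * hp.a[None, p:]
            da = np.concatenate([H.T @ ds, H.T @ dt])
            dW = dH.T @ Xv
            grads.extend([dW, da])
        return grads


def save_encoder(path, encoder: GATEncoder) -> None:
    """Serialize encoder parameters and config to an .npz blob."""
    arrays = {}
    for k, hp in enumerate(encoder.heads):
        arrays[f"W{k}"] = hp.W
        arrays[f"a{k}"] = hp.a
    arrays["meta_h"] = np.array([len(encoder.heads)])
    arrays["meta_slope"] = np.array([encoder.slope])
    arrays["meta_activation"] = np.array([encoder.activation])
    np.savez(path, **arrays)


def load_encoder(path) -> GATEncoder:
    with np.load(path, allow_pickle=False) as blob:
        h = int(blob["meta_h"][0])
        slope = float(blob["meta_slope"][0])
        activation = str(blob["meta_activation"][0])
        heads = [HeadParams(W=blob[f"W{k}"], a=blob[f"a{k}"]) for k in range(h)]
    return GATEncoder(heads, slope=slope, activation=activation)
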
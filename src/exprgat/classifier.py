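"""Supervised classification on graph-attention embeddings.

The classifier is the attention encoder followed by one fully connected
layer and a softmax; the whole stack is trained end to end by
minimizing the negative log-likelihood of the training-subset labels.
Training is transductive: every sample (and the full graph) takes part
in the forward pass, but only training labels enter the loss.  Splits
follow an 80/20 pre-train/test division with the pre-train set further
split 80/20 into train/validation; the checkpoint with the best
validation loss is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix, LabelVector
from .gat import GATEncoder, EmbeddingMatrix
from .graph import AdjacencyMatrix
from .metrics import auroc as evaluate_auroc  # noqa: F401  (re-exported per module surface)
from .optim import Adam

__all__ = [
    "SplitSpec",
    "ClassifierHead",
    "GATConfig",
    "TrainConfig",
    "split_samples",
    "classify_forward",
    "nll_loss",
    "train_classifier",
    "TrainedClassifier",
    "evaluate_auroc",
    "repeated_classification",
]


@dataclass
class SplitSpec:
    """Protocol for the train/validation/test division."""

    test_fraction: float = 0.2
    val_fraction_of_pretrain: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.val_fraction_of_pretrain):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class ClassifierHead:
    """Fully connected output layer mapping embeddings to class logits."""

    W_cls: np.ndarray  # c x (p*h)
    b_cls: np.ndarray  # c

    def __post_init__(self) -> None:
        self.W_cls = np.asarray(self.W_cls, dtype=float)
        self.b_cls = np.asarray(self.b_cls, dtype=float).reshape(-1)
        if self.W_cls.shape[0] != self.b_cls.shape[0]:
            raise ValueError("W_cls rows must match b_cls length")
        if self.W_cls.shape[0] < 2:
            raise ValueError("need at least 2 classes")

    def copy(self) -> "ClassifierHead":
        return ClassifierHead(self.W_cls.copy(), self.b_cls.copy())


@dataclass
class GATConfig:
    """Encoder hyperparameters: h heads of size p over the masked graph."""

    embed_size: int = 8
    heads: int = 8
    slope: float = 0.2
    activation: str = "elu"


@dataclass
class TrainConfig:
    lr: float = 0.005
    weight_decay: float = 5e-4
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0


def _allocate_counts(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of `total` picks across strata."""
    n = sizes.sum()
    quotas = sizes * total / n
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for j in order[:remainder]:
        counts[j] += 1
    return np.minimum(counts, sizes)


def split_samples(n: int, labels: LabelVector | None, spec: SplitSpec):
    """Partition {0..n-1} into (train, val, test) index arrays.

    Sizes are |test| = round(test_fraction * n) and
    |val| = round(val_fraction * |pretrain|); when stratified, each
    class contributes proportionally (largest-remainder rounding).
    Deterministic given ``spec.seed``.
    """
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(spec.seed)
    n_test = int(round(spec.test_fraction * n))
    n_test = min(max(n_test, 1), n - 2)

    if spec.stratified and labels is not None:
        y = labels.indices()
        strata = [np.flatnonzero(y == c) for c in range(labels.n_classes)]
    else:
        strata = [np.arange(n)]
    for s in strata:
        rng.shuffle(s)

    sizes = np.array([len(s) for s in strata])
    test_counts = _allocate_counts(sizes, n_test)
    test_idx = np.concatenate([s[:c] for s, c in zip(strata, test_counts)])
    pre_strata = [s[c:] for s, c in zip(strata, test_counts)]

    n_pre = n - len(test_idx)
    n_val = int(round(spec.val_fraction_of_pretrain * n_pre))
    n_val = min(max(n_val, 1), n_pre - 1)
    pre_sizes = np.array([len(s) for s in pre_strata])
    val_counts = _allocate_counts(pre_sizes[pre_sizes > 0], n_val)
    # re-expand counts for empty strata
    full_val_counts = np.zeros(len(pre_strata), dtype=int)
    full_val_counts[pre_sizes > 0] = val_counts
    val_idx = np.concatenate([s[:c] for s, c in zip(pre_strata, full_val_counts)])
    train_idx = np.concatenate([s[c:] for s, c in zip(pre_strata, full_val_counts)])

    train_idx = np.sort(train_idx)
    val_idx = np.sort(val_idx)
    test_idx = np.sort(test_idx)
    assert len(train_idx) + len(val_idx) + len(test_idx) == n
    return train_idx, val_idx, test_idx


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def classify_forward(Z, head: ClassifierHead) -> np.ndarray:
    """Class probabilities Softmax(W_cls z_i + b_cls), one row per sample."""
    Zv = Z.values if isinstance(Z, EmbeddingMatrix) else np.asarray(Z, dtype=float)
    if Zv.shape[1] != head.W_cls.shape[1]:
        raise ValueError("embedding width does not match classifier head")
    logits = Zv @ head.W_cls.T + head.b_cls
    return np.exp(_log_softmax(logits))


def nll_loss(probs: np.ndarray, labels: LabelVector, subset_idx=None) -> float:
    """Negative log-likelihood  -sum_i log p_i[y_i]  over the subset.

    Computed through log-probabilities (floored at 1e-300) so it stays
    finite for any probability >= ~1e-30.
    """
    probs = np.asarray(probs, dtype=float)
    y = labels.indices()
    if probs.shape[0] != len(y):
        raise ValueError("probs and labels lengths differ")
    if y.max() >= probs.shape[1]:
        raise ValueError("label index outside probability columns")
    idx = np.arange(len(y)) if subset_idx is None else np.asarray(subset_idx)
    if len(idx) == 0:
        raise ValueError("empty subset")
    picked = probs[idx, y[idx]]
    return float(-np.log(np.maximum(picked, 1e-300)).sum())


class TrainedClassifier:
    """Encoder + classifier head with training history."""

    def __init__(self, encoder: GATEncoder, head: ClassifierHead, classes: list, history: dict):
        self.encoder = encoder
        self.head = head
        self.classes = classes
        self.history = history

    def predict_proba(self, X, A) -> np.ndarray:
        Xv = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
        Av = A.values if hasattr(A, "values") else np.asarray(A, dtype=float)
        Z = self.encoder.forward(Xv, Av)
        return classify_forward(Z, self.head)

    def decision_scores(self, X, A) -> np.ndarray:
        """Positive-class probability for binary tasks (classes[1])."""
        return self.predict_proba(X, A)[:, 1]


def train_classifier(
    X: FeatureMatrix,
    A: AdjacencyMatrix,
    labels: LabelVector,
    split: tuple | SplitSpec | None = None,
    gat: GATConfig | None = None,
    train: TrainConfig | None = None,
) -> TrainedClassifier:
    """Train the attention encoder + FC head end to end.

    ``split`` may be a precomputed (train, val, test) triple or a
    SplitSpec (default: SplitSpec seeded from the training seed).
    Returns the best-validation-loss checkpoint with per-epoch loss
    history.  Raises on divergence (non-finite loss).
    """
    gat = gat or GATConfig()
    train = train or TrainConfig()
    if split is None:
        split = SplitSpec(seed=train.seed)
    if isinstance(split, SplitSpec):
        train_idx, val_idx, test_idx = split_samples(X.n_samples, labels, split)
    else:
        train_idx, val_idx, test_idx = split

    Xv, Av = X.values, A.values
    c = labels.n_classes
    y = labels.indices()
    onehot = np.eye(c)[y]

    encoder = GATEncoder.initialize(
        X.n_features, gat.embed_size, gat.heads, seed=train.seed,
        slope=gat.slope, activation=gat.activation,
    )
    rng = np.random.default_rng(train.seed + 1)
    d = encoder.out_dim
    head = ClassifierHead(
        W_cls=rng.normal(0.0, np.sqrt(2.0 / (d + c)), size=(c, d)),
        b_cls=np.zeros(c),
    )

    params = encoder.parameters() + [head.W_cls, head.b_cls]
    opt = Adam(params, lr=train.lr, weight_decay=train.weight_decay)

    best_val = np.inf
    best_state = [p.copy() for p in params]
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    since_best = 0

    for epoch in range(train.max_epochs):
        Z, caches = encoder.forward(Xv, Av, need_cache=True)
        logits = Z @ head.W_cls.T + head.b_cls
        logp = _log_softmax(logits)
        P = np.exp(logp)

        tr_loss = float(-logp[train_idx, y[train_idx]].mean())
        val_loss = float(-logp[val_idx, y[val_idx]].mean())
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(
                f"classifier training diverged at epoch {epoch}: "
                f"train={tr_loss}, val={val_loss}"
            )
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.copy() for p in params]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > train.patience:
                break

        # backward: mean NLL over training rows
        G = np.zeros_like(P)
        G[train_idx] = (P[train_idx] - onehot[train_idx]) / len(train_idx)
        dW_cls = G.T @ Z
        db_cls = G.sum(axis=0)
        dZ = G @ head.W_cls
        grads = encoder.backward(dZ, Xv, Av, caches) + [dW_cls, db_cls]
        opt.step(grads)

    # restore best checkpoint
    for p, b in zip(params, best_state):
        p[...] = b
    history["best_epoch"] = best_epoch
    history["split"] = (train_idx, val_idx, test_idx)
    return TrainedClassifier(encoder, head, list(labels.classes), history)


def repeated_classification(
    X: FeatureMatrix,
    A: AdjacencyMatrix,
    labels: LabelVector,
    n_repeats: int = 10,
    base_seed: int = 0,
    gat: GATConfig | None = None,
    train: TrainConfig | None = None,
) -> list[float]:
    """Re-split, re-initialize and re-train ``n_repeats`` times.

    Every repeat reshuffles all three splits and the parameter
    initialization from its own derived seed; returns the test AUROC of
    each repeat (binary tasks: positive class = classes[1]).
    """
    aurocs = []
    for r in range(n_repeats):
        seed_r = int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0] % (2**31))
        cfg = TrainConfig(**{**(train or TrainConfig()).__dict__, "seed": seed_r})
        model = train_classifier(X, A, labels, split=SplitSpec(seed=seed_r), gat=gat, train=cfg)
        _, _, test_idx = model.history["split"]
        scores = model.decision_scores(X, A)
        y = labels.indices()
        aurocs.append(evaluate_auroc(scores[test_idx], (y[test_idx] == 1).astype(int)))
    return aurocs
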
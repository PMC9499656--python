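"""Self-contained evaluation metrics: AUROC, NMI, ARI.

Each formula is implemented directly from its definition so it can be
checked against exhaustive enumeration (pair counting for AUROC,
contingency-table formulas for NMI/ARI).  scikit-learn's versions serve
as independent cross-checks in the test suite, never as the
implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb
from scipy.stats import rankdata

__all__ = ["auroc", "contingency", "nmi", "ari", "evaluate_clustering"]


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Equals the probability that a uniformly chosen positive outranks a
    uniformly chosen negative, counting ties as one half:
    U / (n_pos * n_neg) with U the Mann-Whitney statistic of the
    positive class's mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)  # mid-ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def contingency(labels_a, labels_b) -> np.ndarray:
    """r x s table of co-occurrence counts between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D arrays")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(labels_a, labels_b, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    MI is computed from the contingency table and normalized by the
    chosen mean of the two marginal entropies (arithmetic by default;
    geometric / min / max also supported).
    """
    table = contingency(labels_a, labels_b).astype(float)
    n = table.sum()
    pij = table / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)
    outer = pa[:, None] * pb[None, :]
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    ha = _entropy(table.sum(axis=1))
    hb = _entropy(table.sum(axis=0))
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both partitions trivial -> identical
    norms = {
        "arithmetic": (ha + hb) / 2.0,
        "geometric": np.sqrt(ha * hb),
        "min": min(ha, hb),
        "max": max(ha, hb),
    }
    try:
        denom = norms[normalization]
    except KeyError:
        raise ValueError(f"unknown normalization {normalization!r}") from None
    if denom == 0.0:
        return 0.0
    return float(max(0.0, mi) / denom)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index: pair-counting agreement corrected for chance."""
    table = contingency(labels_a, labels_b)
    n = table.sum()
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # degenerate: all-singletons or one cluster on both sides
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate_clustering(assignment, truth) -> tuple[float, float]:
    """(NMI, ARI) of a cluster assignment against ground-truth labels."""
    pred = getattr(assignment, "labels", assignment)
    true = getattr(truth, "labels", truth)
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("assignment and truth lengths differ")
    return nmi(pred, true), ari(pred, true)
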
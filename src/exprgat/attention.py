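"""Sample x sample attention-matrix extraction and clustering.

After training, each head assigns its own coefficients to a sample's
neighbors.  To summarize what the model learned about neighbor
importance, the attention matrix keeps, for every (target, neighbor)
pair on the graph support, the highest coefficient across the h heads.
The matrix is generally asymmetric, its rows need not sum to one, and
it is zero exactly where the adjacency is zero.  Treating each row as
the sample's feature vector, hierarchical clustering of the attention
matrix can be compared against clustering the binary adjacency itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment, hierarchical_cluster
from .gat import GATEncoder, HeadParams, masked_attention, raw_attention_scores
from .graph import AdjacencyMatrix

__all__ = ["AttentionMatrix", "extract_attention_matrix", "cluster_attention_matrix"]


@dataclass
class AttentionMatrix:
    values: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("attention matrix must be square")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValueError("attention coefficients must lie in [0, 1]")


def extract_attention_matrix(
    heads: list[HeadParams] | GATEncoder,
    X,
    A: AdjacencyMatrix,
    slope: float = 0.2,
) -> AttentionMatrix:
    """Elementwise maximum of the per-head attention coefficients.

    Coefficients are recomputed on the given features and graph with
    the trained parameters; entry (i, j) is max_k alpha^k_ij.
    """
    if isinstance(heads, GATEncoder):
        slope = heads.slope
        heads = heads.heads
    if not heads:
        raise ValueError("empty head list")
    M = None
    for params in heads:
        c = raw_attention_scores(X, params)
        alpha = masked_attention(c, A, slope)
        M = alpha if M is None else np.maximum(M, alpha)
    sample_ids = getattr(X, "sample_ids", None)
    return AttentionMatrix(values=M, sample_ids=list(sample_ids) if sample_ids else None)


def cluster_attention_matrix(
    M: AttentionMatrix | np.ndarray,
    k: int,
    metric: str = "cosine",
    linkage: str = "average",
) -> ClusterAssignment:
    """Hierarchical clustering with each sample's attention row as features.

    Cosine distance is the default here (unlike the embedding presets):
    taking the max over heads gives rows unequal total mass, and the
    group signal lives in *which* neighbors a sample attends to, not in
    that scale.  Cosine compares support patterns scale-invariantly;
    magnitude-sensitive metrics remain available.
    """
    V = M.values if hasattr(M, "values") else np.asarray(M, dtype=float)
    return hierarchical_cluster(V, k, metric=metric, linkage=linkage)
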
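"""Hierarchical clustering of embeddings and its evaluation.

Agglomerative clustering (scikit-learn) groups samples by the
similarity of their learned embeddings.  Metric/linkage presets mirror
the two study settings: bulk patient stratification uses Manhattan
distance with average linkage, single-cell clustering uses cosine
distance with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .metrics import evaluate_clustering  # noqa: F401  (module surface)

__all__ = [
    "ClusterAssignment",
    "hierarchical_cluster",
    "evaluate_clustering",
    "PRESETS",
]

#: named (metric, linkage) presets for the two data regimes
PRESETS = {
    "blca": ("manhattan", "average"),
    "scrna": ("cosine", "average"),
}

_METRICS = ("manhattan", "cosine", "euclidean")
_LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    metric: str
    linkage: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("cluster indices outside [0, k)")


def hierarchical_cluster(
    Z,
    k: int,
    metric: str = "manhattan",
    linkage: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of embedding rows into k groups.

    Ward linkage is only defined for euclidean distance; any other
    combination of the supported metrics/linkages is allowed.
    Deterministic (no randomness in agglomeration).
    """
    V = Z.values if hasattr(Z, "values") else np.asarray(Z, dtype=float)
    n = V.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, n={n}]")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    model = AgglomerativeClustering(n_clusters=k, metric=metric, linkage=linkage)
    labels = model.fit_predict(V)
    return ClusterAssignment(labels=labels, k=k, metric=metric, linkage=linkage)
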
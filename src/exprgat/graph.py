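"""Correlation-based sample-similarity graph construction.

Each sample's neighborhood is the set of other samples whose expression
profiles correlate most strongly with it.  The Pearson correlation
matrix is binarized per row: the top-k correlations are kept (k set by a
target network density) and a self-connection is always added, so every
sample aggregates information from itself as well as its neighbors.
The per-row top-k makes the graph directed in general; row i's nonzeros
are exactly the neighborhood N_i that the attention softmax normalizes
over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "pairwise_correlation",
    "build_adjacency",
    "save_matrix",
    "load_adjacency",
]


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    sample_ids: list[str]
    density: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("adjacency diagonal must be all ones (self-connections)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def pairwise_correlation(X: FeatureMatrix) -> CorrelationMatrix:
    """Pearson correlation between all pairs of sample rows.

    Pearson is the standard similarity for expression profiles; it is
    invariant to positive affine rescaling of a sample's features.
    """
    V = X.values
    if V.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = V.std(axis=1)
    if np.any(sd == 0):
        bad = [X.sample_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample rows: {bad}")
    C = np.corrcoef(V)
    # numerical guard: exact symmetry and unit diagonal
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(values=C, sample_ids=list(X.sample_ids))


def neighbors_per_row(n: int, density: float) -> int:
    """Number of non-self neighbors retained per sample for a density."""
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    return max(1, int(round(density * (n - 1))))


def build_adjacency(C: CorrelationMatrix, density: float) -> AdjacencyMatrix:
    """Binarize a correlation matrix into a top-k neighbor graph.

    For every sample the k = max(1, round(density * (n-1))) most
    correlated other samples are kept; ties at the k-th rank go to the
    lower sample index for determinism.  The self-connection is added
    afterwards and never counts toward k.
    """
    n = C.values.shape[0]
    k = neighbors_per_row(n, density)
    A = np.zeros((n, n), dtype=float)
    for i in range(n):
        row = C.values[i].copy()
        row[i] = -np.inf  # self excluded from the top-k
        # lexsort: primary key descending correlation, ties -> lower index
        order = np.lexsort((np.arange(n), -row))
        A[i, order[:k]] = 1.0
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(values=A, sample_ids=list(C.sample_ids), density=density)


def save_matrix(values: np.ndarray, sample_ids, path, delimiter: str = "\t") -> None:
    """Write a square sample x sample matrix with IDs on both axes."""
    pd.DataFrame(values, index=list(sample_ids), columns=list(sample_ids)).to_csv(
        path, sep=delimiter, index_label="sample_id"
    )


def load_adjacency(path, delimiter: str = "\t") -> AdjacencyMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return AdjacencyMatrix(values=df.to_numpy(dtype=float), sample_ids=df.index.astype(str).tolist())
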
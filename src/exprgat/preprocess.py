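"""Expression matrix I/O and preprocessing.

Matrices live on disk as delimited text (TSV by default) with a header
row and the first column holding identifiers, samples-as-rows or
genes-as-rows.  Preprocessing mirrors common bulk/scRNA-seq practice:
a log2(x+1) variance-stabilising transform followed by optional PCA
reduction of the feature space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, FeatureMatrix, LabelVector

__all__ = [
    "load_expression",
    "save_expression",
    "load_labels",
    "save_labels",
    "log_transform",
    "pca_reduce",
]


def load_expression(
    path,
    orientation: str = "samples-rows",
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression matrix, returning it samples x genes.

    Parameters
    ----------
    path
        Delimited text file with a header row; first column = IDs.
    orientation
        ``samples-rows`` if rows are samples, ``genes-rows`` if the file
        stores the transpose (Xena-style genomicMatrix).
    """
    if orientation not in ("samples-rows", "genes-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "genes-rows":
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    return ExpressionMatrix(
        values=values,
        sample_ids=df.index.tolist(),
        feature_ids=df.columns.tolist(),
    )


def save_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=delimiter, index_label="sample_id")


def load_labels(path, delimiter: str = "\t") -> tuple[list[str], LabelVector]:
    """Read a two-column (sample_id, label) file.

    Returns the sample ID order together with the labels so callers can
    align them against an expression matrix.
    """
    df = pd.read_csv(path, sep=delimiter, header=0)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, label")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].to_numpy()
    return sample_ids, LabelVector(labels=labels)


def save_labels(sample_ids, labels: LabelVector, path, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": labels.labels}).to_csv(
        path, sep=delimiter, index=False
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1) elementwise; shape and identifiers unchanged."""
    if np.any(expr.values < 0):
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(
        values=np.log2(expr.values + 1.0),
        sample_ids=list(expr.sample_ids),
        feature_ids=list(expr.feature_ids),
    )


def pca_reduce(X: FeatureMatrix, n_components: int, seed: int = 0) -> FeatureMatrix:
    """Project samples onto their top principal components.

    The data is mean-centered (never variance-scaled) and each
    component's sign is fixed so that its largest-magnitude loading is
    positive, making scores reproducible across platforms.
    """
    n, m = X.values.shape
    if not (1 <= n_components <= min(n, m)):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n={n}, m={m})]"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X.values)
    # sign convention: largest-|loading| entry of each component positive
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return FeatureMatrix(
        values=scores,
        sample_ids=list(X.sample_ids),
        provenance="pca",
        feature_ids=[f"PC{j + 1}" for j in range(n_components)],
    )
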
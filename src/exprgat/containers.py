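"""Lightweight containers for expression data, features and labels.

These are thin, validated wrappers around numpy arrays plus identifier
lists.  They exist so that sample identity survives every pipeline stage
(load -> transform -> graph -> embedding -> clusters) and so that shape
and invariant violations fail loudly at the boundary rather than deep
inside a matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "FeatureMatrix", "LabelVector"]


def _as_id_list(ids) -> list[str]:
    return [str(i) for i in ids]


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of non-negative expression values.

    Rows are samples (patients or cells), columns are features (genes).
    Values may be raw counts/TPM or already log-scale; they must be
    finite, non-negative and complete.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_id_list(self.sample_ids)
        self.feature_ids = _as_id_list(self.feature_ids)
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if len(self.sample_ids) != n or len(self.feature_ids) != m:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class FeatureMatrix:
    """The samples x features matrix actually fed to the network.

    ``provenance`` records how it was derived from the raw expression:
    ``raw`` (identity), ``log2p1`` (log2(x+1)) or ``pca`` (principal
    component scores).
    """

    values: np.ndarray
    sample_ids: list[str]
    provenance: str = "raw"
    feature_ids: list[str] | None = field(default=None)

    _PROVENANCES = ("raw", "log2p1", "pca")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_id_list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.feature_ids is None:
            self.feature_ids = [f"f{j}" for j in range(self.values.shape[1])]
        else:
            self.feature_ids = _as_id_list(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, provenance: str = "raw") -> "FeatureMatrix":
        return cls(
            values=expr.values.copy(),
            sample_ids=list(expr.sample_ids),
            provenance=provenance,
            feature_ids=list(expr.feature_ids),
        )


@dataclass
class LabelVector:
    """Per-sample categorical labels with an ordered class list."""

    labels: np.ndarray
    classes: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.classes is None:
            self.classes = sorted(np.unique(self.labels).tolist())
        else:
            self.classes = list(self.classes)
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        known = set(self.classes)
        for lab in self.labels.tolist():
            if lab not in known:
                raise ValueError(f"label {lab!r} not in class list")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def indices(self) -> np.ndarray:
        """Labels encoded as integer indices into ``classes``."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[lab] for lab in self.labels.tolist()], dtype=int)
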
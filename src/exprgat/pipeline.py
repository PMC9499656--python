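"""End-to-end pipeline driver with config handling and run manifests.

``run_pipeline`` chains preprocessing -> graph construction -> model
(classifier or autoencoder, optionally attention extraction), writes
every artifact to the output directory and records a manifest (config
hash, master seed, derived stage seeds, library versions, outputs,
metrics) from which the run is reproducible.

Seeding contract: one master seed; every stochastic stage gets its own
seed derived deterministically from (master, stage name).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .attention import cluster_attention_matrix, extract_attention_matrix
from .autoencoder import AEConfig, train_autoencoder
from .classifier import (
    GATConfig,
    SplitSpec,
    TrainConfig,
    evaluate_auroc,
    train_classifier,
)
from .cluster import PRESETS, evaluate_clustering, hierarchical_cluster
from .containers import FeatureMatrix, LabelVector
from .gat import save_encoder
from .graph import build_adjacency, pairwise_correlation, save_matrix
from .preprocess import load_expression, load_labels, log_transform, pca_reduce

logger = logging.getLogger("exprgat")

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

_MODES = ("classify", "cluster", "attention")


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Flat, YAML-serializable configuration of a full run."""

    features: str = ""
    labels: str | None = None
    orientation: str = "samples-rows"
    delimiter: str = "\t"
    log2: bool = False
    pca_components: int | None = None
    density: float = 0.1
    embed_size: int = 8
    heads: int = 8
    slope: float = 0.2
    activation: str = "elu"
    lr: float = 0.005
    weight_decay: float = 5e-4
    max_epochs: int = 500
    patience: int = 50
    ae_lr: float = 0.001
    ae_epochs: int = 500
    k: int = 2
    metric: str = "manhattan"
    linkage: str = "average"
    seed: int = 0
    out_dir: str = "exprgat_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """Error annotated with the pipeline stage it arose in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # annotate and re-raise
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("preprocess")
def _load_features(cfg: RunConfig):
    expr = load_expression(cfg.features, orientation=cfg.orientation, delimiter=cfg.delimiter)
    if cfg.log2:
        expr = log_transform(expr)
    X = FeatureMatrix.from_expression(expr, provenance="log2p1" if cfg.log2 else "raw")
    if cfg.pca_components:
        X = pca_reduce(X, cfg.pca_components, seed=derive_seed(cfg.seed, "pca"))
    return X


@_stage("labels")
def _load_aligned_labels(cfg: RunConfig, X: FeatureMatrix) -> LabelVector:
    if cfg.labels is None:
        raise FileNotFoundError("classifier stage requires a labels file")
    ids, labels = load_labels(cfg.labels, delimiter=cfg.delimiter)
    lookup = dict(zip(ids, labels.labels.tolist()))
    missing = [s for s in X.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    aligned = [lookup[s] for s in X.sample_ids]
    return LabelVector(labels=np.asarray(aligned), classes=labels.classes)


def run_pipeline(config: RunConfig, mode: str) -> dict:
    """Execute one full run; returns (and writes) the manifest dict."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    metrics: dict = {"auroc": None, "nmi": None, "ari": None, "seed": config.seed}

    X = _load_features(config)
    metrics["n"] = X.n_samples
    logger.info("loaded %d samples x %d features (%s)", X.n_samples, X.n_features, X.provenance)

    try:
        C = pairwise_correlation(X)
        A = build_adjacency(C, config.density)
    except Exception as exc:
        raise StageError("graph_build", exc) from exc
    save_matrix(A.values, A.sample_ids, out / "adjacency.tsv")
    outputs["adjacency"] = "adjacency.tsv"

    gat_cfg = GATConfig(
        embed_size=config.embed_size, heads=config.heads,
        slope=config.slope, activation=config.activation,
    )

    if mode == "classify":
        labels = _load_aligned_labels(config, X)
        seed = derive_seed(config.seed, "classifier")
        try:
            model = train_classifier(
                X, A, labels,
                split=SplitSpec(seed=seed),
                gat=gat_cfg,
                train=TrainConfig(
                    lr=config.lr, weight_decay=config.weight_decay,
                    max_epochs=config.max_epochs, patience=config.patience, seed=seed,
                ),
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("classifier", exc) from exc
        _, _, test_idx = model.history["split"]
        y = labels.indices()
        if labels.n_classes == 2:
            scores = model.decision_scores(X, A)
            metrics["auroc"] = evaluate_auroc(scores[test_idx], (y[test_idx] == 1).astype(int))
        save_encoder(out / "model.npz", model.encoder)
        outputs["model"] = "model.npz"
        _write_history(out / "loss_history.csv", model.history)
        outputs["loss_history"] = "loss_history.csv"
        logger.info("classifier test AUROC: %s", metrics["auroc"])
    else:
        seed = derive_seed(config.seed, "autoencoder")
        try:
            ae = train_autoencoder(
                X, A, gat=gat_cfg,
                config=AEConfig(lr=config.ae_lr, epochs=config.ae_epochs, seed=seed),
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("autoencoder", exc) from exc
        Z = ae.embed(X, A)
        _write_embedding(out / "embeddings.tsv", Z, X.sample_ids)
        outputs["embeddings"] = "embeddings.tsv"
        save_encoder(out / "model.npz", ae.encoder)
        outputs["model"] = "model.npz"

        if mode == "attention":
            M = extract_attention_matrix(ae.encoder, X, A)
            save_matrix(M.values, X.sample_ids, out / "attention.tsv")
            outputs["attention"] = "attention.tsv"
            assignment = cluster_attention_matrix(M, config.k, config.metric, config.linkage)
        else:
            assignment = hierarchical_cluster(Z, config.k, config.metric, config.linkage)

        _write_assignment(out / "clusters.tsv", assignment, X.sample_ids)
        outputs["clusters"] = "clusters.tsv"
        if config.labels is not None:
            truth = _load_aligned_labels(config, X)
            metrics["nmi"], metrics["ari"] = evaluate_clustering(assignment, truth)
        logger.info("clustering NMI=%s ARI=%s", metrics["nmi"], metrics["ari"])

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    outputs["metrics"] = "metrics.json"

    manifest = {
        "mode": mode,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in ("pca", "classifier", "autoencoder")},
        "versions": {"exprgat": __version__, "numpy": np.__version__},
        "outputs": outputs,
        "metrics": metrics,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_embedding(path, Z, sample_ids) -> None:
    import pandas as pd

    cols = [f"e{j}" for j in range(Z.values.shape[1])]
    pd.DataFrame(Z.values, index=sample_ids, columns=cols).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def _write_assignment(path, assignment, sample_ids) -> None:
    import pandas as pd

    pd.DataFrame({"sample_id": sample_ids, "cluster": assignment.labels}).to_csv(
        path, sep="\t", index=False
    )


def _write_history(path, history) -> None:
    import pandas as pd

    pd.DataFrame(
        {"epoch": range(len(history["train_loss"])),
         "train_loss": history["train_loss"],
         "val_loss": history["val_loss"]}
    ).to_csv(path, index=False)
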
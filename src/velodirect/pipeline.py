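"""End-to-end experiment: preprocess -> velocity -> labels -> features ->
stratified 8:2 split -> SMOTE-Tomek on the training split -> train the
cascade and the four standalone base ensembles -> evaluate on the untouched
test split with accuracy, macro-F1 and Cohen's kappa.

Unsupervised stages (kinetic fits, feature ranking) see all cells; classifier
fitting and resampling see only training rows, so the test split never leaks
into any trained model.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from velodirect import preprocess as pp
from velodirect import velocity_models as vm
from velodirect.cascade_forest import (
    default_estimator_specs,
    fit_cascade,
    predict_cascade,
)
from velodirect.direction_labeling import embed_pca2, label_directions
from velodirect.errors import ConfigError, PipelineStageError, StratificationError
from velodirect.eval_metrics import compute_report
from velodirect.feature_selection import build_features, rank_velocity_genes
from velodirect.preprocess import CountDataset
from velodirect.resampling import smote_tomek


@dataclass
class ExperimentConfig:
    """Knobs of one classification experiment."""

    mode: str = "steady"              # "steady" | "dynamic"
    k: int = 20                       # top genes per cluster
    d: int = 4                        # number of direction classes
    split_ratio: float = 0.8
    seed: int = 0
    min_shared_counts: int = 20
    hvg: str | int = "auto"           # "auto" -> tiered rule by n_cells
    n_pcs: int = 30
    k_neighbors: int = 30
    smote_enabled: bool = True
    smote_k: int = 5
    classifiers: tuple = ("cascade", "random_forest", "extra_trees", "xgboost", "lightgbm")
    cascade_max_levels: int = 8
    cascade_patience: int = 1
    cascade_tol: float = 1e-4
    cascade_folds: int = 5

    def validate(self):
        if not 0 < self.split_ratio < 1:
            raise ConfigError("split_ratio must be in (0, 1)")
        if self.k < 1 or self.d < 2:
            raise ConfigError("need k >= 1 and d >= 2")
        if self.mode not in ("steady", "dynamic"):
            raise ConfigError("mode must be 'steady' or 'dynamic'")
        if self.hvg != "auto" and (not isinstance(self.hvg, int) or self.hvg < 1):
            raise ConfigError("hvg must be 'auto' or a positive integer")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Metrics per classifier plus dataset summary and provenance."""

    metrics: dict                      # classifier -> metric dict
    dataset_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "dataset_summary": self.dataset_summary,
            "provenance": self.provenance,
        }


def stratified_split(labels, ratio: float = 0.8, seed: int = 0):
    """Seeded per-class proportional split into (train_idx, test_idx).

    Disjoint and exhaustive; every class contributes at least one sample to
    each side, so classes need >= 2 members.
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ConfigError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise StratificationError(f"class {cls!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_train = int(np.clip(round(ratio * idx.size), 1, idx.size - 1))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def prepare_labeled(ds: CountDataset, config: ExperimentConfig):
    """Run the unsupervised half of the pipeline.

    Returns ``(proc, moments, vfield, emb, labels)`` where ``proc`` is the
    filtered/normalized/HVG-restricted dataset and ``labels`` the d-way
    direction classes.
    """
    config.validate()
    with _stage("preprocess"):
        proc = pp.filter_genes(ds, config.min_shared_counts)
        proc = pp.normalize(proc)
        n_top = pp.hvg_count_rule(proc.n_cells) if config.hvg == "auto" else int(config.hvg)
        proc = pp.select_hvgs(proc, n_top)
        moments = pp.compute_moments(proc, n_pcs=config.n_pcs,
                                     k_neighbors=min(config.k_neighbors, proc.n_cells))
    with _stage("velocity"):
        if config.mode == "steady":
            fit = vm.fit_steady_state(moments.Mu, moments.Ms)
            vfield = vm.steady_state_velocity(moments.Mu, moments.Ms, fit)
        else:
            fit = vm.fit_dynamic(moments.Mu, moments.Ms)
            vfield = vm.dynamic_velocity(moments.Mu, moments.Ms, fit)
    with _stage("label"):
        emb = embed_pca2(proc)
        labels = label_directions(vfield, emb, d=config.d)
        n_zero = int((~labels.valid).sum())
        if n_zero:
            warnings.warn(f"{n_zero} cell(s) with zero projected velocity excluded from training")
    return proc, moments, vfield, emb, labels


def run_experiment(config: ExperimentConfig, ds: CountDataset) -> RunReport:
    """Full supervised experiment on one dataset; see module docstring."""
    t0 = time.time()
    proc, moments, vfield, emb, labels = prepare_labeled(ds, config)

    with _stage("features"):
        if "cluster" not in proc.cell_meta.columns:
            raise ConfigError("cell_meta must carry a 'cluster' column for feature selection")
        rankings = rank_velocity_genes(vfield, proc.cell_meta["cluster"].to_numpy(),
                                       proc.gene_ids)
        table = build_features(proc, rankings, k=config.k)

    with _stage("split"):
        cells = np.flatnonzero(labels.valid)
        y = labels.class_label[cells]
        X = table.matrix[cells]
        tr, te = stratified_split(y, ratio=config.split_ratio, seed=config.seed)
        X_train, y_train = X[tr], y[tr]
        X_test, y_test = X[te], y[te]

    with _stage("resample"):
        if config.smote_enabled:
            res = smote_tomek(X_train, y_train, k_neighbors=config.smote_k, seed=config.seed)
            X_train, y_train = res.matrix, res.labels

    metrics = {}
    specs = {s.name: s for s in default_estimator_specs()}
    with _stage("train"):
        preds = {}
        for name in config.classifiers:
            if name == "cascade":
                model = fit_cascade(
                    X_train, y_train,
                    n_folds=config.cascade_folds,
                    max_levels=config.cascade_max_levels,
                    patience=config.cascade_patience,
                    tol=config.cascade_tol,
                    seed=config.seed,
                )
                preds[name], _ = predict_cascade(model, X_test)
            elif name in specs:
                clf = specs[name].factory(config.seed)
                clf.fit(X_train, y_train)
                preds[name] = np.asarray(clf.predict(X_test))
            else:
                raise ConfigError(f"unknown classifier {name!r}")

    with _stage("evaluate"):
        for name, yhat in preds.items():
            metrics[name] = compute_report(y_test, yhat, n_classes=config.d).to_dict()

    class_hist = {int(c): int(n) for c, n in
                  zip(*np.unique(labels.class_label[labels.valid], return_counts=True))}
    return RunReport(
        metrics=metrics,
        dataset_summary={
            "n_cells": ds.n_cells,
            "n_genes_raw": ds.n_genes,
            "n_genes_hvg": proc.n_genes,
            "n_features": len(table.gene_ids),
            "n_labeled_cells": int(labels.valid.sum()),
            "class_histogram": class_hist,
            "mode": config.mode,
        },
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
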
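"""Per-cluster velocity-gene ranking and classifier feature construction.

Genes are ranked within each cluster by the Welch t-statistic of their
velocity values (cluster vs. rest); the classifier's feature matrix is the
log-normalized spliced expression of the union of the top-k genes per
cluster.  Expression (not velocity) is the feature: the task is to predict
the velocity direction of a cell from its gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from velodirect.errors import ConfigError, EmptyResultError, ShapeError
from velodirect.preprocess import CountDataset
from velodirect.velocity_models import VelocityField


@dataclass
class FeatureTable:
    """cells x p feature matrix plus provenance of the selected genes."""

    matrix: np.ndarray
    gene_ids: list
    per_cluster_rankings: dict     # cluster -> ordered gene-id list


def rank_velocity_genes(v: VelocityField, clusters, gene_ids) -> dict:
    """Ordered gene lists per cluster, by descending Welch t of velocity.

    For each cluster the per-gene statistic contrasts velocity values of
    in-cluster cells against all other cells; ties (and degenerate zero
    variances) break deterministically by gene id.  Clusters with fewer than
    3 cells are skipped with a warning.  With a single cluster, genes are
    ranked globally by absolute mean velocity.
    """
    clusters = np.asarray(clusters)
    gene_ids = np.asarray(gene_ids)
    V = v.velocity
    if V.shape[0] != clusters.shape[0]:
        raise ShapeError("clusters length must match velocity rows")
    if V.shape[1] != gene_ids.shape[0]:
        raise ShapeError("gene_ids length must match velocity columns")
    labels = np.unique(clusters)

    def _order(score: np.ndarray) -> list:
        idx = sorted(range(len(gene_ids)), key=lambda i: (-score[i], gene_ids[i]))
        return [gene_ids[i] for i in idx]

    if labels.size == 1:
        return {labels[0]: _order(np.abs(V.mean(axis=0)))}

    rankings = {}
    for lab in labels:
        mask = clusters == lab
        if mask.sum() < 3:
            warnings.warn(f"cluster {lab!r} has fewer than 3 cells; skipped from ranking")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t = stats.ttest_ind(V[mask], V[~mask], equal_var=False, axis=0).statistic
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        rankings[lab] = _order(t)
    return rankings


def build_features(ds: CountDataset, rankings: dict, k: int = 20) -> FeatureTable:
    """Union of top-k ranked genes per cluster as an expression feature matrix.

    Clusters are visited in sorted order; duplicates keep their first
    occurrence, so the column order is reproducible bit-exactly.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if ds.log_spliced is None:
        raise ConfigError("build_features requires a normalized dataset with a log layer")
    selected: list = []
    seen = set()
    for lab in sorted(rankings):
        for gid in rankings[lab][:k]:
            if gid not in seen:
                seen.add(gid)
                selected.append(gid)
    if not selected:
        raise EmptyResultError("feature union is empty; no ranked genes available")
    pos = {gid: i for i, gid in enumerate(ds.gene_ids)}
    missing = [g for g in selected if g not in pos]
    if missing:
        raise ShapeError(f"ranked genes absent from dataset: {missing[:5]}")
    cols = np.array([pos[g] for g in selected])
    return FeatureTable(
        matrix=ds.log_spliced[:, cols].copy(),
        gene_ids=list(selected),
        per_cluster_rankings={lab: list(r) for lab, r in rankings.items()},
    )
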
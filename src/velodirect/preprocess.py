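"""Preprocessing of paired spliced/unspliced count matrices.

Mirrors the conventional single-cell velocity workflow: gene filtering by
shared counts, per-cell depth normalization with a log1p copy of the spliced
layer, tiered highly-variable-gene selection, and kNN moment smoothing on a
PCA embedding of the log layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from velodirect.errors import ConfigError, EmptyResultError, ProvenanceError, ShapeError


@dataclass
class CountDataset:
    """Paired spliced/unspliced cells x genes matrices with metadata.

    ``cell_meta`` is indexed by cell id and must carry a ``cluster`` column
    before feature selection; ``gene_meta`` is indexed by gene id.  Layer
    provenance is tracked by ``normalized``; ``log_spliced`` is the
    log1p-transformed normalized spliced layer used for HVG selection and
    embeddings (velocity layers stay normalized-but-unlogged).
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    normalized: bool = False
    log_spliced: Optional[np.ndarray] = None

    def __post_init__(self):
        n, g = self.spliced.shape
        if self.unspliced.shape != (n, g):
            raise ShapeError("spliced and unspliced shapes differ")
        if len(self.cell_meta) != n:
            raise ShapeError(f"cell_meta has {len(self.cell_meta)} rows, expected {n}")
        if len(self.gene_meta) != g:
            raise ShapeError(f"gene_meta has {len(self.gene_meta)} rows, expected {g}")
        if self.log_spliced is not None and self.log_spliced.shape != (n, g):
            raise ShapeError("log_spliced shape differs from spliced")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return np.asarray(self.gene_meta.index)

    def subset_genes(self, index) -> "CountDataset":
        """Return a new dataset restricted to the given gene positions (all layers)."""
        index = np.asarray(index)
        return CountDataset(
            spliced=self.spliced[:, index].copy(),
            unspliced=self.unspliced[:, index].copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[index].copy(),
            normalized=self.normalized,
            log_spliced=None if self.log_spliced is None else self.log_spliced[:, index].copy(),
        )

    def copy(self) -> "CountDataset":
        return self.subset_genes(np.arange(self.n_genes))


@dataclass
class MomentsResult:
    """kNN-smoothed first/second moments of both layers.

    Each cell's neighbor list contains the cell itself, so ``k_neighbors=1``
    returns the layers unchanged.
    """

    Mu: np.ndarray
    Ms: np.ndarray
    Mu2: np.ndarray
    Ms2: np.ndarray
    knn_indices: np.ndarray  # cells x k


def filter_genes(ds: CountDataset, min_shared_counts: int = 20) -> CountDataset:
    """Keep genes whose summed spliced AND summed unspliced counts reach the threshold."""
    if min_shared_counts < 0:
        raise ConfigError("min_shared_counts must be >= 0")
    keep = (ds.spliced.sum(axis=0) >= min_shared_counts) & (
        ds.unspliced.sum(axis=0) >= min_shared_counts
    )
    if not keep.any():
        raise EmptyResultError(
            f"min_shared_counts={min_shared_counts} removed all {ds.n_genes} genes"
        )
    return ds.subset_genes(np.flatnonzero(keep))


def hvg_count_rule(n_cells: int) -> int:
    """Tiered number of highly variable genes to retain, by dataset size.

    2000 below 3000 cells, 2500 for mid-sized datasets, 3000 above 6000 cells.
    The boundary counts 3000 and 6000 fall in the middle tier.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if n_cells < 3000:
        return 2000
    if n_cells <= 6000:
        return 2500
    return 3000


def normalize(ds: CountDataset) -> CountDataset:
    """Per-cell depth normalization of both layers plus a log1p spliced copy.

    Each layer is scaled by its own size factors (cell total / median total).
    Cells with zero total get size factor 1 with a warning.  Re-normalizing an
    already-normalized dataset is rejected.
    """
    if ds.normalized:
        raise ProvenanceError("dataset is already normalized; refusing to compound")

    def _scale(layer: np.ndarray) -> np.ndarray:
        totals = layer.sum(axis=1)
        med = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
        sf = totals / med
        zero = totals == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} cell(s) with zero total; size factor set to 1")
            sf[zero] = 1.0
        return layer / sf[:, None]

    spliced = _scale(ds.spliced)
    unspliced = _scale(ds.unspliced)
    return CountDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_meta=ds.cell_meta.copy(),
        gene_meta=ds.gene_meta.copy(),
        normalized=True,
        log_spliced=np.log1p(spliced),
    )


def dispersion_ranking(ds: CountDataset, n_bins: int = 20) -> np.ndarray:
    """Gene positions ordered by decreasing binned normalized dispersion.

    Dispersion = variance/mean of the normalized spliced layer, z-scored
    within ``n_bins`` equal-width mean bins (the standard single-cell
    dispersion flavor).  Ties (and degenerate single-gene bins) break by gene
    position, so the ordering is deterministic.
    """
    if not ds.normalized:
        raise ProvenanceError("select_hvgs requires a normalized dataset")
    x = ds.spliced
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if ds.n_cells > 1 else np.zeros(ds.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp})
    try:
        df["bin"] = pd.cut(df["mean"], bins=min(n_bins, max(ds.n_genes, 1)))
    except ValueError:  # all means identical
        df["bin"] = 0
    grp = df.groupby("bin", observed=True)["disp"]
    z = (df["disp"] - grp.transform("mean")) / grp.transform("std")
    z = z.fillna(0.0).to_numpy()
    order = np.lexsort((np.arange(ds.n_genes), -z))
    return order


def select_hvgs(ds: CountDataset, n_top: int) -> CountDataset:
    """Keep the ``n_top`` most highly variable genes (all genes if fewer exist).

    Gene order of the original matrix is preserved in the subset.
    """
    if n_top < 1:
        raise ConfigError("n_top must be >= 1")
    if n_top >= ds.n_genes:
        return ds.copy()
    top = np.sort(dispersion_ranking(ds)[:n_top])
    return ds.subset_genes(top)


def compute_moments(ds: CountDataset, n_pcs: int = 30, k_neighbors: int = 30) -> MomentsResult:
    """kNN moment smoothing of both layers.

    The graph is built with Euclidean distance in the top ``n_pcs`` principal
    components of the log layer; each cell's neighborhood includes itself.
    First moments are neighborhood means, second moments means of squares.
    """
    if k_neighbors <= 0:
        raise ConfigError("k_neighbors must be >= 1")
    if k_neighbors > ds.n_cells:
        raise ConfigError("k_neighbors must be <= n_cells")
    if not ds.normalized or ds.log_spliced is None:
        raise ProvenanceError("compute_moments requires a normalized dataset with a log layer")

    n_comp = int(min(n_pcs, ds.n_cells - 1, ds.n_genes))
    if n_comp >= 1:
        pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(ds.log_spliced)
    else:
        pcs = ds.log_spliced
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    # guarantee self-inclusion even when duplicate points shadow the query cell
    rows = np.arange(ds.n_cells)
    has_self = (idx == rows[:, None]).any(axis=1)
    idx[~has_self, -1] = rows[~has_self]

    Mu = ds.unspliced[idx].mean(axis=1)
    Ms = ds.spliced[idx].mean(axis=1)
    Mu2 = (ds.unspliced**2)[idx].mean(axis=1)
    Ms2 = (ds.spliced**2)[idx].mean(axis=1)
    return MomentsResult(Mu=Mu, Ms=Ms, Mu2=Mu2, Ms2=Ms2, knn_indices=idx)
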
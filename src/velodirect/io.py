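"""On-disk bundle: MatrixMarket count layers plus TSV metadata tables.

A dataset directory contains ``spliced.mtx`` and ``unspliced.mtx``
(coordinate MatrixMarket, cells x genes), ``cells.tsv`` (cell_id, cluster,
optional latent_time / true_class) and ``genes.tsv`` (gene_id plus any
per-gene columns such as kinetic parameters).  Derived artifacts use the
same directory: ``velocity.mtx`` + ``gene_fits.tsv``, ``embedding.tsv``,
``labels.tsv``, ``features.tsv``, ``metrics.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from velodirect.errors import ConfigError
from velodirect.preprocess import CountDataset


def write_dataset(ds: CountDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "spliced.mtx", sparse.coo_matrix(ds.spliced))
    spio.mmwrite(out / "unspliced.mtx", sparse.coo_matrix(ds.unspliced))
    ds.cell_meta.to_csv(out / "cells.tsv", sep="\t")
    ds.gene_meta.to_csv(out / "genes.tsv", sep="\t")


def read_dataset(in_dir) -> CountDataset:
    src = Path(in_dir)
    for fname in ("spliced.mtx", "unspliced.mtx", "cells.tsv", "genes.tsv"):
        if not (src / fname).exists():
            raise ConfigError(f"dataset bundle is missing {fname} in {src}")
    spliced = np.asarray(spio.mmread(src / "spliced.mtx").todense(), dtype=float)
    unspliced = np.asarray(spio.mmread(src / "unspliced.mtx").todense(), dtype=float)
    cells = pd.read_csv(src / "cells.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(src / "genes.tsv", sep="\t", index_col=0)
    return CountDataset(spliced=spliced, unspliced=unspliced,
                       cell_meta=cells, gene_meta=genes)


def write_velocity(v, gene_fits: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "velocity.mtx", sparse.coo_matrix(v.velocity))
    gene_fits.to_csv(out / "gene_fits.tsv", sep="\t")


def write_labels(labels, cell_ids, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "dx": labels.displacement[:, 0],
            "dy": labels.displacement[:, 1],
            "angle": labels.angle,
            "class": labels.class_label,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    ).to_csv(out / "labels.tsv", sep="\t")


def write_features(table, cell_ids, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(table.matrix, columns=table.gene_ids,
                 index=pd.Index(cell_ids, name="cell_id")).to_csv(
        out / "features.tsv", sep="\t")
    with open(out / "rankings.json", "w") as fh:
        json.dump({str(k): [str(g) for g in v]
                   for k, v in table.per_cluster_rankings.items()}, fh, indent=1)


def write_metrics(report_dict: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report_dict, fh, indent=1, default=float)
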
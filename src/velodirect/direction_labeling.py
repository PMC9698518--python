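"""2D projection of velocity and equal angular class labels.

The velocity field is pushed through the linear PCA map of the expression
embedding (``displacement = v @ loadings``) and the displacement angle,
measured counterclockwise from the +x axis, is discretized into ``d``
half-open equal segments ``[2*pi*c/d, 2*pi*(c+1)/d)`` — the supervised
classification target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from velodirect.errors import ConfigError, ShapeError
from velodirect.preprocess import CountDataset
from velodirect.velocity_models import VelocityField

#: relative tolerance for snapping d*theta/(2*pi) onto a segment boundary, so
#: displacements lying exactly on a boundary follow the half-open rule instead
#: of a one-ULP float rounding.
_BOUNDARY_SNAP = 1e-9


@dataclass
class Embedding2D:
    """A linear 2D embedding: ``coords = (X - mean) @ loadings``."""

    coords: np.ndarray        # cells x 2
    loadings: np.ndarray      # genes x 2
    mean: np.ndarray          # per-gene centering vector
    gene_ids: np.ndarray
    method: str = "pca"


@dataclass
class DirectionLabels:
    """Per-cell 2D displacement, angle in [0, 2*pi), and direction class.

    Cells with zero displacement have no defined direction: they get
    ``class_label = -1``, ``valid = False`` and are excluded from training.
    """

    displacement: np.ndarray  # cells x 2
    angle: np.ndarray         # radians in [0, 2*pi); NaN where invalid
    class_label: np.ndarray   # int in {0..d-1}; -1 where invalid
    d: int
    valid: np.ndarray         # bool per cell


def embed_pca2(ds: CountDataset, gene_positions: Optional[Sequence[int]] = None) -> Embedding2D:
    """Top-2 PCA of the log layer with a deterministic sign convention.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making repeated runs bit-identical.
    """
    if ds.log_spliced is None:
        raise ConfigError("embed_pca2 requires a normalized dataset with a log layer")
    X = ds.log_spliced
    ids = ds.gene_ids
    if gene_positions is not None:
        gene_positions = np.asarray(gene_positions)
        X = X[:, gene_positions]
        ids = ids[gene_positions]
    if X.shape[1] < 2:
        raise ConfigError("need at least 2 genes for a 2D embedding")
    pca = PCA(n_components=2, svd_solver="full").fit(X)
    loadings = pca.components_.T.copy()      # genes x 2
    coords = (X - pca.mean_) @ loadings
    for c in range(2):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            coords[:, c] *= -1
    return Embedding2D(coords=coords, loadings=loadings, mean=pca.mean_.copy(),
                       gene_ids=np.asarray(ids))


def project_velocity(v: VelocityField, emb: Embedding2D,
                     gene_ids: Optional[Sequence] = None) -> np.ndarray:
    """Exact linear pushforward of the velocity through the embedding map.

    ``gene_ids`` names the velocity columns; it must match the embedding's
    gene set (in order) or a :class:`ShapeError` is raised.
    """
    if gene_ids is not None and not np.array_equal(np.asarray(gene_ids), emb.gene_ids):
        raise ShapeError("velocity gene set does not match the embedding gene set")
    if v.velocity.shape[1] != emb.loadings.shape[0]:
        raise ShapeError(
            f"velocity has {v.velocity.shape[1]} genes, embedding expects {emb.loadings.shape[0]}"
        )
    return v.velocity @ emb.loadings


def angle_to_class(displacement: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map 2D displacements to angles and half-open equal angular classes.

    Returns ``(class_label, angle, valid)``.  The angle is ``atan2(dy, dx)``
    wrapped to [0, 2*pi); the class is ``floor(d*angle/(2*pi))`` with values
    on a segment boundary assigned to the higher class (half-open intervals).
    Zero displacements are flagged invalid (class -1, angle NaN).
    """
    if d < 2:
        raise ConfigError("need d >= 2 angular classes")
    disp = np.atleast_2d(np.asarray(displacement, dtype=float))
    if disp.shape[1] != 2:
        raise ShapeError("displacement must be (n, 2)")
    norm = np.hypot(disp[:, 0], disp[:, 1])
    valid = norm > 0
    angle = np.full(disp.shape[0], np.nan)
    cls = np.full(disp.shape[0], -1, dtype=int)
    theta = np.arctan2(disp[valid, 1], disp[valid, 0]) % (2 * np.pi)
    x = d * theta / (2 * np.pi)
    r = np.rint(x)
    x = np.where(np.abs(x - r) < _BOUNDARY_SNAP, r, x)
    cls[valid] = np.floor(x).astype(int) % d
    angle[valid] = theta
    return cls, angle, valid


def label_directions(v: VelocityField, emb: Embedding2D, d: int = 4,
                     gene_ids: Optional[Sequence] = None) -> DirectionLabels:
    """Project velocity to 2D and assign the d-way angular class per cell."""
    disp = project_velocity(v, emb, gene_ids=gene_ids)
    cls, angle, valid = angle_to_class(disp, d)
    return DirectionLabels(displacement=disp, angle=angle, class_label=cls,
                           d=d, valid=valid)
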
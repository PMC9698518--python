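"""Class balancing for training data: SMOTE oversampling + Tomek-link cleaning.

SMOTE oversamples every minority class to the majority count by interpolating
each synthetic sample between a class member and one of its k nearest
same-class neighbors.  Tomek cleaning then removes the non-minority members
of all Tomek links (mutual nearest neighbors with different labels), which
sharpens class boundaries while preserving minority information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from velodirect.errors import ConfigError, ShapeError, StratificationError


@dataclass
class ResampledSet:
    """Feature matrix and labels after resampling.

    ``synthetic_flag`` marks interpolated rows; ``removed_ids`` lists the
    original row positions dropped as Tomek links.  Original non-removed rows
    appear unchanged.
    """

    matrix: np.ndarray
    labels: np.ndarray
    synthetic_flag: np.ndarray
    removed_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ShapeError("X must be 2-D and aligned with 1-D labels")
    return X, y


def _same_class_neighbors(Xc: np.ndarray, k: int) -> np.ndarray:
    """Indices (within Xc) of up to k nearest neighbors of each row, excluding self."""
    n = Xc.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(Xc)
    _, idx = nn.kneighbors(Xc)
    out = np.empty((n, min(k, n - 1)), dtype=int)
    for i in range(n):
        row = [j for j in idx[i] if j != i]
        # duplicates can shadow self; pad from remaining points deterministically
        if len(row) < out.shape[1]:
            extra = [j for j in range(n) if j != i and j not in row]
            row += extra[: out.shape[1] - len(row)]
        out[i] = row[: out.shape[1]]
    return out


def smote(X, y, k_neighbors: int = 5, seed: int = 0) -> ResampledSet:
    """Oversample every minority class up to the majority count.

    Each synthetic row is ``x_i + lam * (x_nn - x_i)`` with ``lam ~ U(0, 1)``
    and ``x_nn`` chosen uniformly among the (up to) ``k_neighbors`` nearest
    same-class neighbors of ``x_i``.  Deterministic given ``seed``.
    """
    if k_neighbors < 1:
        raise ConfigError("k_neighbors must be >= 1")
    X, y = _check_xy(X, y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()

    new_rows = []
    new_labels = []
    for cls, cnt in zip(classes, counts):
        if cnt == majority:
            continue
        if cnt < 2:
            raise StratificationError(
                f"class {cls!r} has a single sample; SMOTE needs >= 2 per class"
            )
        Xc = X[y == cls]
        nbrs = _same_class_neighbors(Xc, k_neighbors)
        n_new = majority - cnt
        base = rng.integers(0, cnt, size=n_new)
        pick = rng.integers(0, nbrs.shape[1], size=n_new)
        lam = rng.random(n_new)
        xb = Xc[base]
        xn = Xc[nbrs[base, pick]]
        new_rows.append(xb + lam[:, None] * (xn - xb))
        new_labels.append(np.full(n_new, cls, dtype=y.dtype))

    if new_rows:
        matrix = np.vstack([X] + new_rows)
        labels = np.concatenate([y] + new_labels)
    else:
        matrix, labels = X.copy(), y.copy()
    flag = np.zeros(matrix.shape[0], dtype=bool)
    flag[X.shape[0]:] = True
    return ResampledSet(matrix=matrix, labels=labels, synthetic_flag=flag)


def find_tomek_links(X, y) -> list:
    """All Tomek links: pairs (i, j), i < j, of mutual nearest neighbors with different labels."""
    X, y = _check_xy(X, y)
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(2, n)).fit(X)
    _, idx = nn.kneighbors(X)
    nearest = np.empty(n, dtype=int)
    for i in range(n):
        nearest[i] = idx[i, 1] if idx[i, 0] == i else idx[i, 0]
    links = []
    for i in range(n):
        j = nearest[i]
        if j > i and nearest[j] == i and y[i] != y[j]:
            links.append((i, int(j)))
    return links


def tomek_clean(X, y) -> ResampledSet:
    """Remove non-minority members of every Tomek link.

    The minority class is the globally least frequent label (ties break to
    the lowest label); its members are never removed.
    """
    X, y = _check_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError("Tomek cleaning needs >= 2 classes")
    minority = classes[np.argmin(counts)]
    removed = set()
    for i, j in find_tomek_links(X, y):
        for m in (i, j):
            if y[m] != minority:
                removed.add(m)
    removed_ids = np.array(sorted(removed), dtype=int)
    keep = np.setdiff1d(np.arange(X.shape[0]), removed_ids)
    return ResampledSet(
        matrix=X[keep].copy(),
        labels=y[keep].copy(),
        synthetic_flag=np.zeros(keep.size, dtype=bool),
        removed_ids=removed_ids,
    )


def smote_tomek(X, y, k_neighbors: int = 5, seed: int = 0) -> ResampledSet:
    """SMOTE oversampling followed by Tomek-link cleaning."""
    over = smote(X, y, k_neighbors=k_neighbors, seed=seed)
    classes = np.unique(over.labels)
    if classes.size < 2:
        return over
    cleaned = tomek_clean(over.matrix, over.labels)
    keep = np.setdiff1d(np.arange(over.matrix.shape[0]), cleaned.removed_ids)
    return ResampledSet(
        matrix=over.matrix[keep].copy(),
        labels=over.labels[keep].copy(),
        synthetic_flag=over.synthetic_flag[keep].copy(),
        removed_ids=cleaned.removed_ids[cleaned.removed_ids < X.shape[0]],
    )
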
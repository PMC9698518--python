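"""Cascade forest: a layered ensemble of heterogeneous tree learners.

Each level holds four base ensembles (two bagging: random forest and
extremely randomized trees; two boosting: XGBoost and LightGBM).  Every
estimator produces out-of-fold class-probability vectors via stratified
5-fold cross-validation; the 4*d probabilities are concatenated to the
original features as input for the next level.  Level depth is chosen
automatically: growth stops once the level's out-of-fold accuracy stops
improving, and inference propagates through the best-scoring level, averaging
the retained per-fold models of each estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from velodirect.errors import ConfigError, ModelIOError, ShapeError, StratificationError

_MAGIC = "velodirect-cascade"
_VERSION = 1


@dataclass
class EstimatorSpec:
    """A pluggable base ensemble: a name and a seed -> classifier factory.

    The classifier must implement ``fit(X, y)``, ``predict_proba(X)`` (rows
    summing to 1) and expose ``classes_`` after fitting, and be deterministic
    given the seed.
    """

    name: str
    factory: Callable[[int], object]


def _make_xgb(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=100,
        max_depth=4,
        learning_rate=0.2,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


_QUIET_LGBM_CLS = None


def _quiet_lgbm_class():
    """LGBMClassifier that doesn't warn about missing feature names on ndarray input."""
    global _QUIET_LGBM_CLS
    if _QUIET_LGBM_CLS is None:
        import warnings

        from lightgbm import LGBMClassifier

        class _QuietLGBM(LGBMClassifier):
            def predict(self, X, **kwargs):
                with warnings.catch_warnings():
                    warnings.filterwarnings("ignore", message="X does not have valid feature names")
                    return super().predict(X, **kwargs)

            def predict_proba(self, X, **kwargs):
                with warnings.catch_warnings():
                    warnings.filterwarnings("ignore", message="X does not have valid feature names")
                    return super().predict_proba(X, **kwargs)

        # hoist to module scope (via __getattr__ below) so instances pickle
        _QuietLGBM.__qualname__ = "_QuietLGBM"
        _QUIET_LGBM_CLS = _QuietLGBM
    return _QUIET_LGBM_CLS


def __getattr__(name):
    if name == "_QuietLGBM":
        return _quiet_lgbm_class()
    raise AttributeError(name)


def _make_lgbm(seed: int):
    return _quiet_lgbm_class()(
        n_estimators=100,
        learning_rate=0.2,
        num_leaves=31,
        min_child_samples=5,
        n_jobs=1,
        random_state=seed,
        verbose=-1,
    )


def default_estimator_specs() -> list[EstimatorSpec]:
    """The default 4-learner roster: RF, ExtraTrees, XGBoost, LightGBM."""
    return [
        EstimatorSpec("random_forest",
                      lambda seed: RandomForestClassifier(n_estimators=100, n_jobs=1,
                                                          random_state=seed)),
        EstimatorSpec("extra_trees",
                      lambda seed: ExtraTreesClassifier(n_estimators=100, n_jobs=1,
                                                        random_state=seed)),
        EstimatorSpec("xgboost", _make_xgb),
        EstimatorSpec("lightgbm", _make_lgbm),
    ]


@dataclass
class CascadeLevel:
    """Fitted state of one cascade level."""

    fold_models: list           # per estimator: list of n_folds fitted models
    fold_assign: np.ndarray     # per training row: validation fold id
    oof_proba: np.ndarray       # n x (n_estimators * d) out-of-fold probabilities
    score: float                # OOF accuracy of the averaged ensemble


@dataclass
class CascadeModel:
    """A fitted cascade with its validation history and stopping record."""

    levels: list
    classes_: np.ndarray
    p: int                      # original feature dimension
    d: int                      # number of classes
    n_folds: int
    validation_history: list
    best_level: int             # 1-based; inference uses levels[:best_level]
    seed: int
    estimator_names: list


def _proba_full(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """predict_proba mapped onto the full class set (guards missing columns)."""
    raw = model.predict_proba(X)
    if raw.shape[1] == classes.size:
        return raw
    out = np.zeros((X.shape[0], classes.size))
    lookup = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(model.classes_):
        out[:, lookup[c]] = raw[:, j]
    return out


def fit_cascade(
    X,
    y,
    specs: Optional[Sequence[EstimatorSpec]] = None,
    n_folds: int = 5,
    max_levels: int = 8,
    patience: int = 1,
    tol: float = 1e-4,
    seed: int = 0,
) -> CascadeModel:
    """Grow a cascade level by level with out-of-fold early stopping.

    Per level, each base estimator is fitted on the stratified folds of the
    current (augmented) features; its out-of-fold class-probability vectors
    are concatenated to the ORIGINAL features to form the next level's input.
    The level score is the accuracy of the argmax of the four estimators'
    averaged out-of-fold probabilities; growth stops after ``patience``
    consecutive levels without an improvement greater than ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ShapeError("X must be 2-D and aligned with 1-D labels")
    if specs is None:
        specs = default_estimator_specs()
    classes, y_enc = np.unique(y, return_inverse=True)
    d = classes.size
    if d < 2:
        raise StratificationError("need at least 2 classes")
    counts = np.bincount(y_enc)
    if counts.min() < n_folds:
        small = classes[int(np.argmin(counts))]
        raise StratificationError(
            f"class {small!r} has {counts.min()} samples, fewer than n_folds={n_folds}; "
            "every class must appear in every fold"
        )
    if max_levels < 1 or patience < 1:
        raise ConfigError("max_levels and patience must be >= 1")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    current = X
    levels: list[CascadeLevel] = []
    history: list[float] = []
    best_score = -np.inf
    best_level = 1
    bad = 0

    for level_idx in range(max_levels):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        est_seeds = rng.integers(0, 2**31 - 1, size=(len(specs), n_folds))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        splits = list(skf.split(current, y_enc))
        fold_assign = np.full(n, -1, dtype=int)
        for f, (_, val_idx) in enumerate(splits):
            fold_assign[val_idx] = f

        fold_models = []
        oof_blocks = []
        for e, spec in enumerate(specs):
            models = []
            oof = np.full((n, d), np.nan)
            for f, (tr_idx, val_idx) in enumerate(splits):
                model = spec.factory(int(est_seeds[e, f]))
                model.fit(current[tr_idx], y_enc[tr_idx])
                oof[val_idx] = _proba_full(model, current[val_idx], np.arange(d))
                models.append(model)
            if np.isnan(oof).any():
                raise StratificationError("out-of-fold matrix not fully covered by CV folds")
            fold_models.append(models)
            oof_blocks.append(oof)

        mean_oof = np.mean(oof_blocks, axis=0)
        score = float((np.argmax(mean_oof, axis=1) == y_enc).mean())
        oof_concat = np.hstack(oof_blocks)
        levels.append(CascadeLevel(fold_models=fold_models, fold_assign=fold_assign,
                                   oof_proba=oof_concat, score=score))
        history.append(score)

        if score > best_score + tol:
            best_score = score
            best_level = level_idx + 1
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
        current = np.hstack([X, oof_concat])

    return CascadeModel(
        levels=levels,
        classes_=classes,
        p=X.shape[1],
        d=d,
        n_folds=n_folds,
        validation_history=history,
        best_level=best_level,
        seed=seed,
        estimator_names=[s.name for s in specs],
    )


def predict_cascade(model: CascadeModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Propagate new samples through levels 1..best_level.

    At each level every estimator's class vector is the average of its
    retained fold models; the final probabilities average the estimators at
    the best level.  Labels are the argmax, ties to the lowest class index.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.p:
        raise ShapeError(f"X_new must have {model.p} columns")
    d = model.d
    current = X_new
    proba_blocks = None
    for level in model.levels[: model.best_level]:
        proba_blocks = []
        for models in level.fold_models:
            probas = [_proba_full(m, current, np.arange(d)) for m in models]
            proba_blocks.append(np.mean(probas, axis=0))
        current = np.hstack([X_new] + proba_blocks)
    final = np.mean(proba_blocks, axis=0)
    labels = model.classes_[np.argmax(final, axis=1)]
    return labels, final


def save_model(model: CascadeModel, path) -> None:
    """Serialize a fitted cascade (versioned joblib archive)."""
    joblib.dump({"magic": _MAGIC, "version": _VERSION, "model": model}, path)


def load_model(path) -> CascadeModel:
    """Load a cascade saved by :func:`save_model`; rejects foreign/corrupt files."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt pickle, wrong format
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
        raise ModelIOError(f"{path} is not a velodirect cascade model file")
    if payload.get("version") != _VERSION:
        raise ModelIOError(
            f"unsupported model version {payload.get('version')!r} (expected {_VERSION})"
        )
    return payload["model"]
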
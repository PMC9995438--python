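"""Classifier training and tuning on the patch matrix.

Four model families are supported — multinomial logistic regression (LR),
random forest (RF), gradient-boosted trees (XGB) and one-vs-rest support
vector machines (SVM) — each trained on either the two-map feature set
(DT, CBF) or the full four-map set (DT, CBF, MTT, CBV).  Tuning follows a
randomized search with k-fold cross-validation, optionally refined by a
small grid around the best candidate; the SVM search covers only linear and
polynomial kernels and skips grid refinement.

A fitted model ships as a :class:`ModelBundle` together with the
standardizer fitted on its training rows and the chosen hyperparameters, so
inference on new data reuses the exact training-time preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RandomizedSearchCV
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import hyperparams
from .evaluation import dsc as _dsc
from .evaluation import jaccard as _jaccard
from .patch_sampling import PATCH_SIZE, PatchMatrix, Standardizer, fit_standardizer

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "two_map": ("dt", "cbf"),
    "four_map": ("dt", "cbf", "mtt", "cbv"),
}
ALGORITHMS = ("lr", "rf", "xgb", "svm")


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str = "xgb"
    feature_set: str = "four_map"
    random_candidates: int = 10
    grid_refine: bool = True
    cv_folds: int = 3
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {tuple(FEATURE_SETS)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.random_candidates < 1:
            raise ValueError("random_candidates must be >= 1")

    @property
    def feature_maps(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to apply it elsewhere."""

    model: Any
    standardizer: Standardizer
    config: ModelConfig
    best_params: dict[str, Any]
    cv_score: float
    metrics: dict[str, Any] = field(default_factory=dict)

    @property
    def feature_maps(self) -> tuple[str, ...]:
        return self.config.feature_maps

    @property
    def n_features(self) -> int:
        return PATCH_SIZE * len(self.feature_maps)

    def manifest(self) -> dict[str, Any]:
        import sklearn
        import xgboost

        return {
            "algorithm": self.config.algorithm,
            "feature_set": self.config.feature_set,
            "feature_maps": list(self.feature_maps),
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
            "cv_score": self.cv_score,
            "seed": self.config.seed,
            "sklearn_version": sklearn.__version__,
            "xgboost_version": xgboost.__version__,
        }

    def save(self, path: str | Path) -> None:
        joblib.dump({"manifest": self.manifest(), "bundle": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        return joblib.load(path)["bundle"]


def make_estimator(cfg: ModelConfig):
    """Fresh unfitted estimator for one algorithm family."""
    if cfg.algorithm == "lr":
        return LogisticRegression(max_iter=2000)
    if cfg.algorithm == "rf":
        return RandomForestClassifier(random_state=cfg.seed, n_jobs=cfg.n_jobs)
    if cfg.algorithm == "xgb":
        return XGBClassifier(
            objective="multi:softprob",
            tree_method="hist",
            random_state=cfg.seed,
            n_jobs=cfg.n_jobs,
            verbosity=0,
        )
    return OneVsRestClassifier(SVC(random_state=cfg.seed), n_jobs=cfg.n_jobs)


def _refine_grid(algorithm: str, best: dict[str, Any]) -> dict[str, list]:
    """x0.5 / x1 / x2 grid around the randomized optimum, clipped to bounds."""
    grid: dict[str, list] = {}
    for name in hyperparams.GRID_REFINE[algorithm]:
        b = best[name]
        lo, hi = hyperparams.BOUNDS[name.split("__")[-1]]
        vals = [b / 2, b, b * 2]
        if isinstance(b, (int, np.integer)):
            vals = [int(round(v)) for v in vals]
        vals = sorted({min(max(v, lo), hi) for v in vals})
        grid[name] = vals
    for name, val in best.items():
        if name not in grid:
            grid[name] = [val]
    return grid


def tune_and_train(train: PatchMatrix, cfg: ModelConfig) -> ModelBundle:
    """Randomized search + optional grid refinement, then refit on all rows.

    The feature-set channel blocks are selected from ``train`` and the
    standardizer is fitted on those training rows alone; validation data can
    therefore never influence either the scaling or the hyperparameters.
    """
    sub = train.select_maps(cfg.feature_maps)
    if len(np.unique(sub.labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    standardizer = fit_standardizer(sub)
    X = standardizer.transform(sub.features)
    y = sub.labels

    search = RandomizedSearchCV(
        make_estimator(cfg),
        hyperparams.RANDOM_SPACES[cfg.algorithm],
        n_iter=cfg.random_candidates,
        cv=cfg.cv_folds,
        random_state=cfg.seed,
        n_jobs=cfg.n_jobs,
        refit=False,
    )
    search.fit(X, y)
    best_params = dict(search.best_params_)
    best_score = float(search.best_score_)

    if cfg.grid_refine and hyperparams.GRID_REFINE[cfg.algorithm]:
        grid = GridSearchCV(
            make_estimator(cfg),
            _refine_grid(cfg.algorithm, best_params),
            cv=cfg.cv_folds,
            n_jobs=cfg.n_jobs,
            refit=False,
        )
        grid.fit(X, y)
        best_params = dict(grid.best_params_)
        best_score = float(grid.best_score_)

    final = clone(make_estimator(cfg)).set_params(**best_params)
    final.fit(X, y)
    return ModelBundle(
        model=final,
        standardizer=standardizer,
        config=cfg,
        best_params=best_params,
        cv_score=best_score,
    )


def predict_scores(bundle: ModelBundle, X: np.ndarray) -> np.ndarray:
    """Class-score matrix aligned with ``bundle.model.classes_``.

    Probabilistic models report ``predict_proba``; margin-based models (SVM)
    report a softmax over the one-vs-rest decision function, so scores always
    form a row-stochastic matrix whose argmax matches ``predict``.
    """
    model = bundle.model
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)
        except AttributeError:
            pass
    margins = model.decision_function(X)
    margins = margins - margins.max(axis=1, keepdims=True)
    e = np.exp(margins)
    return e / e.sum(axis=1, keepdims=True)


def evaluate_on_validation(bundle: ModelBundle, validation: PatchMatrix) -> dict[str, Any]:
    """Sample-level validation metrics: macro one-vs-rest ROC-AUC plus
    per-class Dice and Jaccard computed on the label vectors (not images)."""
    from sklearn.metrics import roc_auc_score

    sub = validation.select_maps(bundle.feature_maps)
    if sub.features.shape[1] != bundle.standardizer.n_features:
        raise ValueError("validation feature dimensionality does not match the bundle")
    X = bundle.standardizer.transform(sub.features)
    y = sub.labels
    pred = bundle.model.predict(X)
    scores = predict_scores(bundle, X)
    auc = float(
        roc_auc_score(y, scores, multi_class="ovr", average="macro", labels=bundle.model.classes_)
    )
    per_class_dsc = {}
    per_class_ji = {}
    for cls in sorted(np.unique(y).tolist()):
        a, b = y == cls, pred == cls
        per_class_dsc[int(cls)] = _dsc(a, b)
        per_class_ji[int(cls)] = _jaccard(a, b)
    metrics = {
        "roc_auc_macro": auc,
        "accuracy": float((pred == y).mean()),
        "dsc": per_class_dsc,
        "ji": per_class_ji,
        "n_validation": int(len(y)),
    }
    bundle.metrics = metrics
    return metrics


def compare_feature_sets(
    train: PatchMatrix,
    validation: PatchMatrix,
    algorithm: str,
    seed: int = 0,
    **cfg_kwargs,
) -> dict[str, Any]:
    """Train one algorithm twice — two-map (DT, CBF) vs four-map — and
    report both validation metric records side by side.

    The two-map matrix is a column-block subset of the four-map matrix
    (taken inside :func:`tune_and_train`), never re-sampled.
    """
    out: dict[str, Any] = {"algorithm": algorithm}
    for feature_set in ("two_map", "four_map"):
        cfg = ModelConfig(algorithm=algorithm, feature_set=feature_set, seed=seed, **cfg_kwargs)
        bundle = tune_and_train(train, cfg)
        out[feature_set] = {
            "metrics": evaluate_on_validation(bundle, validation),
            "best_params": bundle.best_params,
            "bundle": bundle,
        }
    return out
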
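"""Versioned hyperparameter search spaces for the four classifier families.

Randomized search draws from ``RANDOM_SPACES``; the optional grid refinement
step builds a small grid (x0.5 / x1 / x2, clipped to the space bounds) around
the randomized-search optimum over the parameters listed in ``GRID_REFINE``.
Restricting refinement to the most influential numeric parameters keeps the
grid affordable while still narrowing the optimum.
"""

from __future__ import annotations

from scipy.stats import loguniform, randint, uniform

RANDOM_SPACES: dict[str, dict] = {
    "lr": {
        "C": loguniform(1e-3, 1e3),
    },
    "rf": {
        "n_estimators": randint(50, 301),
        "max_depth": [None, 4, 6, 8, 12, 16],
        "min_samples_split": randint(2, 11),
        "max_features": ["sqrt", "log2", None],
    },
    "xgb": {
        "n_estimators": randint(50, 301),
        "max_depth": randint(2, 9),
        "learning_rate": loguniform(0.01, 0.5),
        "subsample": uniform(0.6, 0.4),
    },
    # the SVM search covers linear and polynomial kernels only; C on the
    # conventional decade grid
    "svm": {
        "estimator__kernel": ["linear", "poly"],
        "estimator__C": [0.1, 1.0, 10.0, 100.0],
        "estimator__degree": [2, 3],
    },
}

#: numeric parameters refined by grid search around the randomized optimum
GRID_REFINE: dict[str, list[str]] = {
    "lr": ["C"],
    "rf": ["n_estimators", "min_samples_split"],
    "xgb": ["n_estimators", "learning_rate"],
    "svm": [],  # no grid refinement for SVM
}

#: hard bounds used when clipping refined grids (min, max) per parameter
BOUNDS: dict[str, tuple[float, float]] = {
    "C": (1e-3, 1e3),
    "n_estimators": (10, 500),
    "min_samples_split": (2, 20),
    "learning_rate": (0.005, 1.0),
}
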
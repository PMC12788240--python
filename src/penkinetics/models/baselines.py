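"""Grid-searched classical baselines on summary features.

Four supervised families are tuned by exhaustive grid search with 3-fold
stratified inner cross-validation, scoring by ROC AUC.  Features are z-score
standardized inside the pipeline so scaling statistics are always learned on
the training partition only (no leakage into validation or test folds).

Search spaces (fixed):

* Logistic Regression — C in {0.01, 0.1, 1, 10}, liblinear solver
* SVM (RBF kernel)    — C in {0.1, 1, 10}, gamma in {scale, auto}
* Random Forest       — n_estimators in {50, 100}, max_depth in {5, 10}
* k-NN                — k in {3, 5, 7, 9}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

BASELINE_FAMILIES = ("LR", "SVM", "RF", "kNN")

_GRIDS: Dict[str, dict] = {
    "LR": {"clf__C": [0.01, 0.1, 1, 10]},
    "SVM": {"clf__C": [0.1, 1, 10], "clf__gamma": ["scale", "auto"]},
    "RF": {"clf__n_estimators": [50, 100], "clf__max_depth": [5, 10]},
    "kNN": {"clf__n_neighbors": [3, 5, 7, 9]},
}


@dataclass
class BaselineSpec:
    """One baseline family plus its fixed hyperparameter search space."""

    family: str
    grid: Optional[dict] = None
    inner_cv_folds: int = 3

    def __post_init__(self) -> None:
        if self.family not in BASELINE_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {BASELINE_FAMILIES}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in _GRIDS[self.family].items()}

    @property
    def n_grid_cells(self) -> int:
        n = 1
        for values in self.grid.values():
            n *= len(values)
        return n


def _make_estimator(family: str, seed: int):
    if family == "LR":
        return LogisticRegression(solver="liblinear", random_state=seed)
    if family == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed)
    if family == "kNN":
        return KNeighborsClassifier()
    raise ValueError(family)


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> GridSearchCV:
    """Grid-search one baseline family and refit the best cell on all of X.

    ``y`` holds binary labels (1 = impaired class).  Returns the fitted
    ``GridSearchCV`` whose ``best_estimator_`` is a StandardScaler+classifier
    pipeline and whose ``best_params_`` names the selected grid cell.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fit_baseline requires both classes present")
    if counts.min() < 2:
        raise ValueError("fit_baseline requires >= 2 samples per class")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("clf", _make_estimator(spec.family, seed)),
    ])
    inner = StratifiedKFold(n_splits=spec.inner_cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, spec.grid, scoring="roc_auc", cv=inner, refit=True)
    search.fit(X, y)
    return search


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class scores from any fitted baseline.

    Uses ``predict_proba`` when available, else the decision function
    (SVM); either is a valid ROC score since AUC is invariant under
    monotone transforms.
    """
    est = getattr(model, "best_estimator_", model)
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)
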
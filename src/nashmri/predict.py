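"""Random-Forest prediction of histology from imaging features.

UDC signatures (optionally with mean RLE / FF) serve as feature vectors
for (a) stratified cross-validated classification of NASH vs simple
steatosis, returning out-of-fold class-probability scores, and (b)
cross-validated regression of each SAF component, whose out-of-fold
predictions feed low-vs-high-grade association t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from .stats import t_test

SAF_COMPONENTS = ("steatosis_grade", "inflammation", "ballooning", "fibrosis")

# Low/high dichotomization cuts: grades strictly below the cut are "low".
LOWHIGH_CUTS = {
    "steatosis_grade": 2,  # low = {0, 1}
    "fibrosis": 3,         # low = {0, 1, 2}
    "inflammation": 2,     # low = {0, 1}
    "ballooning": 2,       # low = {0, 1}
}


@dataclass
class PredictionResult:
    scores: np.ndarray      # out-of-fold probability (cls) or prediction (reg)
    fold_ids: np.ndarray
    n_folds: int
    seed: int
    target: str


def _as_matrix(features) -> np.ndarray:
    X = pd.DataFrame(features).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    return X


def cv_classify(
    features,
    labels,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> PredictionResult:
    """Stratified k-fold Random-Forest classification; every subject is
    scored exactly once out-of-fold with the positive-class probability."""
    X = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    if counts.min() < folds:
        raise ValueError(
            f"stratification error: smallest class ({counts.min()}) < folds ({folds})"
        )
    scores = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold)
        forest.fit(X[tr], y[tr])
        scores[te] = forest.predict_proba(X[te])[:, list(forest.classes_).index(1)]
        fold_ids[te] = fold
    assert not np.isnan(scores).any()
    return PredictionResult(scores=scores, fold_ids=fold_ids, n_folds=folds, seed=seed, target="nash")


def cv_regress_components(
    features,
    grades: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> dict[str, PredictionResult]:
    """One cross-validated Random-Forest regression per SAF component;
    returns out-of-fold continuous grade predictions per component."""
    X = _as_matrix(features)
    grades = pd.DataFrame(grades)
    if folds < 2 or len(grades) != len(X):
        raise ValueError("folds must be >= 2 and grades must align with features")
    results = {}
    for comp in SAF_COMPONENTS:
        y = grades[comp].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            raise ValueError(f"degenerate target: {comp} is constant")
        scores = np.full(len(y), np.nan)
        fold_ids = np.full(len(y), -1)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(splitter.split(X)):
            forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed + fold)
            forest.fit(X[tr], y[tr])
            scores[te] = forest.predict(X[te])
            fold_ids[te] = fold
        results[comp] = PredictionResult(
            scores=scores, fold_ids=fold_ids, n_folds=folds, seed=seed, target=comp
        )
    return results


def lowhigh_test(pred: PredictionResult, grades, component: str) -> float:
    """Two-sample pooled t-test of out-of-fold predictions between the
    low- and high-grade strata of the actual component grades."""
    if component not in LOWHIGH_CUTS:
        raise ValueError(f"unknown component {component!r}")
    g = pd.DataFrame(grades)[component].to_numpy()
    cut = LOWHIGH_CUTS[component]
    low, high = pred.scores[g < cut], pred.scores[g >= cut]
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"empty or singleton stratum for {component} at cut {cut} "
            f"(low n={len(low)}, high n={len(high)})"
        )
    return t_test(low, high)
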
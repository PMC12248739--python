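"""Gradient-boosted classifier construction and cross-validated F1 scoring.

Thin wrapper around :class:`xgboost.XGBClassifier` shared by the wrapper
feature-selection fitness and the hyperparameter-tuning fitness.  Everything
is single-threaded and seeded for reproducibility.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

#: XGBoost settings used whenever the caller does not tune them.
DEFAULT_PARAMS: dict = {"max_depth": 6, "learning_rate": 0.3, "n_estimators": 100}

#: Fixed wrapper-selection classifier: boosted stumps.  An additive model is
#: enough to rank candidate feature subsets here (the recurrence signal in
#: one-hot indicator data is additive in the indicators), and stumps are far
#: more robust to uninformative columns than deeper trees, so the wrapper
#: fitness varies little across masks that carry the same signal and the
#: feature-count penalty can act.
SELECTION_PARAMS: dict = {"max_depth": 1, "learning_rate": 0.3, "n_estimators": 100}


def build_classifier(params: Optional[dict] = None, seed: int = 0) -> XGBClassifier:
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    return XGBClassifier(
        max_depth=int(p["max_depth"]),
        learning_rate=float(p["learning_rate"]),
        n_estimators=int(p["n_estimators"]),
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        eval_metric="logloss",
    )


def cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    params: Optional[dict] = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold cross-validated F1 (mean, std) of the classifier.

    Fold assignment and the classifier's own randomness both derive from
    ``seed``.  A fold whose train or test part holds a single class is
    skipped with a warning; if every fold is degenerate the score is 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            logger.warning("skipping CV fold with a single class")
            continue
        clf = build_classifier(params, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        scores.append(f1_score(y[test_idx], pred, zero_division=0))
    if not scores:
        logger.warning("all CV folds degenerate; reporting F1 = 0")
        return 0.0, 0.0
    arr = np.asarray(scores)
    return float(arr.mean()), float(arr.std())
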
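"""Train/test experiment plumbing shared by the CLI and scripts."""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import model as _model
from .cohort import CategoricalCohort, one_hot_encode, stratified_split
from .metrics import EvaluationReport, evaluate_predictions
from .selection import FeatureMask, mask_columns


def evaluate_split(
    cohort: CategoricalCohort,
    params: Optional[dict] = None,
    mask: Optional[FeatureMask] = None,
    test_fraction: float = 0.25,
    seed: int = 0,
    model_label: str = "model",
) -> EvaluationReport:
    """Train on a stratified split, score the held-out part.

    ``params`` are decoded XGBoost hyperparameters (library defaults when
    None); ``mask`` optionally restricts the model to selected source
    features.  The split, fold-free training and prediction all derive from
    ``seed``.
    """
    train, test = stratified_split(cohort, test_fraction=test_fraction, seed=seed)
    names = cohort.schema.feature_names
    enc_train = one_hot_encode(train)
    enc_test = one_hot_encode(test)
    X_train, X_test = enc_train.matrix, enc_test.matrix
    if mask is not None:
        cols = mask_columns(mask, enc_train, names)
        X_train, X_test = X_train[:, cols], X_test[:, cols]
    clf = _model.build_classifier(params, seed=seed)
    clf.fit(X_train, train.target)
    pred = clf.predict(X_test)
    scores = clf.predict_proba(X_test)[:, 1]
    return evaluate_predictions(test.target, pred, scores=scores, model_label=model_label)
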
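"""Continuous WOA/MWOA search over the three key XGBoost hyperparameters.

The search box is max_depth ∈ [3, 10] (integer), learning_rate ∈ [0.01, 0.3]
(continuous), n_estimators ∈ [10, 200] (integer).  The optimizer works on raw
real triples; the classifier is always trained on the decoded (rounded)
values, and both are reported.  Fitness is 1 − meanF1 under stratified
k-fold cross-validation with fold assignment fixed per run, so candidate
configurations are compared on identical folds.  The library-default
configuration is injected as agent 0, which by elitism guarantees the tuned
result never scores below the baseline on its own folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import model as _model
from .cohort import CategoricalCohort, EncodedMatrix, one_hot_encode
from .core import OptimizationResult, SearchSpace, WOAConfig, optimize
from .mwoa import mwoa_optimize, pwlcm_init_population, xy0_from_seed
from .selection import VARIANTS, FeatureMask, mask_columns

logger = logging.getLogger(__name__)


def default_hyperparam_space() -> SearchSpace:
    """max_depth [3,10] (integer) × learning_rate [0.01,0.3] × n_estimators [10,200] (integer)."""
    return SearchSpace(
        lower=[3.0, 0.01, 10.0],
        upper=[10.0, 0.3, 200.0],
        codec=("integer", "continuous", "integer"),
    )


@dataclass
class TuningResult:
    raw_position: np.ndarray
    decoded: dict
    cv_f1_mean: float
    cv_f1_std: float
    history: np.ndarray
    seed: int
    variant: str
    default_cv_f1_mean: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(
            {
                "raw_position": [float(v) for v in self.raw_position],
                "decoded": self.decoded,
                "cv_f1_mean": self.cv_f1_mean,
                "cv_f1_std": self.cv_f1_std,
                "default_cv_f1_mean": self.default_cv_f1_mean,
                "history": [float(h) for h in self.history],
                "seed": self.seed,
                "variant": self.variant,
            },
            indent=2,
        )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def decode_hyperparams(raw, space: Optional[SearchSpace] = None) -> dict:
    """Raw triple → trainable hyperparameters.

    Integer dimensions are rounded half away from zero and floored at 1;
    learning_rate passes through.  Out-of-bounds raws are clipped first with
    a warning.
    """
    if space is None:
        space = default_hyperparam_space()
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (3,):
        raise ValueError("expected a raw triple (max_depth, learning_rate, n_estimators)")
    if np.any(raw < space.lower) or np.any(raw > space.upper):
        logger.warning("raw hyperparameters %s outside bounds; clipping", raw)
        raw = np.clip(raw, space.lower, space.upper)
    return {
        "max_depth": max(1, _round_half_away(raw[0])),
        "learning_rate": float(raw[1]),
        "n_estimators": max(1, _round_half_away(raw[2])),
    }


def tuning_fitness(
    raw,
    encoded: EncodedMatrix,
    y: np.ndarray,
    cv_folds: int = 5,
    sub_seed: int = 0,
    columns: Optional[np.ndarray] = None,
) -> float:
    """1 − mean CV F1 of the classifier built from the decoded triple."""
    params = decode_hyperparams(raw)
    X = encoded.matrix if columns is None else encoded.matrix[:, columns]
    mean_f1, _ = _model.cv_f1(X, y, params=params, cv_folds=cv_folds, seed=sub_seed)
    return 1.0 - mean_f1


def tune(
    cohort: CategoricalCohort,
    variant: str = "mwoa",
    opt_cfg: Optional[WOAConfig] = None,
    space: Optional[SearchSpace] = None,
    cv_folds: int = 5,
    mask: Optional[FeatureMask] = None,
) -> TuningResult:
    """Optimize the hyperparameter triple on the (optionally masked) cohort.

    ``mask`` restricts the classifier to the one-hot columns of the selected
    source features, mirroring tuning-on-selected-features experiments;
    default is all features.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    opt_cfg = opt_cfg or WOAConfig(n_agents=10, n_iters=15)
    opt_cfg.validate()
    if space is None:
        space = default_hyperparam_space()
    encoded = one_hot_encode(cohort)
    y = cohort.target
    columns = None
    if mask is not None:
        columns = mask_columns(mask, encoded, cohort.schema.feature_names)
    sub_seed = int(opt_cfg.seed) % (2**31)
    cache: dict[tuple, float] = {}

    def fitness(raw: np.ndarray) -> float:
        key = tuple(decode_hyperparams(raw).values())
        if key not in cache:
            cache[key] = tuning_fitness(
                raw, encoded, y, cv_folds=cv_folds, sub_seed=sub_seed, columns=columns
            )
        return cache[key]

    default_vec = np.array(
        [
            _model.DEFAULT_PARAMS["max_depth"],
            _model.DEFAULT_PARAMS["learning_rate"],
            _model.DEFAULT_PARAMS["n_estimators"],
        ],
        dtype=float,
    )
    # baseline injected as agent 0 so the tuned optimum can never trail it
    if variant == "woa":
        init_rng = np.random.default_rng([opt_cfg.seed, 1])
        init = init_rng.uniform(space.lower, space.upper, size=(opt_cfg.n_agents, space.n_dims))
        init[0] = np.clip(default_vec, space.lower, space.upper)
        res = optimize(space, fitness, opt_cfg, init_positions=init)
    else:
        init = pwlcm_init_population(
            opt_cfg.n_agents, space, xy0=xy0_from_seed(opt_cfg.seed)
        )
        init[0] = np.clip(default_vec, space.lower, space.upper)
        res = mwoa_optimize(space, fitness, opt_cfg, init_positions=init)
    decoded = decode_hyperparams(res.best_position, space)
    X = encoded.matrix if columns is None else encoded.matrix[:, columns]
    mean_f1, std_f1 = _model.cv_f1(X, y, params=decoded, cv_folds=cv_folds, seed=sub_seed)
    default_f1, _ = _model.cv_f1(
        X, y, params=dict(_model.DEFAULT_PARAMS), cv_folds=cv_folds, seed=sub_seed
    )
    return TuningResult(
        raw_position=res.best_position,
        decoded=decoded,
        cv_f1_mean=mean_f1,
        cv_f1_std=std_f1,
        history=res.history,
        seed=opt_cfg.seed,
        variant=variant,
        default_cv_f1_mean=default_f1,
    )
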
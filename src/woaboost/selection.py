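"""Binary-encoded wrapper feature selection driven by WOA / MWOA.

Whales live in the continuous unit hypercube [0,1]^d (one dimension per
source feature, d = 16 for the DTC schema) and are thresholded at 0.5 into
feature masks at evaluation time.  A mask's fitness is a convex combination
of the classifier's cross-validated F1 shortfall and the selected-feature
fraction,

    fitness = alpha · (1 − meanF1_cv) + beta_penalty · (k / d),

minimized, so the search favors small masks that classify well.  Masks act
on *source* features: a feature's whole one-hot indicator group is kept or
dropped atomically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import model as _model
from .cohort import CategoricalCohort, EncodedMatrix, one_hot_encode
from .core import OptimizationResult, SearchSpace, WOAConfig, optimize
from .mwoa import InertiaSchedule, mwoa_optimize, pwlcm_iterates, xy0_from_seed

VARIANTS = ("woa", "mwoa")


@dataclass(frozen=True)
class FeatureMask:
    """Binary vector over source features; at least one bit always set."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0/1")
        if sum(self.bits) == 0:
            raise ValueError("mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return sum(self.bits)

    @property
    def selected_indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class SelectionFitnessConfig:
    """Weights and CV settings of the penalized selection fitness.

    ``alpha`` weighs the classification-error term, ``beta_penalty`` the
    selected-feature fraction; they must form a convex combination.  The
    classifier used inside the wrapper is fixed (not co-tuned).
    """

    alpha: float = 0.99
    beta_penalty: float = 0.01
    cv_folds: int = 5
    model_config: dict = field(default_factory=lambda: dict(_model.SELECTION_PARAMS))

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta_penalty < 0:
            raise ValueError("alpha and beta_penalty must be non-negative")
        if abs(self.alpha + self.beta_penalty - 1.0) > 1e-9:
            raise ValueError("alpha + beta_penalty must equal 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass
class SelectionResult:
    mask: FeatureMask
    feature_names: list[str]
    fitness: float
    cv_f1_mean: float
    cv_f1_std: float
    history: np.ndarray
    seed: int
    variant: str

    @property
    def selected_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.mask.selected_indices]

    def to_json(self) -> str:
        k, d = self.mask.n_selected, len(self.mask)
        return json.dumps(
            {
                "bits": list(self.mask.bits),
                "selected_indices_1based": [i + 1 for i in self.mask.selected_indices],
                "selected_features": self.selected_names,
                "fitness": self.fitness,
                "fitness_decomposition": {
                    "f1_term": 1.0 - self.cv_f1_mean,
                    "penalty_term": k / d,
                },
                "cv_f1_mean": self.cv_f1_mean,
                "cv_f1_std": self.cv_f1_std,
                "history": [float(h) for h in self.history],
                "seed": self.seed,
                "variant": self.variant,
            },
            indent=2,
        )


def binarize_position(X: np.ndarray, threshold: float = 0.5) -> FeatureMask:
    """Threshold a continuous position in [0,1]^d into a mask.

    Bit i is set iff X[i] > threshold.  An all-zero result is repaired by
    setting the bit with the largest component, keeping the search space
    connected instead of assigning a penalty fitness.
    """
    X = np.asarray(X, dtype=float)
    bits = (X > threshold).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(X))] = 1
    return FeatureMask(bits=tuple(int(b) for b in bits))


def mask_to_feature_indices(mask: FeatureMask, one_based: bool = True) -> tuple[int, ...]:
    """Set-bit positions; 1-based by convention (feature 1 is the first)."""
    off = 1 if one_based else 0
    return tuple(i + off for i in mask.selected_indices)


def initial_selection_positions(
    n_agents: int, d: int, seed: int, beta: float = 0.4, burn_in: int = 100
) -> np.ndarray:
    """Chaotic-map initial whale positions with non-overlapping initial masks.

    The selection procedure seeds the population so that no two whales start
    with the same feature switched on: a chaotic permutation deals the d
    source features round-robin to the n agents, and each agent's position is
    placed above the 0.5 threshold only on its dealt features (off-bits in
    (0.35, 0.475), on-bits in (0.525, 0.70), magnitudes from the chaotic
    orbit).  Starting sparse and disjoint gives the penalized search small
    incumbent masks to refine instead of dense random ones, and the union of
    the initial masks still covers every feature.  Components start close to
    the threshold on purpose: the whale updates perturb a coordinate in
    proportion to position-difference terms, so a bit parked near 0 or 1 is
    practically unrecoverable, while a bit hovering near 0.5 can be switched
    in either direction throughout the run.  Deterministic given seed.
    """
    raw = pwlcm_iterates(xy0_from_seed(seed), beta, d + n_agents * d, burn_in=burn_in)
    perm = np.argsort(raw[:d], kind="stable")  # chaotic feature permutation
    vals = raw[d:].reshape(n_agents, d)
    pos = 0.35 + vals * 0.125
    for j, feat in enumerate(perm):
        agent = j % n_agents
        pos[agent, feat] = 0.525 + vals[agent, feat] * 0.175
    return pos


def mask_columns(mask: FeatureMask, encoded: EncodedMatrix, feature_names: list[str]) -> np.ndarray:
    """One-hot column indices covered by the mask's selected source features."""
    cols: list[int] = []
    for i in mask.selected_indices:
        cols.extend(encoded.feature_column_indices(feature_names[i]))
    return np.asarray(cols, dtype=int)


def selection_fitness(
    mask: FeatureMask,
    encoded: EncodedMatrix,
    y: np.ndarray,
    feature_names: list[str],
    cfg: SelectionFitnessConfig,
    sub_seed: int = 0,
) -> float:
    """Penalized CV-F1 fitness of one mask (lower is better)."""
    cols = mask_columns(mask, encoded, feature_names)
    mean_f1, _ = _model.cv_f1(
        encoded.matrix[:, cols], y, params=cfg.model_config,
        cv_folds=cfg.cv_folds, seed=sub_seed,
    )
    k, d = mask.n_selected, len(mask)
    return cfg.alpha * (1.0 - mean_f1) + cfg.beta_penalty * (k / d)


def select_features(
    cohort: CategoricalCohort,
    variant: str = "mwoa",
    opt_cfg: Optional[WOAConfig] = None,
    sel_cfg: Optional[SelectionFitnessConfig] = None,
) -> SelectionResult:
    """Run WOA/MWOA wrapper selection and return the best mask with its trace.

    The CV fold assignment (one sub-seed per run, derived from the optimizer
    seed) is shared by every fitness evaluation, so masks are compared on
    identical folds; repeated masks are served from a cache.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    opt_cfg = opt_cfg or WOAConfig()
    sel_cfg = sel_cfg or SelectionFitnessConfig()
    feature_names = cohort.schema.feature_names
    d = len(feature_names)
    if d < 2:
        raise ValueError("need at least 2 source features to select from")
    encoded = one_hot_encode(cohort)
    y = cohort.target
    sub_seed = int(opt_cfg.seed) % (2**31)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(X: np.ndarray) -> float:
        mask = binarize_position(X)
        if mask.bits not in cache:
            cache[mask.bits] = selection_fitness(
                mask, encoded, y, feature_names, sel_cfg, sub_seed=sub_seed
            )
        return cache[mask.bits]

    space = SearchSpace.unit_hypercube(d, codec="binary")
    init = initial_selection_positions(opt_cfg.n_agents, d, opt_cfg.seed)
    if variant == "woa":
        res = optimize(space, fitness, opt_cfg, init_positions=init)
    else:
        res = mwoa_optimize(space, fitness, opt_cfg, init_positions=init)
    best_mask = binarize_position(res.best_position)
    cols = mask_columns(best_mask, encoded, feature_names)
    mean_f1, std_f1 = _model.cv_f1(
        encoded.matrix[:, cols], y, params=sel_cfg.model_config,
        cv_folds=sel_cfg.cv_folds, seed=sub_seed,
    )
    return SelectionResult(
        mask=best_mask,
        feature_names=feature_names,
        fitness=res.best_fitness,
        cv_f1_mean=mean_f1,
        cv_f1_std=std_f1,
        history=res.history,
        seed=opt_cfg.seed,
        variant=variant,
    )
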
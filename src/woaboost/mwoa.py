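"""Modified WOA: cosine inertia weight and chaotic-map initialization.

Two changes to the basic optimizer:

1. the encircling move becomes ``w·X + C∘(X* − X)`` with an inertia weight
   ``w(t) = cos(nπ t / t_max)`` — large early (broad search), small late
   (local refinement);
2. the initial population is harvested from a piecewise linear chaotic map
   (PWLCM) instead of uniform draws, giving a deterministic, well-spread,
   low-discrepancy-like start.

The spiral and exploration branches, elitism, clipping and seeding contracts
are inherited unchanged from :mod:`woaboost.core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Optional

import numpy as np

from .core import (
    FitnessFn,
    OptimizationResult,
    SearchSpace,
    WOAConfig,
    _run_loop,
)

_EPS = 1e-10


@dataclass(frozen=True)
class InertiaSchedule:
    """Cosine inertia schedule w(t) = cos(n·π·t / t_max).

    ``n`` sets the oscillation frequency.  The default n = 0.5 sweeps w from
    1 down to 0 over the run, keeping the self-term non-negative; n = 1 runs
    the full cosine into negative weights (as printed, self-term reversed in
    the second half).
    """

    t_max: int
    n: float = 0.5

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.n <= 0:
            raise ValueError("oscillation constant n must be positive")


def inertia_weight(t: float, sched: InertiaSchedule) -> float:
    if not 0 <= t <= sched.t_max:
        raise ValueError(f"iteration t={t} outside [0, {sched.t_max}]")
    return math.cos(sched.n * math.pi * t / sched.t_max)


@dataclass
class PWLCMState:
    """State of the piecewise linear chaotic map on (0, 1).

    ``beta`` is the control parameter in (0, 0.5); ``xy`` the current orbit
    value.  Boundary outputs {0, 1} are perturbed by 1e-10 so the orbit never
    leaves the open interval.
    """

    xy: float
    beta: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 0.5:
            raise ValueError("beta must lie strictly in (0, 0.5)")
        if not 0.0 < self.xy < 1.0:
            raise ValueError("xy must lie strictly in (0, 1)")


def _pwlcm_half(y: float, beta: float) -> float:
    # Lower two branches of the map, defined on (0, 0.5); inputs at the
    # domain edge (y == 0.5 arises from xy == 0.5 via the mirror branch)
    # are nudged inside.
    if y >= 0.5:
        y = 0.5 - _EPS
    if y <= 0.0:
        y = _EPS
    if y < beta:
        out = y / beta
    else:
        out = (y - beta) / (0.5 - beta)
    if out <= 0.0:
        out = _EPS
    elif out >= 1.0:
        out = 1.0 - _EPS
    return out


def _pwlcm_value(xy: float, beta: float) -> float:
    if xy < 0.5:
        return _pwlcm_half(xy, beta)
    # mirror branch: apply the lower branches to (1 - xy)
    return _pwlcm_half(1.0 - xy, beta)


def pwlcm_next(state: PWLCMState) -> PWLCMState:
    """One application of the three-branch PWLCM.

    xy′ = xy/β on (0, β); xy′ = (xy − β)/(0.5 − β) on [β, 0.5); on [0.5, 1)
    the same map is applied to (1 − xy).  Degenerate outputs {0, 1} are
    perturbed by 1e-10.
    """
    if not 0.0 < state.xy < 1.0:
        raise ValueError("chaotic state escaped (0, 1)")
    return PWLCMState(xy=_pwlcm_value(state.xy, state.beta), beta=state.beta)


def xy0_from_seed(seed: int) -> float:
    """Fixed Knuth-style hash of the run seed onto (0, 1)."""
    h = (int(seed) * 2654435761) % (2**32)
    return (h + 0.5) / 2**32


def pwlcm_iterates(xy0: float, beta: float, count: int, burn_in: int = 0) -> np.ndarray:
    """Burn in the map, then return ``count`` successive orbit values.

    A value mapping onto itself (a period-1 cycle, e.g. an orbit collapsing
    onto a fixed point through floating-point rounding) is perturbed so the
    stream never stalls.
    """
    if not 0.0 < xy0 < 1.0:
        raise ValueError("xy0 must lie strictly in (0, 1)")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    xy = xy0
    out = np.empty(count)
    total = burn_in + count
    for k in range(total):
        nxt = _pwlcm_value(xy, beta)
        if nxt == xy:  # fixed cycle of length 1: kick the orbit
            nxt = _pwlcm_value(min(max(xy + 1e-7, _EPS), 1.0 - _EPS), beta)
        xy = nxt
        if k >= burn_in:
            out[k - burn_in] = xy
    return out


def pwlcm_init_population(
    n_agents: int,
    space: SearchSpace,
    beta: float = 0.4,
    xy0: float = 0.7,
    burn_in: int = 100,
) -> np.ndarray:
    """Chaotic initial positions: one map orbit reshaped to (n_agents, n_dims).

    Raw orbit values in (0, 1) are scaled affinely onto the per-dimension
    bounds.  Fully deterministic given (xy0, beta, burn_in).
    """
    PWLCMState(xy=xy0, beta=beta)  # validates both
    raw = pwlcm_iterates(xy0, beta, n_agents * space.n_dims, burn_in=burn_in)
    grid = raw.reshape(n_agents, space.n_dims)
    return space.lower + grid * (space.upper - space.lower)


def mwoa_encircle_update(
    X: np.ndarray, X_star: np.ndarray, C: np.ndarray, w: float
) -> np.ndarray:
    """Inertia-weighted encircle: w·X + C∘(X* − X), as printed (no |·|, no A)."""
    X = np.asarray(X, dtype=float)
    X_star = np.asarray(X_star, dtype=float)
    C = np.asarray(C, dtype=float)
    if not (X.shape == X_star.shape == C.shape):
        raise ValueError("position/coefficient vectors must share one length")
    return w * X + C * (X_star - X)


def mwoa_optimize(
    space: SearchSpace,
    fitness_fn: FitnessFn,
    cfg: WOAConfig,
    sched: Optional[InertiaSchedule] = None,
    beta: float = 0.4,
    xy0: Optional[float] = None,
    burn_in: int = 100,
    init_positions: Optional[np.ndarray] = None,
    trace: Optional[IO[str]] = None,
) -> OptimizationResult:
    """Run the modified WOA.

    Same loop as :func:`woaboost.core.optimize` except the initial population
    comes from the PWLCM (``xy0`` defaults to a fixed hash of the seed) and
    the encircling branch applies the inertia-weighted update with
    w = cos(nπt/t_max).  ``init_positions`` overrides the chaotic start (used
    e.g. to inject a baseline agent).
    """
    cfg.validate()
    if sched is None:
        sched = InertiaSchedule(t_max=cfg.n_iters)
    if sched.t_max != cfg.n_iters:
        raise ValueError("inertia schedule t_max must equal cfg.n_iters")
    if xy0 is None:
        xy0 = xy0_from_seed(cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    if init_positions is None:
        init = pwlcm_init_population(cfg.n_agents, space, beta=beta, xy0=xy0, burn_in=burn_in)
    else:
        init = np.clip(np.array(init_positions, dtype=float), space.lower, space.upper)
        if init.shape != (cfg.n_agents, space.n_dims):
            raise ValueError(
                f"init_positions must have shape {(cfg.n_agents, space.n_dims)}"
            )

    def rule_for_t(t: int):
        w = inertia_weight(t, sched)
        return lambda X, X_star, A, C: mwoa_encircle_update(X, X_star, C, w)

    return _run_loop(
        space,
        fitness_fn,
        cfg,
        init,
        rng,
        encircle_rule_for_t=rule_for_t,
        trace=trace,
        trace_extra=lambda t: {"w": inertia_weight(t, sched)},
    )
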
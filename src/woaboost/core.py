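"""Whale optimization algorithm (WOA) as a seeded, bounded minimizer.

The WOA is a population metaheuristic modelled on the bubble-net hunting of
humpback whales.  Each search agent (whale) holds a position ``X`` in a box;
per iteration every agent either

* *encircles* the incumbent best ``X*`` (shrinking-circle exploitation),
* performs a logarithmic *spiral* move around ``X*`` (bubble-net attack), or
* *explores* toward a randomly chosen agent (global search),

with the branch picked by a uniform draw ``p`` and by the magnitude of the
coefficient vector ``A``.  The control scalar ``a`` decays linearly from 2 to
0 over the run, shifting the population from exploration to exploitation.

All randomness flows through a single :class:`numpy.random.Generator`, so a
run is bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, IO, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

FitnessFn = Callable[[np.ndarray], float]

CODECS = ("continuous", "integer", "binary")


@dataclass(frozen=True)
class SearchSpace:
    """A box search domain with per-dimension decoding tags.

    ``codec`` tags how each dimension is interpreted downstream
    (``continuous`` pass-through, ``integer`` rounded, ``binary``
    thresholded); the optimizer itself always works on real vectors.
    """

    lower: np.ndarray
    upper: np.ndarray
    codec: tuple[str, ...]

    def __init__(self, lower, upper, codec: Optional[Sequence[str]] = None):
        lower = np.atleast_1d(np.asarray(lower, dtype=float))
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-d arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("need lower[i] < upper[i] for every dimension")
        if codec is None:
            codec = ("continuous",) * lower.size
        codec = tuple(codec)
        if len(codec) != lower.size:
            raise ValueError("codec length must match dimensionality")
        for i, c in enumerate(codec):
            if c not in CODECS:
                raise ValueError(f"unknown codec {c!r} at dimension {i}")
            if c == "binary" and not (lower[i] == 0.0 and upper[i] == 1.0):
                raise ValueError(f"binary dimension {i} must have bounds [0, 1]")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "codec", codec)

    @property
    def n_dims(self) -> int:
        return self.lower.size

    @classmethod
    def unit_hypercube(cls, n_dims: int, codec: str = "continuous") -> "SearchSpace":
        return cls(np.zeros(n_dims), np.ones(n_dims), (codec,) * n_dims)


@dataclass
class WOAConfig:
    """Run parameters for :func:`optimize`.

    ``spiral_b`` is the logarithmic-spiral shape constant ``b``;
    ``branch_prob`` is the threshold on ``p`` that switches between the
    encircle/explore pair and the spiral move; ``literal_equations`` swaps the
    standard exploration update for the as-printed variant that multiplies the
    distance term by the agent's own position instead of ``A`` (ablation only).
    """

    n_agents: int = 20
    n_iters: int = 50
    spiral_b: float = 1.0
    branch_prob: float = 0.5
    seed: int = 0
    literal_equations: bool = False
    patience: Optional[int] = None  # early stop after this many stagnant iterations

    def validate(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.n_iters < 1:
            raise ValueError("n_iters must be at least 1")
        if not 0.0 < self.branch_prob < 1.0:
            raise ValueError("branch_prob must lie strictly in (0, 1)")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be positive when set")


@dataclass
class Population:
    """Whale positions with cached fitness and the elitist incumbent best."""

    positions: np.ndarray          # (n_agents, n_dims)
    fitness: np.ndarray            # (n_agents,)
    best_position: np.ndarray      # (n_dims,)
    best_fitness: float
    n_evals: int = 0

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray            # per-iteration incumbent best, non-increasing
    n_evals: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "history": [float(v) for v in self.history],
            "n_evals": int(self.n_evals),
            "seed": int(self.seed),
        }


def linear_decay_a(t: float, t_max: int) -> float:
    """Control scalar ``a``: linear decay from 2 at t=0 to 0 at t=t_max."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return 2.0 * (1.0 - t / t_max)


def draw_coefficients(
    a: float, rng: np.random.Generator, n_dims: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Draw per-iteration coefficients (A, C, l, p).

    A = 2a·r − a with r ~ U[0,1]^d (so A ∈ [−a, a]); C = 2·r′ with an
    independent r′ (C ∈ [0, 2]); l ~ U[−1,1] parameterizes the spiral;
    p ~ U[0,1] selects the update branch.
    """
    r = rng.uniform(size=n_dims)
    A = 2.0 * a * r - a
    C = 2.0 * rng.uniform(size=n_dims)
    l = float(rng.uniform(-1.0, 1.0))
    p = float(rng.uniform())
    return A, C, l, p


def _check_same_length(*vecs: np.ndarray) -> None:
    n = {np.asarray(v).shape for v in vecs}
    if len(n) != 1:
        raise ValueError("position/coefficient vectors must share one length")


def encircle_update(
    X: np.ndarray, X_star: np.ndarray, A: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Shrinking-encircle move toward the incumbent best.

    D = |C∘X* − X| componentwise; next position is X* − A∘D.
    """
    _check_same_length(X, X_star, A, C)
    D = np.abs(C * X_star - X)
    return X_star - A * D


def spiral_update(X: np.ndarray, X_star: np.ndarray, b: float, l: float) -> np.ndarray:
    """Logarithmic-spiral (bubble-net) move around the incumbent best.

    D′ = |X* − X|; next position is D′·e^{bl}·cos(2πl) + X*.
    """
    D_prime = np.abs(X_star - X)
    return D_prime * np.exp(b * l) * np.cos(2.0 * np.pi * l) + X_star


def exploration_update(
    X: np.ndarray,
    X_rand: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    literal_equations: bool = False,
) -> np.ndarray:
    """Global-search move toward a random agent.

    D = |C∘X_rand − X|.  Default is the standard form X_rand − A∘D; with
    ``literal_equations`` the distance is scaled by the agent's own position
    (X_rand − X∘D), exposed for ablation of the as-printed update.
    """
    _check_same_length(X, X_rand, A, C)
    D = np.abs(C * X_rand - X)
    mult = X if literal_equations else A
    return X_rand - mult * D


def clip_to_bounds(X: np.ndarray, space: SearchSpace) -> np.ndarray:
    return np.clip(X, space.lower, space.upper)


EncircleRule = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _evaluate_initial(
    positions: np.ndarray, fitness_fn: FitnessFn
) -> Population:
    fitness = np.empty(positions.shape[0])
    for i in range(positions.shape[0]):
        f = float(fitness_fn(positions[i]))
        if not np.isfinite(f):
            logger.warning("non-finite fitness at initial agent %d; treated as +inf", i)
            f = np.inf
        fitness[i] = f
    best_i = int(np.argmin(fitness))  # lowest index wins ties
    if not np.isfinite(fitness[best_i]):
        raise ValueError("every initial agent returned non-finite fitness")
    return Population(
        positions=positions,
        fitness=fitness,
        best_position=positions[best_i].copy(),
        best_fitness=float(fitness[best_i]),
        n_evals=positions.shape[0],
    )


def woa_step(
    pop: Population,
    t: int,
    cfg: WOAConfig,
    space: SearchSpace,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    encircle_rule: Optional[EncircleRule] = None,
) -> Population:
    """One synchronous sweep over all agents, updated sequentially in place.

    The random partner for the exploration branch is drawn from the live
    population, so agents updated earlier in the sweep can be chosen.  The
    incumbent best is replaced only on strict improvement; a candidate whose
    fitness is non-finite is rejected and the agent keeps its position.
    """
    a = linear_decay_a(t, cfg.n_iters)
    n = len(pop)
    for i in range(n):
        A, C, l, p = draw_coefficients(a, rng, space.n_dims)
        X = pop.positions[i]
        if p >= cfg.branch_prob:
            cand = spiral_update(X, pop.best_position, cfg.spiral_b, l)
        elif abs(float(A[0])) < 1.0:
            # branch on a single component of A: it has the U[-a, a] law of
            # the canonical scalar coefficient, so exploration fires with
            # probability (a-1)/a while a > 1 and never afterwards.  A
            # whole-vector reduction such as mean(|A|) concentrates at a/2 by
            # averaging and would shut exploration off after the first sweep,
            # collapsing population diversity.
            rule = encircle_rule if encircle_rule is not None else encircle_update
            cand = rule(X, pop.best_position, A, C)
        else:
            j = int(rng.integers(n))
            cand = exploration_update(
                X, pop.positions[j], A, C, cfg.literal_equations
            )
        cand = clip_to_bounds(cand, space)
        f = float(fitness_fn(cand))
        pop.n_evals += 1
        if not np.isfinite(f):
            logger.warning("non-finite fitness for agent %d at t=%d; move rejected", i, t)
            continue
        pop.positions[i] = cand
        pop.fitness[i] = f
        if f < pop.best_fitness:
            pop.best_fitness = f
            pop.best_position = cand.copy()
    return pop


def _run_loop(
    space: SearchSpace,
    fitness_fn: FitnessFn,
    cfg: WOAConfig,
    init_positions: np.ndarray,
    rng: np.random.Generator,
    encircle_rule_for_t: Optional[Callable[[int], Optional[EncircleRule]]] = None,
    trace: Optional[IO[str]] = None,
    trace_extra: Optional[Callable[[int], dict]] = None,
) -> OptimizationResult:
    pop = _evaluate_initial(np.array(init_positions, dtype=float), fitness_fn)
    history: list[float] = []
    stagnant = 0
    for t in range(cfg.n_iters):
        prev_best = pop.best_fitness
        rule = encircle_rule_for_t(t) if encircle_rule_for_t is not None else None
        woa_step(pop, t, cfg, space, fitness_fn, rng, encircle_rule=rule)
        history.append(pop.best_fitness)
        if trace is not None:
            rec = {"t": t, "best_fitness": pop.best_fitness, "a": linear_decay_a(t, cfg.n_iters)}
            if trace_extra is not None:
                rec.update(trace_extra(t))
            trace.write(json.dumps(rec) + "\n")
        if cfg.patience is not None:
            stagnant = stagnant + 1 if pop.best_fitness >= prev_best else 0
            if stagnant >= cfg.patience:
                break
    return OptimizationResult(
        best_position=pop.best_position,
        best_fitness=pop.best_fitness,
        history=np.asarray(history),
        n_evals=pop.n_evals,
        seed=cfg.seed,
    )


def optimize(
    space: SearchSpace,
    fitness_fn: FitnessFn,
    cfg: WOAConfig,
    init_positions: Optional[np.ndarray] = None,
    trace: Optional[IO[str]] = None,
) -> OptimizationResult:
    """Run the basic WOA and return the elitist optimum with its trace.

    ``init_positions`` overrides the default uniform-random initialization
    (rows are clipped into the box).  Identical ``cfg`` (including seed) and
    identical inputs reproduce the result bit for bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if init_positions is None:
        init = rng.uniform(space.lower, space.upper, size=(cfg.n_agents, space.n_dims))
    else:
        init = np.array(init_positions, dtype=float)
        if init.shape != (cfg.n_agents, space.n_dims):
            raise ValueError(
                f"init_positions must have shape {(cfg.n_agents, space.n_dims)}"
            )
        init = np.clip(init, space.lower, space.upper)
    return _run_loop(space, fitness_fn, cfg, init, rng, trace=trace)
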
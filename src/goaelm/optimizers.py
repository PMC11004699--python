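"""Grasshopper Optimization Algorithm (GOA) and its Amended variant (AGOA).

GOA is a swarm metaheuristic in which agents ("grasshoppers") attract and
repel one another through a social-force kernel and drift toward the best
position found so far.  A comfort-zone coefficient ``c`` shrinks linearly
over iterations, shifting the swarm from exploration to exploitation.

AGOA adds two amendments aimed at premature convergence:

* **chaotic r-streams** — three scalars iterated through the singer map
  replace uniform random draws; ``r1`` scales the social-interaction term,
  ``r2`` the target-attraction term, and ``r3`` supplies the uniform
  fraction of the quasi-opposition draw;
* **quasi-opposition-based learning (QOBL)** — each updated agent is
  compared against a point drawn uniformly between the box centre and its
  reflection through the centre; the fitter of the two survives.

All optimization is minimization over a box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "BoxBounds",
    "OptimizerConfig",
    "ChaoticStreams",
    "SearchPopulation",
    "OptimizationResult",
    "social_force",
    "comfort_coefficient",
    "singer_step",
    "opposite_point",
    "quasi_opposite_point",
    "goa_position_update",
    "qobl_select",
    "optimize",
    "goa_config",
    "agoa_config",
]

# singer map leaves (0,1) only marginally; exact 0 after the mod-1 fold is
# remapped to this constant so streams stay strictly interior
_SINGER_FLOOR = 1e-6


@dataclass(frozen=True)
class BoxBounds:
    """Axis-aligned search box with strict ``lower < upper`` per dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def cube(cls, low: float, high: float, dimension: int) -> "BoxBounds":
        return cls(np.full(dimension, low), np.full(dimension, high))

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 1e-12) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs shared by GOA and AGOA.

    ``attraction_intensity`` (f) and ``attraction_length_scale`` (l) shape
    the social-force kernel ``s(d) = f e^(-d/l) - e^(-d)``; the defaults
    0.5 / 1.5 are the values used throughout the GOA literature.  Gravity
    and wind are retained as optional constants but default to zero: the
    working position-update equation omits them.
    """

    population_size: int = 50
    max_iterations: int = 100
    c_max: float = 1.0
    c_min: float = 0.01
    attraction_intensity: float = 0.5
    attraction_length_scale: float = 1.5
    gravity_constant: float = 0.0
    wind_strength: float = 0.0
    use_chaos: bool = False
    use_qobl: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if not (0.0 < self.c_min < self.c_max):
            raise ValueError("require 0 < c_min < c_max")
        if self.attraction_length_scale <= 0:
            raise ValueError("attraction_length_scale must be positive")


def goa_config(**overrides) -> OptimizerConfig:
    """Baseline GOA configuration (no chaos, no QOBL)."""
    return OptimizerConfig(use_chaos=False, use_qobl=False, **overrides)


def agoa_config(**overrides) -> OptimizerConfig:
    """Amended GOA configuration (singer chaos + quasi-opposition)."""
    return OptimizerConfig(use_chaos=True, use_qobl=True, **overrides)


@dataclass
class ChaoticStreams:
    """Three scalar chaotic states on (0,1) advanced by the singer map."""

    r1: float
    r2: float
    r3: float

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "r3"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly inside (0,1), got {v}")

    @classmethod
    def from_rng(cls, rng: np.random.Generator) -> "ChaoticStreams":
        draw = lambda: float(np.clip(rng.random(), _SINGER_FLOOR, 1 - _SINGER_FLOOR))
        return cls(draw(), draw(), draw())

    def advance(self) -> None:
        self.r1 = singer_step(self.r1)
        self.r2 = singer_step(self.r2)
        self.r3 = singer_step(self.r3)


@dataclass
class SearchPopulation:
    positions: np.ndarray          # (N, D)
    fitness: np.ndarray            # (N,)
    target_position: np.ndarray    # (D,)
    target_fitness: float


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    convergence_history: np.ndarray   # length L+1, best-so-far per iteration
    evaluations_used: int


def social_force(
    distance: Union[float, np.ndarray], config: OptimizerConfig
) -> Union[float, np.ndarray]:
    """Social-force kernel s(d) = f·exp(-d/l) - exp(-d).

    Positive values attract, negative repel; the kernel vanishes for large
    separations, which is why the comfort coefficient rescales distances.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    f = config.attraction_intensity
    l = config.attraction_length_scale
    out = f * np.exp(-d / l) - np.exp(-d)
    return float(out) if np.isscalar(distance) else out


def comfort_coefficient(iteration: int, config: OptimizerConfig) -> float:
    """Linearly decreasing comfort-zone coefficient c(l) = c_max - l·(c_max-c_min)/L."""
    L = config.max_iterations
    if not (0 <= iteration <= L):
        raise ValueError(f"iteration must lie in [0, {L}], got {iteration}")
    return config.c_max - iteration * (config.c_max - config.c_min) / L


def singer_step(r: float) -> float:
    """One iterate of the singer chaotic map, safeguarded into (0,1).

    Raw map: 1.07·(7.9 r − 23.3 r² + 28.7 r³ − 13.3 r⁴).  The raw quartic
    can exit the unit interval on a thin sliver of states; the safeguard
    folds the value back via ``|v| mod 1`` and floors an exact zero.
    """
    if not (0.0 < r < 1.0):
        raise ValueError(f"chaotic state must lie strictly inside (0,1), got {r}")
    v = 1.07 * (7.9 * r - 23.3 * r**2 + 28.7 * r**3 - 13.3 * r**4)
    if not (0.0 < v < 1.0):
        v = abs(v) % 1.0
        if v == 0.0:
            v = _SINGER_FLOOR
    return v


def opposite_point(x: np.ndarray, bounds: BoxBounds) -> np.ndarray:
    """Reflection of ``x`` through the box centre: Lb + Ub − x (an involution)."""
    x = np.asarray(x, dtype=float)
    if not bounds.contains(x):
        raise ValueError("point lies outside the bounds")
    return bounds.lower + bounds.upper - x


def quasi_opposite_point(
    x: np.ndarray,
    bounds: BoxBounds,
    rand_source: Union[np.random.Generator, float],
) -> np.ndarray:
    """Point drawn uniformly between the box centre and the opposite of ``x``.

    ``rand_source`` may be a numpy Generator (independent uniform per
    component) or a scalar fraction in [0,1] (the AGOA chaotic ``r3``
    stream supplies one scalar per iteration).
    """
    x = np.asarray(x, dtype=float)
    if not bounds.contains(x):
        raise ValueError("point lies outside the bounds")
    m = bounds.center
    opp = bounds.lower + bounds.upper - x
    if isinstance(rand_source, np.random.Generator):
        u = rand_source.random(x.shape)
    else:
        u = float(rand_source)
        if not (0.0 <= u <= 1.0):
            raise ValueError("scalar rand_source must lie in [0,1]")
    return m + u * (opp - m)


def goa_position_update(
    pop: SearchPopulation,
    bounds: BoxBounds,
    c: float,
    config: OptimizerConfig,
    streams: Optional[ChaoticStreams] = None,
) -> np.ndarray:
    """One swarm position update; returns the new (N, D) position matrix.

    For agent i, dimension d::

        x_i^d  <-  c * sum_{j != i}  c * (ub_d - lb_d)/2
                        * s(|x_j^d - x_i^d|) * (x_j^d - x_i^d) / d_ij
                   + T_d

    with d_ij the Euclidean inter-agent distance.  Coincident agents
    contribute zero (limit convention, never a division failure).  With
    chaotic streams the social sum is scaled by r1 and the target term by
    r2.  All outputs are clamped into the bounds.
    """
    X = np.asarray(pop.positions, dtype=float)
    n, dim = X.shape
    if n < 2:
        raise ValueError("population must have at least 2 agents")
    if c <= 0:
        raise ValueError("comfort coefficient must be positive")

    diff = X[None, :, :] - X[:, None, :]            # diff[i, j, d] = x_j^d - x_i^d
    dist = np.linalg.norm(diff, axis=2)             # (N, N) Euclidean
    kernel = social_force(np.abs(diff), config)     # s per dimension
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(dist[:, :, None] > 0, diff / dist[:, :, None], 0.0)
    contrib = (c * bounds.span[None, None, :] / 2.0) * kernel * unit
    idx = np.arange(n)
    contrib[idx, idx, :] = 0.0
    social = contrib.sum(axis=1)                    # (N, D)

    target = pop.target_position[None, :]
    if streams is not None:
        social = streams.r1 * social
        target = streams.r2 * target

    new = c * social + target
    if config.gravity_constant != 0.0:
        new = new - config.gravity_constant
    if config.wind_strength != 0.0:
        new = new + config.wind_strength
    return np.clip(new, bounds.lower, bounds.upper)


def qobl_select(
    candidate: tuple[np.ndarray, float],
    quasi_opposite: tuple[np.ndarray, float],
) -> tuple[np.ndarray, float]:
    """Keep the member with lower fitness; ties keep the original candidate."""
    return quasi_opposite if quasi_opposite[1] < candidate[1] else candidate


def _safe_eval(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    v = float(objective(x))
    return v if math.isfinite(v) else math.inf


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: BoxBounds,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Run GOA (or AGOA, per ``config`` flags) on ``objective`` over ``bounds``.

    The convergence history records the best fitness ever evaluated after
    each iteration (entry 0 = after initialization) and is therefore
    non-increasing.  Identical seeds give identical results.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, dim = config.population_size, bounds.dimension

    X = rng.uniform(bounds.lower, bounds.upper, size=(n, dim))
    fit = np.array([_safe_eval(objective, x) for x in X])
    evals = n

    best_idx = int(np.argmin(fit))
    pop = SearchPopulation(
        positions=X,
        fitness=fit,
        target_position=X[best_idx].copy(),
        target_fitness=float(fit[best_idx]),
    )
    streams = ChaoticStreams.from_rng(rng) if config.use_chaos else None

    history = [pop.target_fitness]
    for it in range(1, config.max_iterations + 1):
        c = comfort_coefficient(it, config)
        new_X = goa_position_update(pop, bounds, c, config, streams)
        new_fit = np.array([_safe_eval(objective, x) for x in new_X])
        evals += n

        if config.use_qobl:
            rand_source: Union[np.random.Generator, float]
            rand_source = streams.r3 if streams is not None else rng
            for i in range(n):
                q = quasi_opposite_point(new_X[i], bounds, rand_source)
                q_fit = _safe_eval(objective, q)
                evals += 1
                new_X[i], new_fit[i] = qobl_select(
                    (new_X[i], new_fit[i]), (q, q_fit)
                )

        pop.positions = new_X
        pop.fitness = new_fit
        i_best = int(np.argmin(new_fit))
        if new_fit[i_best] < pop.target_fitness:   # strict improvement only
            pop.target_fitness = float(new_fit[i_best])
            pop.target_position = new_X[i_best].copy()

        if streams is not None:
            streams.advance()
        history.append(pop.target_fitness)

    return OptimizationResult(
        best_position=pop.target_position,
        best_fitness=pop.target_fitness,
        convergence_history=np.asarray(history),
        evaluations_used=evals,
    )
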
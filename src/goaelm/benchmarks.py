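"""Benchmark test functions and the repeated-trial validation harness.

Five classic unconstrained minimization problems (all with minimum 0):

====  ==============================================  ============
name  definition                                      box
====  ==============================================  ============
F1    sphere, sum x_i^2                               [-100, 100]
F2    shifted quadratic, sum (x_i + 0.5)^2            [-100, 100]
F3    Schwefel 2.22, sum |x_i| + prod |x_i|           [-30, 30]
F4    quartic with additive uniform[0,1) noise        [-128, 128]
F5    Rosenbrock                                      [-128, 128]
====  ==============================================  ============

F2 also exposes a floor-step variant (``sum floor(x_i + 0.5)^2``, the
classic De Jong step function); the literal quadratic form is the default.
The harness runs an optimizer repeatedly with consecutive seeds and
summarizes the final best fitnesses by mean (AVE) and standard deviation
(STD), the protocol used to compare optimizer variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .optimizers import BoxBounds, OptimizerConfig, OptimizationResult, optimize

__all__ = [
    "BenchmarkFunction",
    "TrialSummary",
    "FUNCTION_NAMES",
    "get_benchmark",
    "evaluate_benchmark",
    "analytic_minimizer",
    "run_trials",
    "summarize_table",
]

FUNCTION_NAMES = ("F1", "F2", "F3", "F4", "F5")

_RANGES = {
    "F1": (-100.0, 100.0),
    "F2": (-100.0, 100.0),
    "F3": (-30.0, 30.0),
    "F4": (-128.0, 128.0),
    "F5": (-128.0, 128.0),
}


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dimension: int
    bounds: BoxBounds
    known_minimum: float = 0.0
    stochastic: bool = False
    step_variant: bool = False  # F2 only: floor-step form instead of literal

    def __call__(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        return evaluate_benchmark(
            self.name, x, rng=rng, step_variant=self.step_variant, check_bounds=False
        )


def get_benchmark(name: str, dimension: int, step_variant: bool = False) -> BenchmarkFunction:
    if name not in _RANGES:
        raise ValueError(f"unknown benchmark {name!r}; expected one of {FUNCTION_NAMES}")
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    lo, hi = _RANGES[name]
    return BenchmarkFunction(
        name=name,
        dimension=dimension,
        bounds=BoxBounds.cube(lo, hi, dimension),
        stochastic=(name == "F4"),
        step_variant=step_variant and name == "F2",
    )


def evaluate_benchmark(
    name: str,
    x: Union[Sequence[float], np.ndarray],
    rng: Optional[np.random.Generator] = None,
    step_variant: bool = False,
    check_bounds: bool = True,
) -> float:
    """Evaluate benchmark ``name`` at ``x``; F4 requires an rng for its noise."""
    if name not in _RANGES:
        raise ValueError(f"unknown benchmark {name!r}; expected one of {FUNCTION_NAMES}")
    x = np.asarray(x, dtype=float)
    if check_bounds:
        lo, hi = _RANGES[name]
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"point outside the {name} bounds [{lo}, {hi}]")
    if name == "F1":
        return float(np.sum(x**2))
    if name == "F2":
        shifted = np.floor(x + 0.5) if step_variant else x + 0.5
        return float(np.sum(shifted**2))
    if name == "F3":
        a = np.abs(x)
        return float(np.sum(a) + np.prod(a))
    if name == "F4":
        if rng is None:
            raise ValueError("F4 is stochastic and requires an rng")
        i = np.arange(1, x.size + 1)
        return float(np.sum(i * x**4) + rng.uniform(0.0, 1.0))
    # F5: Rosenbrock
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def analytic_minimizer(name: str, dimension: int, step_variant: bool = False) -> np.ndarray:
    """The argmin of the deterministic part of each benchmark."""
    if name == "F2" and not step_variant:
        return np.full(dimension, -0.5)
    if name == "F5":
        return np.ones(dimension)
    return np.zeros(dimension)


@dataclass(frozen=True)
class TrialSummary:
    """Per-(optimizer, function) summary over repeated seeded runs."""

    optimizer_name: str
    function_name: str
    n_runs: int
    mean_best: float
    std_best: float
    per_run_bests: np.ndarray

    def __post_init__(self) -> None:
        if self.n_runs != len(self.per_run_bests):
            raise ValueError("n_runs must equal len(per_run_bests)")


def run_trials(
    optimizer_name: str,
    function: BenchmarkFunction,
    n_runs: int,
    config: OptimizerConfig,
    seed_base: int = 0,
    run_hook: Optional[Callable[[int, OptimizationResult], None]] = None,
) -> TrialSummary:
    """Run ``n_runs`` independent seeded optimizations and summarize AVE/STD.

    Seeds are ``seed_base + 0 .. seed_base + n_runs - 1``; F4's evaluation
    noise uses an rng derived from the same per-run seed so trials are
    fully reproducible.  Diverged (non-finite) runs are recorded, not
    dropped.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    bests = np.empty(n_runs)
    for k in range(n_runs):
        seed = seed_base + k
        if function.stochastic:
            noise_rng = np.random.default_rng((seed, 0xF4))
            objective = lambda x: function(x, rng=noise_rng)
        else:
            objective = function
        cfg = replace(config, rng_seed=seed)
        result = optimize(objective, function.bounds, cfg)
        bests[k] = result.best_fitness
        if run_hook is not None:
            run_hook(seed, result)
    return TrialSummary(
        optimizer_name=optimizer_name,
        function_name=function.name,
        n_runs=n_runs,
        mean_best=float(np.mean(bests)),
        std_best=float(np.std(bests, ddof=1)),
        per_run_bests=bests,
    )


def summarize_table(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Comparison table keyed by (function, optimizer) with AVE/STD columns."""
    if len(summaries) == 0:
        raise ValueError("need at least one TrialSummary")
    rows = [
        {
            "function": s.function_name,
            "optimizer": s.optimizer_name,
            "n_runs": s.n_runs,
            "ave": s.mean_best,
            "std": s.std_best,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["function", "optimizer"]).any():
        raise ValueError("duplicate (function, optimizer) keys in summaries")
    return df.sort_values(["function", "optimizer"]).reset_index(drop=True)
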
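"""Benchmark test functions and the multi-run validation protocol.

Four classic minimization benchmarks (Sphere, Rosenbrock, Ackley,
Rastrigin, all with minimum value 0) are used to validate the optimizer:
a configuration is run repeatedly with distinct seeds and the mean and
sample standard deviation of the per-run best costs summarize performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optimizer import CSOConfig, OptimizationResult, SearchSpace, optimize


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)
    )


def ackley(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    return float(
        -20.0 * math.exp(-0.2 * math.sqrt(np.sum(x**2) / n))
        - math.exp(np.sum(np.cos(2.0 * math.pi * x)) / n)
        + 20.0
        + math.e
    )


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(np.sum(x**2 - 10.0 * np.cos(2.0 * math.pi * x) + 10.0))


#: name -> (function, symmetric range half-width)
BENCHMARKS = {
    "sphere": (sphere, 100.0),
    "rosenbrock": (rosenbrock, 30.0),
    "ackley": (ackley, 32.0),
    "rastrigin": (rastrigin, 5.12),
}


@dataclass(frozen=True)
class BenchmarkSpec:
    """One benchmark problem: function name, dimension, box range."""

    name: str
    dim: int = 30

    def __post_init__(self) -> None:
        if self.name not in BENCHMARKS:
            raise ValueError(
                f"unknown benchmark {self.name!r}; choose from {sorted(BENCHMARKS)}"
            )

    @property
    def half_range(self) -> float:
        return BENCHMARKS[self.name][1]

    @property
    def space(self) -> SearchSpace:
        return SearchSpace.cube(self.dim, -self.half_range, self.half_range)

    @property
    def fmin(self) -> float:
        return 0.0


def evaluate_benchmark(name: str, x: np.ndarray) -> float:
    """Value of a named benchmark function at x."""
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}")
    return BENCHMARKS[name][0](np.asarray(x, dtype=np.float64))


@dataclass
class TrialSummary:
    """Mean/std of per-run best costs over independent optimizer runs."""

    per_run_best: np.ndarray
    average: float
    std: float
    degenerate_std: bool  # True when runs == 1 and std is reported as 0

    @classmethod
    def from_costs(cls, costs: np.ndarray) -> "TrialSummary":
        costs = np.asarray(costs, dtype=np.float64)
        degenerate = costs.size == 1
        std = 0.0 if degenerate else float(np.std(costs, ddof=1))
        return cls(
            per_run_best=costs,
            average=float(costs.mean()),
            std=std,
            degenerate_std=degenerate,
        )


def run_trials(
    spec: BenchmarkSpec,
    cfg: CSOConfig | None = None,
    runs: int = 35,
    base_seed: int = 0,
    mode: str = "ACSO",
) -> TrialSummary:
    """Independent optimizer runs with seeds base_seed .. base_seed+runs-1.

    The standard deviation uses the sample (n-1) denominator; a single run
    reports std 0 with the ``degenerate_std`` flag set.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    func = BENCHMARKS[spec.name][0]
    best = [
        optimize(func, spec.space, cfg, mode=mode, seed=base_seed + r).best_cost
        for r in range(runs)
    ]
    return TrialSummary.from_costs(np.array(best))


def run_result_record(
    spec: BenchmarkSpec,
    summary: TrialSummary,
    cfg: CSOConfig,
    mode: str,
    runs: int,
) -> dict:
    """JSON-friendly record of one benchmark experiment."""
    return {
        "function": spec.name,
        "algo": mode,
        "dim": spec.dim,
        "pop": cfg.n,
        "iters": cfg.iterations,
        "runs": runs,
        "average": summary.average,
        "std": summary.std,
        "per_run_best": summary.per_run_best.tolist(),
    }
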
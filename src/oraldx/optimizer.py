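"""Competitive Search Optimizer (CSO) and its amended variant (ACSO).

The competitive search metaphor: a population of contestants is ranked by
cost each round and split into an *excellent* group (top EC) and a
*general* group.  Contestants move according to their randomly drawn
learning ability A(i):

* excellent, strong learners (A > L1) take steps of S1 in [LB, UB] percent
  of the search range per coordinate, in a random direction rho in
  {-1, 0, 1};
* excellent, normal learners take smaller steps S2 in [0, LB] percent;
* general, strong learners add a common random scalar alpha*Q to every
  coordinate;
* general, normal learners have their position rescaled elementwise by
  +/- F*A(i) with F = P*o (a destructive, exploratory move);
* contestants with A > L3 additionally move toward the global best
  (reference behaviour);
* after each round the RC worst contestants withdraw and are replaced by
  fresh random ones.

The amendment (ACSO) adds two operators aimed at premature convergence:
a sine-cosine update of the round's worst contestant with a linearly
decaying amplitude, and opposition-based learning (with probability JR a
contestant's bound-reflected point is evaluated and greedily kept).

Minimization convention throughout; all positions are clamped to the box
after every operator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """A box-constrained search domain."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lb, dtype=np.float64))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=np.float64))
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        if lb.shape != ub.shape or np.any(lb >= ub):
            raise ValueError("require lb < ub elementwise")

    @classmethod
    def cube(cls, d: int, low: float, high: float) -> "SearchSpace":
        return cls(lb=np.full(d, low), ub=np.full(d, high))

    @property
    def d(self) -> int:
        return self.lb.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def opposite(self, x: np.ndarray) -> np.ndarray:
        """Opposition-based-learning reflection lb + ub - x."""
        return self.lb + self.ub - x


@dataclass(frozen=True)
class CSOConfig:
    """Algorithm constants of the competitive search optimizer.

    ``ec`` (excellent-group size) defaults to n/2 and ``rc`` (withdrawals
    per round) to max(1, n/10).  ``ub_pct``/``lb_pct`` are the step-size
    percent constants of the excellent-group updates; ``gamma`` is the
    sine-cosine decay constant and ``jump_rate`` the OBL probability.
    """

    n: int = 60
    iterations: int = 250
    ec: int | None = None
    rc: int | None = None
    l1: float = 0.5
    l3: float = 0.7
    ub_pct: float = 20.0
    lb_pct: float = 5.0
    gamma: float = 2.0
    jump_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be at least 2")
        ec = self.n // 2 if self.ec is None else self.ec
        rc = max(1, self.n // 10) if self.rc is None else self.rc
        if not (0 < ec < self.n):
            raise ValueError(f"require 0 < ec < n, got ec={ec}")
        if not (0 <= rc < self.n):
            raise ValueError(f"require 0 <= rc < n, got rc={rc}")
        if not (self.lb_pct < self.ub_pct):
            raise ValueError("require lb_pct < ub_pct")
        for name in ("l1", "l3", "jump_rate"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        object.__setattr__(self, "ec", ec)
        object.__setattr__(self, "rc", rc)


@dataclass
class UpdateDraws:
    """Random draws consumed by one contestant's group update."""

    rho: int  # in {-1, 0, 1}
    alpha: float  # in [-1, 1]
    q: float  # in [0, 2]
    l2: np.ndarray  # length-d vector of +/-1
    o: float  # in {0.1, 0.2, 0.3, 0.4, 0.5}
    p: float  # standard normal
    rand1: float  # in [0, 1]

    @property
    def f(self) -> float:
        return self.p * self.o

    def s1(self, cfg: CSOConfig) -> float:
        """Strong-learner step fraction, in [LB, UB] percent of the range."""
        return (cfg.lb_pct + (cfg.ub_pct - cfg.lb_pct) * self.rand1) / 100.0

    def s2(self, cfg: CSOConfig) -> float:
        """Normal-learner step fraction, in [0, LB] percent of the range."""
        return cfg.lb_pct * self.rand1 / 100.0


def draw_update(rng: np.random.Generator, d: int) -> UpdateDraws:
    """Sample one contestant's update draws from their stated domains."""
    return UpdateDraws(
        rho=int(rng.integers(-1, 2)),
        alpha=float(rng.uniform(-1.0, 1.0)),
        q=float(rng.uniform(0.0, 2.0)),
        l2=rng.choice(np.array([-1.0, 1.0]), size=d),
        o=float(rng.choice(np.array([0.1, 0.2, 0.3, 0.4, 0.5]))),
        p=float(rng.standard_normal()),
        rand1=float(rng.random()),
    )


@dataclass
class AmendmentDraws:
    """Coefficients of the sine-cosine worst-contestant update.

    ``a1`` decays linearly from gamma to 0 across the run; ``a2`` is an
    angle in [0, 2pi]; ``a3`` in [0, 2] scales the attractor; ``a4`` in
    [0, 1] switches between the sine and cosine branch.
    """

    a1: float
    a2: float
    a3: float
    a4: float

    @classmethod
    def draw(
        cls,
        rng: np.random.Generator,
        iter_curr: int,
        iter_max: int,
        gamma: float,
    ) -> "AmendmentDraws":
        return cls(
            a1=gamma - iter_curr * gamma / iter_max,
            a2=float(rng.uniform(0.0, 2.0 * math.pi)),
            a3=float(rng.uniform(0.0, 2.0)),
            a4=float(rng.random()),
        )


@dataclass
class OptimizationResult:
    """Outcome of a CSO/ACSO run (elitist: history is non-increasing)."""

    best_position: np.ndarray
    best_cost: float
    cost_history: np.ndarray
    evaluations: int


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def initialize(
    space: SearchSpace, cfg: CSOConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random positions within bounds and abilities in [0, 1]."""
    positions = rng.uniform(space.lb, space.ub, size=(cfg.n, space.d))
    abilities = rng.random(cfg.n)
    return positions, abilities


def rank_and_split(costs: np.ndarray, ec: int) -> tuple[np.ndarray, np.ndarray]:
    """Ascending-cost ranking (stable ties) split at the top EC."""
    if np.any(~np.isfinite(costs) & ~np.isposinf(costs)):
        raise RuntimeError("all contestants must be evaluated before ranking")
    order = np.argsort(costs, kind="stable")
    return order[:ec], order[ec:]


def update_excellent(
    position: np.ndarray,
    ability: float,
    space: SearchSpace,
    cfg: CSOConfig,
    draws: UpdateDraws,
) -> np.ndarray:
    """Excellent-group step: A*S*rho*(ub-lb), S graded by learning ability."""
    s = draws.s1(cfg) if ability > cfg.l1 else draws.s2(cfg)
    new = position + ability * s * draws.rho * (space.ub - space.lb)
    return space.clamp(new)


def update_general(
    position: np.ndarray,
    ability: float,
    space: SearchSpace,
    cfg: CSOConfig,
    draws: UpdateDraws,
) -> np.ndarray:
    """General-group step: common scalar drift, or elementwise rescale."""
    if ability > cfg.l1:
        new = position + draws.alpha * draws.q
    else:
        new = position * draws.l2 * draws.f * ability
    return space.clamp(new)


def reference_update(
    position: np.ndarray,
    ability: float,
    gbest: np.ndarray,
    l3: float,
    space: SearchSpace,
) -> np.ndarray:
    """Reference behaviour: contestants with A > L3 move toward the best."""
    if ability > l3:
        position = position + (gbest - position) * ability
    return space.clamp(position)


def withdraw_replace(
    positions: np.ndarray,
    abilities: np.ndarray,
    costs: np.ndarray,
    rc: int,
    space: SearchSpace,
    rng: np.random.Generator,
    objective=None,
) -> int:
    """Replace the RC worst contestants (never the best) with fresh ones.

    Mutates the arrays in place; returns the number of objective
    evaluations spent on the newcomers (0 if no objective is given, in
    which case their costs are set to +inf pending evaluation).
    """
    if rc == 0:
        return 0
    best = int(np.argmin(costs))
    order = np.argsort(costs, kind="stable")[::-1]
    victims = [int(i) for i in order if int(i) != best][:rc]
    evals = 0
    for i in victims:
        positions[i] = rng.uniform(space.lb, space.ub)
        abilities[i] = rng.random()
        if objective is None:
            costs[i] = np.inf
        else:
            costs[i] = _safe_eval(objective, positions[i])
            evals += 1
    return evals


def sine_cosine_worst_update(
    worst: np.ndarray,
    gbest: np.ndarray,
    space: SearchSpace,
    draws: AmendmentDraws,
) -> np.ndarray:
    """Sine-cosine move of the round's worst contestant toward the best."""
    gap = np.abs(draws.a3 * gbest - worst)
    trig = math.sin(draws.a2) if draws.a4 < 0.5 else math.cos(draws.a2)
    return space.clamp(worst + draws.a1 * trig * gap)


def opposition_jump(
    position: np.ndarray,
    cost: float,
    objective,
    space: SearchSpace,
    jump_rate: float,
    rand: float,
) -> tuple[np.ndarray, float, int]:
    """Opposition-based learning: greedily keep the better of x and lb+ub-x.

    Fires only when ``rand < jump_rate``; returns (position, cost,
    evaluations spent).
    """
    if rand >= jump_rate:
        return position, cost, 0
    opp = space.opposite(position)
    opp_cost = _safe_eval(objective, opp)
    if opp_cost < cost:
        return opp, opp_cost, 1
    return position, cost, 1


def _safe_eval(objective, x: np.ndarray) -> float:
    v = float(objective(x))
    if not math.isfinite(v):
        logger.warning("non-finite objective value at %s; treating as +inf", x)
        return math.inf
    return v


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def optimize(
    objective,
    space: SearchSpace,
    cfg: CSOConfig | None = None,
    mode: str = "ACSO",
    seed: int | None = None,
    initial_positions: np.ndarray | None = None,
) -> OptimizationResult:
    """Run the competitive search optimizer (amended by default).

    Per iteration: rank and split; update the excellent then the general
    group; apply the reference update to everyone; in ACSO mode apply the
    sine-cosine update to the round's worst contestant; evaluate; in ACSO
    mode apply opposition-based learning to every contestant; withdraw and
    replace the RC worst; resample learning abilities.  The global best is
    tracked elitistically, so the cost history is non-increasing.

    ``initial_positions`` rows, if given, overwrite the first rows of the
    random initial population (used to seed known-good candidates such as
    default hyperparameters).
    """
    if mode not in ("ACSO", "CSO"):
        raise ValueError(f"mode must be 'ACSO' or 'CSO', got {mode!r}")
    cfg = cfg or CSOConfig()
    rng = np.random.default_rng(seed)

    positions, abilities = initialize(space, cfg, rng)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=np.float64))
        positions[: len(seeds)] = space.clamp(seeds)

    costs = np.array([_safe_eval(objective, p) for p in positions])
    evaluations = cfg.n
    best = int(np.argmin(costs))
    gbest_pos, gbest_cost = positions[best].copy(), float(costs[best])

    history = np.empty(cfg.iterations)
    amended = mode == "ACSO"
    for t in range(cfg.iterations):
        excellent, general = rank_and_split(costs, cfg.ec)
        for i in excellent:
            positions[i] = update_excellent(
                positions[i], abilities[i], space, cfg, draw_update(rng, space.d)
            )
        for i in general:
            positions[i] = update_general(
                positions[i], abilities[i], space, cfg, draw_update(rng, space.d)
            )
        for i in range(cfg.n):
            positions[i] = reference_update(
                positions[i], abilities[i], gbest_pos, cfg.l3, space
            )
        if amended:
            worst = int(np.argsort(costs, kind="stable")[-1])
            positions[worst] = sine_cosine_worst_update(
                positions[worst],
                gbest_pos,
                space,
                AmendmentDraws.draw(rng, t + 1, cfg.iterations, cfg.gamma),
            )

        costs = np.array([_safe_eval(objective, p) for p in positions])
        evaluations += cfg.n

        if amended:
            for i in range(cfg.n):
                positions[i], costs[i], spent = opposition_jump(
                    positions[i],
                    costs[i],
                    objective,
                    space,
                    cfg.jump_rate,
                    float(rng.random()),
                )
                evaluations += spent

        evaluations += withdraw_replace(
            positions, abilities, costs, cfg.rc, space, rng, objective
        )

        best = int(np.argmin(costs))
        if costs[best] < gbest_cost:
            gbest_pos, gbest_cost = positions[best].copy(), float(costs[best])
        history[t] = gbest_cost
        abilities = rng.random(cfg.n)  # the ability to learn changes randomly

    return OptimizationResult(
        best_position=gbest_pos,
        best_cost=gbest_cost,
        cost_history=history,
        evaluations=evaluations,
    )
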
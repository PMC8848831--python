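"""Grey wolf optimizer (GWO): bounded continuous minimization.

A pack of candidate solutions ("wolves") moves under the guidance of the
three best solutions found so far -- alpha, beta and delta; the rest of the
pack are omegas.  Each agent is attracted to each leader through the
stochastic encircling equations

    D = |C * X_leader - X|,   X_k = X_leader - A_k * D_k,

with coefficient vectors A = 2 a r1 - a and C = 2 r2 (r1, r2 uniform on
[0, 1]) and moves to the mean of the three attracted positions.  The
exploration scalar ``a`` decays linearly from 2 to 0 over the run, so |A|
shrinks below 1 and the pack shifts from exploration to exploitation around
the leaders.  Leaders are retained elitistically (replaced only by strictly
better solutions), which makes the best-fitness trace non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwoConfig",
    "GwoCoefficients",
    "GwoResult",
    "linear_a_schedule",
    "draw_coefficients",
    "encircle",
    "leader_guided_update",
    "clip_to_bounds",
    "run_gwo",
    "trace_to_csv",
]


@dataclass(frozen=True)
class GwoConfig:
    """Pack size, iteration budget, box bounds and RNG seed.

    Defaults are the segmentation setting of this package: 5 agents, 5
    iterations, search box [0, 225] per dimension (intensity-valued cluster
    centers).
    """

    n_agents: int = 5
    max_iter: int = 5
    lower_bound: float = 0.0
    upper_bound: float = 225.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 3:
            raise ValueError("need at least 3 agents (alpha, beta, delta)")
        if self.max_iter < 2:
            raise ValueError(f"max_iter must be >= 2, got {self.max_iter}")
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"lower bound {self.lower_bound} must be < upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class GwoCoefficients:
    """One draw of the stochastic encircling coefficients."""

    a: float
    A: np.ndarray
    C: np.ndarray
    r1: np.ndarray
    r2: np.ndarray


@dataclass
class GwoResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)   # best-so-far per iteration
    alpha_trace: list[np.ndarray] = field(default_factory=list)


def linear_a_schedule(t: int, T: int) -> float:
    """Exploration scalar a(t) = 2 (1 - t/(T-1)); a(0)=2 and a(T-1)=0."""
    if T < 2:
        raise ValueError(f"total iterations must be >= 2, got {T}")
    if not 0 <= t <= T - 1:
        raise ValueError(f"iteration index {t} outside [0, {T - 1}]")
    return 2.0 * (1.0 - t / (T - 1))


def draw_coefficients(a: float, rng: np.random.Generator, dim: int) -> GwoCoefficients:
    """Draw A = 2 a r1 - a and C = 2 r2 componentwise."""
    if not 0.0 <= a <= 2.0:
        raise ValueError(f"exploration scalar a must lie in [0, 2], got {a}")
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return GwoCoefficients(a=a, A=2.0 * a * r1 - a, C=2.0 * r2, r1=r1, r2=r2)


def encircle(X: np.ndarray, X_p: np.ndarray, coeff: GwoCoefficients):
    """Encircling step: D = |C o X_p - X|, X_next = X_p - A o D."""
    X = np.asarray(X, dtype=float)
    X_p = np.asarray(X_p, dtype=float)
    if X.shape != X_p.shape:
        raise ValueError(f"position shapes differ: {X.shape} vs {X_p.shape}")
    D = np.abs(coeff.C * X_p - X)
    return D, X_p - coeff.A * D


def leader_guided_update(
    X: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    delta: np.ndarray,
    coeffs: Sequence[GwoCoefficients],
) -> np.ndarray:
    """Move ``X`` to the mean of its three leader-attracted positions."""
    if len(coeffs) != 3:
        raise ValueError("exactly three coefficient draws required (one per leader)")
    attracted = [encircle(X, leader, ck)[1]
                 for leader, ck in zip((alpha, beta, delta), coeffs)]
    return np.mean(attracted, axis=0)


def clip_to_bounds(X: np.ndarray, lb: float, ub: float) -> np.ndarray:
    if not lb < ub:
        raise ValueError(f"lower bound {lb} must be < upper bound {ub}")
    return np.clip(np.asarray(X, dtype=float), lb, ub)


class _Leaders:
    """Elitist alpha/beta/delta bookkeeping: replace only on strict improvement."""

    def __init__(self, dim: int):
        self.pos = np.zeros((3, dim))
        self.fit = np.full(3, np.inf)

    def consider(self, x: np.ndarray, f: float) -> None:
        if f < self.fit[0]:
            self.pos[2], self.fit[2] = self.pos[1], self.fit[1]
            self.pos[1], self.fit[1] = self.pos[0], self.fit[0]
            self.pos[0], self.fit[0] = x.copy(), f
        elif f < self.fit[1]:
            self.pos[2], self.fit[2] = self.pos[1], self.fit[1]
            self.pos[1], self.fit[1] = x.copy(), f
        elif f < self.fit[2]:
            self.pos[2], self.fit[2] = x.copy(), f


def _evaluate(fitness: Callable[[np.ndarray], float], pos: np.ndarray) -> np.ndarray:
    fits = np.empty(pos.shape[0])
    for i, x in enumerate(pos):
        f = float(fitness(x))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness {f} at position {x}")
        fits[i] = f
    return fits


def run_gwo(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    cfg: GwoConfig,
    init_positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> GwoResult:
    """Minimize ``fitness`` over the box [lb, ub]^dim.

    ``init_positions`` (if given) seed the first pack slots; remaining agents
    start uniformly at random inside the bounds.  All stochastic draws flow
    through one generator (``rng`` or one seeded from ``cfg.seed``), so runs
    are reproducible.  Returns the elitist best-so-far solution and its
    per-iteration fitness trace, which is monotone non-increasing.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lb, ub = cfg.lower_bound, cfg.upper_bound

    pos = np.empty((cfg.n_agents, dim))
    n_seeded = 0
    if init_positions is not None:
        seeded = np.atleast_2d(np.asarray(init_positions, dtype=float))
        if seeded.shape[1] != dim:
            raise ValueError(f"init positions have dim {seeded.shape[1]}, expected {dim}")
        if np.any(seeded < lb) or np.any(seeded > ub):
            raise ValueError("init positions must lie within the search bounds")
        n_seeded = min(seeded.shape[0], cfg.n_agents)
        pos[:n_seeded] = seeded[:n_seeded]
    if n_seeded < cfg.n_agents:
        pos[n_seeded:] = rng.uniform(lb, ub, (cfg.n_agents - n_seeded, dim))

    fits = _evaluate(fitness, pos)
    leaders = _Leaders(dim)
    for x, f in zip(pos, fits):
        leaders.consider(x, f)

    result = GwoResult(best_position=leaders.pos[0].copy(),
                       best_fitness=float(leaders.fit[0]))
    for t in range(cfg.max_iter):
        a = linear_a_schedule(t, cfg.max_iter)
        new_pos = np.empty_like(pos)
        for i in range(cfg.n_agents):
            coeffs = [draw_coefficients(a, rng, dim) for _ in range(3)]
            moved = leader_guided_update(pos[i], leaders.pos[0], leaders.pos[1],
                                         leaders.pos[2], coeffs)
            new_pos[i] = clip_to_bounds(moved, lb, ub)
        pos = new_pos
        fits = _evaluate(fitness, pos)
        for x, f in zip(pos, fits):
            leaders.consider(x, f)
        result.trace.append(float(leaders.fit[0]))
        result.alpha_trace.append(leaders.pos[0].copy())

    result.best_position = leaders.pos[0].copy()
    result.best_fitness = float(leaders.fit[0])
    return result


def trace_to_csv(result: GwoResult, path) -> None:
    """Export (iteration, best fitness, alpha components) as CSV."""
    rows = {
        "iteration": np.arange(len(result.trace)),
        "best_fitness": result.trace,
    }
    alphas = np.asarray(result.alpha_trace)
    for d in range(alphas.shape[1]):
        rows[f"alpha_{d}"] = alphas[:, d]
    pd.DataFrame(rows).to_csv(path, index=False)
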
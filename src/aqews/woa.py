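"""Whale Optimization Algorithm (WOA).

A population metaheuristic that mimics the bubble-net hunting of humpback
whales.  Each agent either shrinks an encirclement of the best solution
found so far, spirals toward it on a logarithmic helix, or searches around a
randomly chosen agent, the choice depending on a coin flip ``p`` and on the
magnitude of the coefficient vector ``A = 2*a*r - a`` whose envelope ``a``
decays linearly from 2 to 0 over the run.  Minimization throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "WOAConfig",
    "WOAResult",
    "encircle_update",
    "spiral_update",
    "explore_update",
    "optimize",
]


@dataclass
class WOAConfig:
    dim: int
    lower: np.ndarray | float = -1.0
    upper: np.ndarray | float = 1.0
    n_agents: int = 10
    max_iter: int = 200
    spiral_b: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")


@dataclass
class WOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each iteration
    n_evaluations: int

    def __iter__(self):  # allow tuple unpacking
        return iter((self.best_position, self.best_fitness, self.history))


def _check_shapes(*arrays) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    if len({a.size for a in out}) != 1:
        raise ValueError("position/coefficient shapes must agree")
    return out


def encircle_update(x, x_best, A, C) -> np.ndarray:
    """Shrinking encirclement of the best agent: ``X* - A*|C*X* - X|``."""
    x, x_best, A, C = _check_shapes(x, x_best, A, C)
    return x_best - A * np.abs(C * x_best - x)


def spiral_update(x, x_best, l: float, b: float = 1.0) -> np.ndarray:
    """Logarithmic-spiral move toward the best agent."""
    x, x_best = _check_shapes(x, x_best)
    d = np.abs(x_best - x)
    return d * np.exp(b * l) * np.cos(2.0 * np.pi * l) + x_best


def explore_update(x, x_rand, A, C) -> np.ndarray:
    """Global search around a randomly chosen agent."""
    x, x_rand, A, C = _check_shapes(x, x_rand, A, C)
    return x_rand - A * np.abs(C * x_rand - x)


def optimize(fitness: Callable[[np.ndarray], float], cfg: WOAConfig) -> WOAResult:
    """Run WOA on a box-constrained minimization problem.

    Per iteration, each agent resamples its own random coefficients; the
    branch is encirclement when ``p < 0.5`` and ``|A| < 1`` (norm across
    dimensions), exploration when ``p < 0.5`` and ``|A| >= 1``, spiral
    otherwise.  Positions are clamped to the box after every update and the
    best-so-far fitness history is monotone non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    span = cfg.upper - cfg.lower
    X = cfg.lower + rng.uniform(size=(cfg.n_agents, cfg.dim)) * span

    def _eval(x: np.ndarray) -> float:
        f = float(fitness(x))
        if not np.isfinite(f):
            raise FloatingPointError(
                f"non-finite fitness {f!r} at position {np.array2string(x, precision=4)}")
        return f

    fit = np.array([_eval(x) for x in X])
    n_evals = cfg.n_agents
    best_idx = int(np.argmin(fit))
    best_x = X[best_idx].copy()
    best_f = float(fit[best_idx])

    history = np.empty(cfg.max_iter)
    for t in range(cfg.max_iter):
        a = 2.0 - 2.0 * t / cfg.max_iter
        for i in range(cfg.n_agents):
            r1 = rng.uniform(size=cfg.dim)
            r2 = rng.uniform(size=cfg.dim)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            p = rng.uniform()
            if p < 0.5:
                if np.linalg.norm(A) < 1.0:
                    X[i] = encircle_update(X[i], best_x, A, C)
                else:
                    j = int(rng.integers(cfg.n_agents))
                    X[i] = explore_update(X[i], X[j], A, C)
            else:
                l = rng.uniform(-1.0, 1.0)
                X[i] = spiral_update(X[i], best_x, l, cfg.spiral_b)
        np.clip(X, cfg.lower, cfg.upper, out=X)
        for i in range(cfg.n_agents):
            fit[i] = _eval(X[i])
        n_evals += cfg.n_agents
        cand = int(np.argmin(fit))
        if fit[cand] < best_f:
            best_f = float(fit[cand])
            best_x = X[cand].copy()
        history[t] = best_f
    return WOAResult(best_position=best_x, best_fitness=best_f,
                     history=history, n_evaluations=n_evals)
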
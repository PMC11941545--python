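"""Continuous Aquila Optimizer (AO).

The AO is a population-based metaheuristic modelled on four hunting
behaviours of the Aquila eagle.  Each candidate solution is a point in a
bounded D-dimensional box; at every iteration each candidate is moved by
one of four position-update strategies:

* **expanded exploration** — a high soar with a vertical stoop: move
  toward a blend of the best-known position and the population mean,
  with the pull toward the best decaying linearly over iterations;
* **narrowed exploration** — contour flight with a short glide attack:
  a Lévy-flight perturbation of the best position around a fresh random
  point, plus a logarithmic-spiral offset;
* **expanded exploitation** — a low flight with a slow descent: a step
  from the best-minus-mean direction plus a random point in the box;
* **narrowed exploitation** — walking and grabbing the prey: a
  quality-function-weighted pull to the best position with Lévy noise
  whose amplitude decays linearly to zero.

The first two-thirds of the iteration budget is the exploration phase,
the remainder exploitation; within a phase the expanded/narrowed variant
is chosen by a fair coin.  Replacement is greedy (a move is kept only if
it improves the candidate's fitness), so the best-ever fitness trajectory
is non-increasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "Bounds",
    "AOConfig",
    "OptimizationResult",
    "levy_sigma",
    "levy_step",
    "mean_position",
    "expanded_exploration",
    "spiral_offsets",
    "narrowed_exploration",
    "expanded_exploitation",
    "narrowed_exploitation",
    "quality_function",
    "g2_slope",
    "select_strategy",
    "clip_to_bounds",
    "optimize",
]

logger = logging.getLogger(__name__)

EXPANDED_EXPLORATION = "expanded_exploration"
NARROWED_EXPLORATION = "narrowed_exploration"
EXPANDED_EXPLOITATION = "expanded_exploitation"
NARROWED_EXPLOITATION = "narrowed_exploitation"

#: Fraction of the iteration budget spent in the exploration phase.
EXPLORATION_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class Bounds:
    """Box constraints: ``lower <= x <= upper`` elementwise."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if not np.all(lo < hi):
            raise ValueError("lower bound must be strictly below upper bound")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @classmethod
    def cube(cls, dim: int, lower: float = 0.0, upper: float = 1.0) -> "Bounds":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass(frozen=True)
class AOConfig:
    """Hyper-parameters of the optimizer.

    ``alpha`` and ``delta`` are the exploitation coefficients (both in
    (0, 0.1]); ``levy_beta``/``levy_scale`` parameterize the Lévy
    flights; ``omega`` is the spiral angular rate and ``r_cycles_max``
    the upper bound on the spiral's base radius draw.
    """

    pop_size: int = 20
    max_iter: int = 50
    alpha: float = 0.1
    delta: float = 0.1
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    omega: float = 0.005
    r_cycles_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 < self.alpha <= 0.1 and 0.0 < self.delta <= 0.1):
            raise ValueError("alpha and delta must lie in (0, 0.1]")
        if not (0.0 < self.levy_beta <= 2.0):
            raise ValueError("levy_beta must lie in (0, 2]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.r_cycles_max < 1:
            raise ValueError("r_cycles_max must be >= 1")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int
    strategy_trace: list[tuple[int, str]] = field(default_factory=list)

    def trace_frame(self):
        """Strategy trace as a DataFrame (iteration, strategy)."""
        import pandas as pd

        return pd.DataFrame(self.strategy_trace, columns=["iteration", "strategy"])


def levy_sigma(beta: float) -> float:
    """Mantegna scale parameter sigma for a Lévy-stable step of exponent ``beta``.

    sigma = [Gamma(1+b)·sin(pi·b/2) / (Gamma((1+b)/2)·b·2^((b-1)/2))]^(1/b),
    positive on (0, 2) and zero at b = 2 where the distribution collapses
    to a Gaussian.
    """
    if not (0.0 < beta <= 2.0):
        raise ValueError(f"levy beta must lie in (0, 2], got {beta}")
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_step(dim: int, beta: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed random step via the Mantegna construction.

    Draws u ~ N(0, sigma^2) and v ~ N(0, 1) per dimension and returns
    ``scale * u / |v|^(1/beta)``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if scale == 0.0:
        return np.zeros(dim)
    sigma = levy_sigma(beta)
    u = rng.normal(0.0, 1.0, size=dim) * sigma
    v = rng.normal(0.0, 1.0, size=dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


def mean_position(positions: np.ndarray) -> np.ndarray:
    """Elementwise mean of the population positions (rows = candidates)."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("population is empty")
    return positions.mean(axis=0)


def expanded_exploration(
    xi: np.ndarray,
    xbest: np.ndarray,
    xm: np.ndarray,
    t: int,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """High-soar update: X(t+1) = Xbest·(1 − t/T) + (XM − Xbest·rand).

    The linearly decaying first term pulls toward the best solution early
    and releases that pull as iterations progress; the second term mixes
    in the population mean minus a randomly damped copy of the best.
    """
    r = rng.random()
    return xbest * (1.0 - t / T) + (xm - xbest * r)


def spiral_offsets(
    dim: int, omega: float, r_base: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spiral-trajectory offsets for the contour-flight strategy.

    For index j = 1..D: r = r_base + 0.00565·j, theta = −omega·j + 3π/2,
    x = r·sin(theta), y = r·cos(theta).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    d1 = np.arange(1, dim + 1, dtype=float)
    r = r_base + 0.00565 * d1
    theta = -omega * d1 + 3.0 * np.pi / 2.0
    return r * np.sin(theta), r * np.cos(theta)


def narrowed_exploration(
    xbest: np.ndarray,
    xr: np.ndarray,
    bounds: Bounds,
    config: AOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contour-flight update: X(t+1) = Xbest·LF(D) + XR + (y − x)·rand.

    ``xr`` is a stochastically chosen position (a random population
    member in :func:`optimize`); the spiral offsets use a base radius
    drawn uniformly from {1..r_cycles_max}.
    """
    dim = bounds.dim
    lf = levy_step(dim, config.levy_beta, config.levy_scale, rng)
    r3 = float(rng.integers(1, config.r_cycles_max + 1))
    x_off, y_off = spiral_offsets(dim, config.omega, r3)
    r = rng.random()
    return xbest * lf + xr + (y_off - x_off) * r


def expanded_exploitation(
    xbest: np.ndarray,
    xm: np.ndarray,
    bounds: Bounds,
    alpha: float,
    delta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low-flight update: X(t+1) = (Xbest − XM)·α − rand + ((UB−LB)·rand + LB)·δ.

    The bare ``− rand`` term broadcasts a uniform scalar across all
    dimensions; the two draws are independent.
    """
    r1 = rng.random()
    r2 = rng.random()
    return (xbest - xm) * alpha - r1 + ((bounds.upper - bounds.lower) * r2 + bounds.lower) * delta


def quality_function(t: int, T: int, rand: float) -> float:
    """Search-balance quality function QF(t) = t^((2·rand − 1)/(1 − T)^2)."""
    if T == 1:
        return 1.0
    return float(t) ** ((2.0 * rand - 1.0) / (1.0 - T) ** 2)


def g2_slope(t: int, T: int) -> float:
    """Flight-slope factor G2 = 2·(1 − t/T), decaying linearly from 2 to 0."""
    return 2.0 * (1.0 - t / T)


def narrowed_exploitation(
    xi: np.ndarray,
    xbest: np.ndarray,
    t: int,
    T: int,
    config: AOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk-and-grab update:

    X(t+1) = QF·Xbest − G1·Xi·rand − G2·Levy(D) + rand·G1,
    with G1 = 2·rand − 1 in [−1, 1] and G2 decaying linearly to zero.
    """
    dim = xi.shape[0]
    qf = quality_function(t, T, rng.random())
    g1 = 2.0 * rng.random() - 1.0
    g2 = g2_slope(t, T)
    lf = levy_step(dim, config.levy_beta, config.levy_scale, rng)
    r = rng.random()
    return qf * xbest - g1 * xi * r - g2 * lf + r * g1


def select_strategy(t: int, T: int, u_phase: float) -> str:
    """Pick a strategy: exploration while t <= 2T/3 (inclusive), else
    exploitation; expanded if ``u_phase`` <= 0.5 else narrowed."""
    exploring = t <= EXPLORATION_FRACTION * T
    if exploring:
        return EXPANDED_EXPLORATION if u_phase <= 0.5 else NARROWED_EXPLORATION
    return EXPANDED_EXPLOITATION if u_phase <= 0.5 else NARROWED_EXPLOITATION


def clip_to_bounds(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Clamp a position into the box."""
    return np.clip(position, bounds.lower, bounds.upper)


def _propose(
    strategy: str,
    xi: np.ndarray,
    xbest: np.ndarray,
    xm: np.ndarray,
    positions: np.ndarray,
    bounds: Bounds,
    t: int,
    T: int,
    config: AOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    if strategy == EXPANDED_EXPLORATION:
        return expanded_exploration(xi, xbest, xm, t, T, rng)
    if strategy == NARROWED_EXPLORATION:
        xr = positions[rng.integers(positions.shape[0])]
        return narrowed_exploration(xbest, xr, bounds, config, rng)
    if strategy == EXPANDED_EXPLOITATION:
        return expanded_exploitation(xbest, xm, bounds, config.alpha, config.delta, rng)
    return narrowed_exploitation(xi, xbest, t, T, config, rng)


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: AOConfig,
    rng: np.random.Generator | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` over the box with the Aquila Optimizer.

    The population is initialized uniformly in the box and evaluated
    once; each of the T iterations then proposes one move per candidate
    (N·(T+1) objective evaluations in total) and accepts it only on
    improvement.  Candidates whose objective comes back non-finite are
    rejected with a warning.  All randomness flows through a single
    ``numpy`` Generator, so a fixed seed reproduces the run exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, T, dim = config.pop_size, config.max_iter, bounds.dim

    positions = rng.uniform(bounds.lower, bounds.upper, size=(N, dim))
    fitnesses = np.empty(N)
    for i in range(N):
        fitnesses[i] = objective(positions[i])
    if not np.all(np.isfinite(fitnesses)):
        bad = ~np.isfinite(fitnesses)
        warnings.warn(f"{bad.sum()} initial candidates returned non-finite fitness")
        fitnesses[bad] = np.inf

    best_idx = int(np.argmin(fitnesses))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitnesses[best_idx])
    history = [best_fit]
    trace: list[tuple[int, str]] = []
    evaluations = N

    for t in range(1, T + 1):
        xm = mean_position(positions)
        for i in range(N):
            strategy = select_strategy(t, T, rng.random())
            proposal = _propose(
                strategy, positions[i], best_pos, xm, positions, bounds, t, T, config, rng
            )
            proposal = clip_to_bounds(proposal, bounds)
            fit = objective(proposal)
            evaluations += 1
            trace.append((t, strategy))
            if not np.isfinite(fit):
                warnings.warn(
                    f"objective returned non-finite value at iteration {t}; "
                    "candidate rejected"
                )
                continue
            if fit < fitnesses[i]:
                positions[i] = proposal
                fitnesses[i] = fit
                if fit < best_fit:
                    best_fit = float(fit)
                    best_pos = proposal.copy()
        history.append(best_fit)
        if callback is not None:
            callback(t, best_fit)

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=np.asarray(history),
        evaluations=evaluations,
        strategy_trace=trace,
    )


def write_trace(result: OptimizationResult, path) -> None:
    """Write the per-iteration best fitness and strategy log as CSV."""
    import pandas as pd

    hist = pd.DataFrame(
        {"iteration": np.arange(len(result.history)), "best_fitness": result.history}
    )
    hist.to_csv(path, index=False)
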
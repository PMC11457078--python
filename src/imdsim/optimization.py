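"""Optimization of the induced and constitutive defense strategies.

The induced model has 11 free parameters (lambda2, lambda3, R0,
beta1..beta6, Zn, Zs); alpha, k0 and lambda1 describe the bacteria and
are held fixed.  The optimizer is an accept-if-better multiplicative
random walk on the log scale: each proposal multiplies one uniformly
chosen parameter by exp(u), u ~ Uniform(-step_scale, step_scale), and is
accepted only if the fitness under a deterministic sinusoidal influx
improves.  Optimizing against the predictable sinusoid keeps the
objective cheap and deterministic; the resulting strategies are then
evaluated under stochastic walks elsewhere.

The constitutive strategy has a single knob — the constant AMP level A —
and is optimized by exhaustive scan of the grid 0.01..2 (step 0.01)
using Euler integration with h = 0.01, averaging fitness across walks
when the input is a stochastic environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import _kernels
from .encounters import WalkConfig, simulate_walk
from .environments import Environment
from .fitness import FitnessWeights, induced_cost
from .imd_model import COMPONENTS, ImdParameters, ImdState, IntegrationError, _input_values

__all__ = [
    "FREE_PARAMETERS",
    "DEFAULT_A_GRID",
    "OptimizerConfig",
    "OptimizedStrategy",
    "sinusoidal_induced_fitness",
    "optimize_induced",
    "constitutive_fitness_curve",
    "optimize_constitutive",
    "optimize_constitutive_multi",
]

#: The 11 parameters free during induced-defense optimization.
FREE_PARAMETERS = (
    "lambda2", "lambda3", "R0",
    "beta1", "beta2", "beta3", "beta4", "beta5", "beta6",
    "Zn", "Zs",
)

#: AMP levels scanned for the constitutive defense: 0.01..2.00, step 0.01.
DEFAULT_A_GRID = np.round(np.arange(1, 201) * 0.01, 10)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings of the stochastic hill-climb.

    ``t_end`` defaults to ten half-periods of the sinusoid (10*pi/phi)
    capped at ``t_end_cap`` so slow oscillations stay affordable;
    ``bounds`` are enforced by rejecting proposals that leave them and
    ``init_range`` is the log-uniform support of each restart's start.
    """

    n_iterations: int = 2_000
    n_restarts: int = 3
    step_scale: float = 0.5
    bounds: tuple = (1e-4, 1e2)
    init_range: tuple = (0.01, 10.0)
    t_end: Optional[float] = None
    t_end_cap: float = 2_000.0
    omega: float = 1.0
    h: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_restarts < 1:
            raise ValueError("n_iterations and n_restarts must be >= 1")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError(f"bounds must satisfy 0 < low < high, got {self.bounds}")
        if self.t_end is not None and self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.omega < 0 or self.h <= 0:
            raise ValueError("omega must be >= 0 and h > 0")

    def horizon(self, phi: float) -> float:
        """Evaluation horizon snapped to an integer number of Euler steps."""
        t = self.t_end if self.t_end is not None else min(10.0 * math.pi / phi, self.t_end_cap)
        return round(t / self.h) * self.h


@dataclass
class OptimizedStrategy:
    """An optimized defense: parameters, achieved fitness, provenance.

    ``params`` is an :class:`ImdParameters` for the induced strategy or
    the scalar AMP level for the constitutive one.  ``history`` holds the
    accepted-fitness sequence of each hill-climb restart; ``curve`` and
    ``grid`` retain the per-A fitness scan of the constitutive search.
    """

    params: Union[ImdParameters, float]
    fitness: float
    provenance: dict = field(default_factory=dict)
    history: Optional[list] = None
    curve: Optional[np.ndarray] = None
    grid: Optional[np.ndarray] = None


def sinusoidal_induced_cost(
    params: ImdParameters,
    omega: float,
    phi: float,
    t_end: float,
    h: float = 0.01,
    weights: FitnessWeights | None = None,
    _f_cache: np.ndarray | None = None,
) -> float:
    """Summed time-averaged cost (-log fitness) under sinusoidal input.

    Integrates from a zero start with Euler steps of size ``h`` over
    [0, t_end].  The optimizer compares costs rather than fitness values
    so that deep in the low-fitness regime (where ``exp(-cost)``
    underflows to zero) improvements remain visible.  Returns NaN when
    the integration blows up.
    """
    n = int(round(t_end / h))
    f_vals = _f_cache if _f_cache is not None else omega * np.sin(np.arange(n) * h * phi) ** 2
    means, _, bad_step, _ = _kernels.euler_induced_means(
        ImdState().as_array(), params.packed(), f_vals, 1, h, True
    )
    if bad_step >= 0:
        return float("nan")
    return induced_cost(dict(zip(COMPONENTS, means)), weights)


def sinusoidal_induced_fitness(
    params: ImdParameters,
    omega: float,
    phi: float,
    t_end: float,
    h: float = 0.01,
    weights: FitnessWeights | None = None,
    _f_cache: np.ndarray | None = None,
) -> float:
    """Induced fitness under f(t) = omega*sin(t*phi)^2 from a zero start."""
    cost = sinusoidal_induced_cost(params, omega, phi, t_end, h, weights, _f_cache)
    return math.exp(-cost) if math.isfinite(cost) else float("nan")


def optimize_induced(
    phi: float,
    k0: float,
    alpha: float,
    cfg: OptimizerConfig,
    lambda1: float = 0.01,
    weights: FitnessWeights | None = None,
    free: Sequence[str] = FREE_PARAMETERS,
    base: ImdParameters | None = None,
) -> OptimizedStrategy:
    """Hill-climb the free induced-model parameters under sinusoidal input.

    Parameters
    ----------
    phi, k0, alpha, lambda1
        Encounter frequency and the fixed bacterial parameters.
    cfg
        Optimizer settings; ``cfg.seed`` makes the run reproducible.
    free
        Names of the parameters to optimize (defaults to all 11); the
        rest stay at ``base`` values.  A reduced list gives the
        low-dimensional landscapes used for validation.
    base
        Template for the non-free parameters (defaults to package
        defaults with the given alpha, k0, lambda1).

    Returns
    -------
    OptimizedStrategy
        Best parameters over all restarts, with the accepted-fitness
        sequence of each restart in ``history``.
    """
    for name in free:
        if name not in FREE_PARAMETERS:
            raise ValueError(f"{name!r} is not a free parameter; choose from {FREE_PARAMETERS}")
    base = (base or ImdParameters()).replace(alpha=alpha, k0=k0, lambda1=lambda1)
    t_end = cfg.horizon(phi)
    n = int(round(t_end / cfg.h))
    f_vals = cfg.omega * np.sin(np.arange(n) * cfg.h * phi) ** 2
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    log_init = (math.log(cfg.init_range[0]), math.log(cfg.init_range[1]))

    def evaluate(values: np.ndarray) -> float:
        params = base.replace(**dict(zip(free, values)))
        return sinusoidal_induced_cost(
            params, cfg.omega, phi, t_end, cfg.h, weights, _f_cache=f_vals
        )

    # the climb compares costs (-log fitness): strictly equivalent to
    # comparing fitness, but immune to exp underflow far from the optimum
    best_values: np.ndarray | None = None
    best_cost = math.inf
    history: list = []
    for _ in range(cfg.n_restarts):
        values = np.exp(rng.uniform(log_init[0], log_init[1], size=len(free)))
        current = evaluate(values)
        accepted = [math.exp(-current)]
        for _ in range(cfg.n_iterations):
            idx = rng.integers(len(free))
            u = rng.uniform(-cfg.step_scale, cfg.step_scale)
            proposal = values[idx] * math.exp(u)
            if not lo <= proposal <= hi:
                continue
            trial = values.copy()
            trial[idx] = proposal
            c_trial = evaluate(trial)
            if math.isfinite(c_trial) and c_trial < current:
                values, current = trial, c_trial
                accepted.append(math.exp(-current))
        history.append(accepted)
        if current < best_cost:
            best_cost, best_values = current, values

    params = base.replace(**dict(zip(free, best_values)))
    return OptimizedStrategy(
        params=params,
        fitness=float(math.exp(-best_cost)),
        provenance={
            "phi": phi, "k0": k0, "alpha": alpha, "lambda1": lambda1,
            "omega": cfg.omega, "t_end": t_end, "h": cfg.h,
            "n_iterations": cfg.n_iterations, "n_restarts": cfg.n_restarts,
            "step_scale": cfg.step_scale, "seed": cfg.seed,
            "free": list(free),
            "weights": (weights or FitnessWeights()).to_dict(),
        },
        history=history,
    )


def constitutive_fitness_curve(
    source: Union[Environment, Callable, float],
    k0: float,
    grid: np.ndarray = DEFAULT_A_GRID,
    walk_cfg: WalkConfig | None = None,
    t_end: float | None = None,
    h: float = 0.01,
    B0: float = 0.0,
) -> np.ndarray:
    """Mean constitutive fitness at every AMP level of the grid.

    With an :class:`Environment` the curve averages ``exp(-(B̄ + A))``
    over ``walk_cfg.n_walks`` stochastic sojourns; with a deterministic
    input (callable or constant) a single Euler integration over
    ``[0, t_end]`` is used.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("the A grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("the A grid must be strictly increasing")
    if isinstance(source, Environment):
        if walk_cfg is None:
            raise ValueError("a WalkConfig is required to scan an Environment")
        m = int(round(walk_cfg.dt_per_step / h))
        if m < 1 or abs(m * h - walk_cfg.dt_per_step) > 1e-9 * walk_cfg.dt_per_step:
            raise ValueError("h must divide dt_per_step evenly")
        acc = np.zeros(grid.shape)
        for walk in range(walk_cfg.n_walks):
            series = simulate_walk(source, walk_cfg, walk)
            b_means = _kernels.euler_constitutive_grid_means(
                B0, grid, k0, series.influx, m, h, True
            )
            if not np.all(np.isfinite(b_means)):
                raise IntegrationError(f"walk {walk}: non-finite bacterial density")
            acc += np.exp(-(b_means + grid))
        return acc / walk_cfg.n_walks
    if t_end is None:
        raise ValueError("t_end is required for a deterministic input")
    n = int(round(t_end / h))
    f_vals = _input_values(source, np.arange(n) * h)
    b_means = _kernels.euler_constitutive_grid_means(B0, grid, k0, f_vals, 1, h, True)
    if not np.all(np.isfinite(b_means)):
        raise IntegrationError("non-finite bacterial density in deterministic scan")
    return np.exp(-(b_means + grid))


def _argmax_smallest(curve: np.ndarray) -> int:
    # np.argmax returns the first maximum; with an ascending grid that is
    # the smallest A, i.e. the cheaper defense wins ties.
    return int(np.argmax(curve))


def optimize_constitutive(
    source: Union[Environment, Callable, float],
    k0: float,
    grid: np.ndarray = DEFAULT_A_GRID,
    walk_cfg: WalkConfig | None = None,
    t_end: float | None = None,
    h: float = 0.01,
) -> OptimizedStrategy:
    """Grid search for the constant AMP level with the highest fitness.

    Ties are broken toward the smaller (cheaper) AMP level.  The scanned
    fitness curve is kept on the returned strategy so that
    multi-environment analyses can re-optimize mixtures without
    re-simulating.
    """
    grid = np.asarray(grid, dtype=float)
    curve = constitutive_fitness_curve(source, k0, grid, walk_cfg, t_end, h)
    idx = _argmax_smallest(curve)
    provenance = {"k0": k0, "grid_min": float(grid[0]), "grid_max": float(grid[-1]),
                  "grid_size": int(grid.size), "h": h}
    if isinstance(source, Environment):
        provenance["environment"] = source.spec.to_dict()
        provenance["walks"] = walk_cfg.to_dict()
    else:
        provenance["t_end"] = t_end
    return OptimizedStrategy(
        params=float(grid[idx]),
        fitness=float(curve[idx]),
        provenance=provenance,
        curve=curve,
        grid=grid,
    )


def optimize_constitutive_multi(
    curves: Sequence[np.ndarray],
    probabilities: Sequence[float],
    grid: np.ndarray = DEFAULT_A_GRID,
) -> OptimizedStrategy:
    """Best single AMP level across several environments.

    ``curves`` are per-environment fitness curves on the shared ``grid``
    (from :func:`constitutive_fitness_curve`); the optimum maximizes the
    probability-weighted mean curve, reflecting that one constitutive
    level must serve every environment the fly may inhabit.
    """
    grid = np.asarray(grid, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    if len(curves) != probs.size:
        raise ValueError("one probability per environment is required")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")
    stacked = np.vstack([np.asarray(c, dtype=float) for c in curves])
    if stacked.shape[1] != grid.size:
        raise ValueError("curves must be evaluated on the supplied grid")
    mixture = probs @ stacked
    idx = _argmax_smallest(mixture)
    return OptimizedStrategy(
        params=float(grid[idx]),
        fitness=float(mixture[idx]),
        provenance={"n_environments": len(curves), "probabilities": probs.tolist()},
        curve=mixture,
        grid=grid,
    )
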
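"""Experiment designs comparing induced and constitutive defenses.

Three families of analyses are provided:

* **Fitness grids** — for every (density, patchiness) combination an
  environment is generated, both strategies run stochastic sojourns
  through it (the constitutive strategy at its per-environment grid
  optimum), and the proportion of cells in which induction wins (PIW)
  summarizes the grid.
* **Multi-environment fluctuation** — repeated sampling of j
  environments (without replacement, equal weights; or two environments
  with weights q and 1-q) from a pool in which constitutive defense wins
  each environment in isolation, asking how often the induced strategy
  wins once a single constitutive AMP level must serve all of them.
* **Negative-regulator perturbations** — scaling the PGRP-LB/Pirk
  production rates (beta3, beta4) by gamma, or the repressosome binding
  energy Zs by delta, and measuring the effect on PIW or on the
  fitness-maximizing delta per environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import split_seed
from .encounters import WalkConfig, run_encounter_simulation
from .environments import Environment, EnvironmentSpec, generate_environment
from .fitness import FitnessWeights, mean_induced_fitness
from .imd_model import ImdParameters, IntegratorConfig
from .optimization import (
    DEFAULT_A_GRID,
    OptimizedStrategy,
    constitutive_fitness_curve,
)

__all__ = [
    "FitnessGrid",
    "MultiEnvConfig",
    "PerturbationConfig",
    "evaluate_environment",
    "run_fitness_grid",
    "compute_piw",
    "sample_multi_environment",
    "gamma_scan",
    "delta_scan",
]


@dataclass
class FitnessGrid:
    """Strategy fitness over a (density x patchiness) grid of environments."""

    densities: list
    patchiness_levels: list
    F_induced: np.ndarray
    F_constitutive: np.ndarray
    A_opt: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.densities), len(self.patchiness_levels))
        for name in ("F_induced", "F_constitutive", "A_opt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    @property
    def delta_F(self) -> np.ndarray:
        return self.F_constitutive - self.F_induced

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.densities):
            for j, p in enumerate(self.patchiness_levels):
                rows.append(
                    {
                        "density": d,
                        "patchiness": p,
                        "F_induced": self.F_induced[i, j],
                        "F_constitutive": self.F_constitutive[i, j],
                        "delta_F": self.delta_F[i, j],
                        "A_opt": self.A_opt[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MultiEnvConfig:
    """Resampling design for the multi-environment fluctuation analysis.

    ``j`` environments are drawn without replacement per repeat and
    visited with equal probabilities; alternatively ``q`` selects the
    two-environment mode with visit probabilities (q, 1-q).
    """

    j: int = 2
    n_repeats: int = 10_000
    q: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ValueError("j must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.q is not None and not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")


@dataclass(frozen=True)
class PerturbationConfig:
    """Scan of the negative-feedback perturbation multipliers.

    ``gammas`` multiply the PGRP-LB and Pirk production rates (beta3 and
    beta4); ``deltas`` multiply the repressosome binding energy Zs.
    """

    gammas: tuple = (1.0,)
    deltas: tuple = (1.0, 2.0, 4.0, 10.0)

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gammas):
            raise ValueError("gamma values must be positive")
        if any(d <= 0 for d in self.deltas):
            raise ValueError("delta values must be positive")


def _induced_params(strategy: Union[OptimizedStrategy, ImdParameters]) -> ImdParameters:
    params = strategy.params if isinstance(strategy, OptimizedStrategy) else strategy
    if not isinstance(params, ImdParameters):
        raise TypeError("an induced strategy (ImdParameters) is required")
    return params


def evaluate_environment(
    induced: Union[OptimizedStrategy, ImdParameters],
    k0: float,
    env: Environment,
    walk_cfg: WalkConfig,
    grid: np.ndarray = DEFAULT_A_GRID,
    weights: FitnessWeights | None = None,
    integrator: IntegratorConfig | None = None,
) -> dict:
    """Fitness of both strategies in one environment.

    Both strategies experience the same batch of random walks (same walk
    seeds).  The constitutive strategy is set to its per-environment
    grid optimum.  Returns a dict with ``F_induced``, ``F_constitutive``,
    ``A_opt``, ``delta_F`` and the scanned constitutive ``curve``.
    """
    params = _induced_params(induced).replace(k0=k0)
    h = integrator.h if integrator is not None else 0.01
    means = run_encounter_simulation("induced", params, env, walk_cfg, integrator)
    f_ind = mean_induced_fitness(means, weights)
    curve = constitutive_fitness_curve(env, k0, grid, walk_cfg, h=h)
    idx = int(np.argmax(curve))
    f_con = float(curve[idx])
    return {
        "F_induced": f_ind,
        "F_constitutive": f_con,
        "A_opt": float(np.asarray(grid)[idx]),
        "delta_F": f_con - f_ind,
        "curve": curve,
    }


def run_fitness_grid(
    induced: Union[OptimizedStrategy, ImdParameters],
    k0: float,
    densities: Sequence[int],
    patchiness_levels: Sequence[int],
    walk_cfg: WalkConfig,
    grid: np.ndarray = DEFAULT_A_GRID,
    weights: FitnessWeights | None = None,
    size: int = 100,
    cluster_sd: float = 3.0,
    seed: int = 0,
) -> FitnessGrid:
    """Fitness of both strategies over a (density x patchiness) grid.

    One environment is realized per cell (seeded from ``seed`` and the
    cell coordinates); both strategies traverse it with
    ``walk_cfg.n_walks`` sojourns.  Cells with ``patchiness > density``
    are clamped to one cluster per colony (the uniform limit), and zero
    density cells use a sterile lattice.
    """
    nd, np_ = len(densities), len(patchiness_levels)
    F_i = np.zeros((nd, np_))
    F_c = np.zeros((nd, np_))
    A_o = np.zeros((nd, np_))
    for i, d in enumerate(densities):
        for j, p in enumerate(patchiness_levels):
            spec = EnvironmentSpec(
                density=int(d),
                patchiness=max(1, min(int(p), int(d))) if d > 0 else 1,
                size=size,
                cluster_sd=cluster_sd,
                seed=split_seed(seed, "env", d, p),
            )
            env = generate_environment(spec)
            cell_walks = WalkConfig(
                **{**walk_cfg.to_dict(), "seed": split_seed(seed, "walks", d, p)}
            )
            res = evaluate_environment(induced, k0, env, cell_walks, grid, weights)
            F_i[i, j] = res["F_induced"]
            F_c[i, j] = res["F_constitutive"]
            A_o[i, j] = res["A_opt"]
    strategy_prov = (
        induced.provenance if isinstance(induced, OptimizedStrategy) else {}
    )
    return FitnessGrid(
        densities=list(densities),
        patchiness_levels=list(patchiness_levels),
        F_induced=F_i,
        F_constitutive=F_c,
        A_opt=A_o,
        provenance={
            "k0": k0,
            "seed": seed,
            "size": size,
            "cluster_sd": cluster_sd,
            "walks": walk_cfg.to_dict(),
            "induced_strategy": strategy_prov,
            "weights": (weights or FitnessWeights()).to_dict(),
        },
    )


def compute_piw(grid_or_outcomes) -> float:
    """Proportion of induced wins.

    Accepts a :class:`FitnessGrid` (a cell is a win when
    ``F_induced > F_constitutive``; ties count as constitutive wins) or
    any array of win/loss booleans.
    """
    if isinstance(grid_or_outcomes, FitnessGrid):
        wins = grid_or_outcomes.F_induced > grid_or_outcomes.F_constitutive
    else:
        wins = np.asarray(grid_or_outcomes, dtype=bool)
    if wins.size == 0:
        raise ValueError("cannot compute PIW of an empty set of outcomes")
    return float(wins.mean())


def sample_multi_environment(
    cfg: MultiEnvConfig,
    induced_fitness: Sequence[float],
    constitutive_curves: Sequence[np.ndarray],
) -> float:
    """PIW when the fly inhabits several environments at once.

    ``induced_fitness`` holds the per-environment induced fitness of the
    pool and ``constitutive_curves`` the per-environment fitness scans
    over the shared AMP grid.  Each repeat draws ``cfg.j`` environments
    without replacement (or two environments visited with probabilities
    ``q`` and ``1-q``); the induced strategy scores the (weighted) mean
    of its per-environment fitness, while the constitutive strategy is
    re-optimized for the mixture: the maximum over the AMP grid of the
    (weighted) mean fitness curve.  Returns the fraction of repeats in
    which induction strictly wins.
    """
    f_ind = np.asarray(induced_fitness, dtype=float)
    curves = np.vstack([np.asarray(c, dtype=float) for c in constitutive_curves])
    n_env = f_ind.size
    if curves.shape[0] != n_env:
        raise ValueError("need one constitutive curve per environment")
    j = 2 if cfg.q is not None else cfg.j
    if j > n_env:
        raise ValueError(f"cannot draw {j} environments from a pool of {n_env}")
    rng = np.random.default_rng(cfg.seed)
    weights = (
        np.array([cfg.q, 1.0 - cfg.q]) if cfg.q is not None else np.full(j, 1.0 / j)
    )
    wins = 0
    for _ in range(cfg.n_repeats):
        idx = rng.choice(n_env, size=j, replace=False)
        fi = float(weights @ f_ind[idx])
        fc = float((weights @ curves[idx]).max())
        if fi > fc:
            wins += 1
    return wins / cfg.n_repeats


def gamma_scan(
    base: Union[OptimizedStrategy, ImdParameters],
    cfg: PerturbationConfig,
    k0_values: Sequence[float],
    environments: Sequence[Environment],
    walk_cfg: WalkConfig,
    grid: np.ndarray = DEFAULT_A_GRID,
    weights: FitnessWeights | None = None,
) -> pd.DataFrame:
    """PIW as the PGRP-LB/Pirk production rates are rescaled.

    For every gamma the optimized beta3 and beta4 are multiplied by
    gamma and PIW is recomputed across the supplied environments at each
    bacterial proliferation rate.  The constitutive opponent (which
    gamma does not touch) is optimized once per (environment, k0).
    Returns a tidy frame with columns gamma, k0, piw.
    """
    base_params = _induced_params(base)
    rows = []
    for k0 in k0_values:
        const_best = []
        for env in environments:
            curve = constitutive_fitness_curve(env, k0, grid, walk_cfg)
            const_best.append(float(curve.max()))
        for gamma in cfg.gammas:
            perturbed = base_params.replace(
                beta3=gamma * base_params.beta3,
                beta4=gamma * base_params.beta4,
                k0=k0,
            )
            outcomes = []
            for env, fc in zip(environments, const_best):
                means = run_encounter_simulation("induced", perturbed, env, walk_cfg)
                outcomes.append(mean_induced_fitness(means, weights) > fc)
            rows.append({"gamma": gamma, "k0": k0, "piw": compute_piw(outcomes)})
    return pd.DataFrame(rows)


def best_gamma(scan: pd.DataFrame) -> dict:
    """Fitness-maximizing gamma per proliferation rate (first max wins)."""
    out = {}
    for k0, sub in scan.groupby("k0"):
        sub = sub.sort_values("gamma")
        out[float(k0)] = float(sub.loc[sub["piw"].idxmax(), "gamma"])
    return out


def delta_scan(
    base: Union[OptimizedStrategy, ImdParameters],
    cfg: PerturbationConfig,
    k0_values: Sequence[float],
    environments: Sequence[Environment],
    walk_cfg: WalkConfig,
    weights: FitnessWeights | None = None,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """Fitness-maximizing repressosome binding-energy multiplier per environment.

    For each environment and proliferation rate the induced fitness is
    evaluated with Zs multiplied by every delta in the scan (which must
    include the unperturbed delta = 1); the best delta is recorded with
    ties broken toward the smallest delta.  ``gamma`` optionally rescales
    beta3/beta4 first, for the low-PGRP-LB/Pirk variant of the analysis.
    Returns a tidy frame with one row per (environment, k0, delta) and a
    ``best`` flag; counts of best deltas per k0 partition the
    environments.
    """
    if 1.0 not in cfg.deltas:
        raise ValueError("the delta scan must include the unperturbed value 1")
    base_params = _induced_params(base)
    if gamma != 1.0:
        base_params = base_params.replace(
            beta3=gamma * base_params.beta3, beta4=gamma * base_params.beta4
        )
    rows = []
    for k0 in k0_values:
        for env_id, env in enumerate(environments):
            fits = []
            for delta in cfg.deltas:
                perturbed = base_params.replace(Zs=delta * base_params.Zs, k0=k0)
                means = run_encounter_simulation("induced", perturbed, env, walk_cfg)
                fits.append(mean_induced_fitness(means, weights))
            best_idx = int(np.argmax(fits))  # first max = smallest delta
            for i, (delta, fit) in enumerate(zip(cfg.deltas, fits)):
                rows.append(
                    {
                        "k0": k0,
                        "environment": env_id,
                        "delta": delta,
                        "F_induced": fit,
                        "best": i == best_idx,
                    }
                )
    return pd.DataFrame(rows)


def delta_counts(scan: pd.DataFrame) -> pd.DataFrame:
    """Number of environments per (k0, delta) in which that delta is best."""
    best = scan[scan["best"]]
    return (
        best.groupby(["k0", "delta"]).size().rename("n_environments").reset_index()
    )
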
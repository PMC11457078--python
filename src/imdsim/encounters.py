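"""Encounter inputs f(t): sinusoidal forcing and random walks on a lattice.

The fly either experiences a deterministic oscillating bacterial influx
``f(t) = omega * sin(t * phi)**2`` or performs an unbiased random walk
across an :class:`~imdsim.environments.Environment`.  During a walk the
influx is piecewise constant: while the fly occupies a cell holding
colonies it ingests ``dose`` bacteria per unit time per colony, and zero
otherwise.  Colonies are not depleted by visits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .environments import Environment
from .imd_model import (
    COMPONENTS,
    ConstitutiveParameters,
    ImdParameters,
    ImdState,
    IntegrationError,
    IntegratorConfig,
)

__all__ = [
    "SinusoidalInput",
    "WalkConfig",
    "EncounterSeries",
    "sinusoidal_f",
    "simulate_walk",
    "run_encounter_simulation",
]

_NEIGHBORHOODS = {
    "von_neumann": np.array([[1, 0], [-1, 0], [0, 1], [0, -1]]),
    "moore": np.array(
        [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1]]
    ),
}


@dataclass(frozen=True)
class SinusoidalInput:
    """Deterministic oscillating influx ``f(t) = omega * sin(t*phi)**2``.

    ``omega`` sets the amount of bacteria per encounter burst and
    ``phi`` the encounter frequency.
    """

    omega: float = 1.0
    phi: float = 0.01

    def __post_init__(self) -> None:
        if not (math.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be non-negative, got {self.omega!r}")
        if not (math.isfinite(self.phi) and self.phi > 0):
            raise ValueError(f"phi must be positive, got {self.phi!r}")

    def __call__(self, t):
        return sinusoidal_f(self, t)

    def to_dict(self) -> dict:
        return {"omega": self.omega, "phi": self.phi}


def sinusoidal_f(inp: SinusoidalInput, t):
    """Evaluate the sinusoidal influx at time(s) ``t`` (scalar or array)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = inp.omega * np.sin(t_arr * inp.phi) ** 2
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class WalkConfig:
    """Settings for random-walk sojourns through an environment.

    ``dt_per_step`` is the simulated time spent on each lattice cell and
    ``dose`` the bacterial influx rate per colony in the occupied cell.
    Walk ``i`` of a batch is seeded from ``(seed, i)``, so individual
    walks are reproducible and independent of how many walks run.
    """

    n_steps: int = 5_000
    n_walks: int = 100
    dt_per_step: float = 1.0
    dose: float = 1.0
    neighborhood: str = "von_neumann"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.n_walks < 1:
            raise ValueError(f"n_walks must be >= 1, got {self.n_walks}")
        if not (math.isfinite(self.dt_per_step) and self.dt_per_step > 0):
            raise ValueError(f"dt_per_step must be positive, got {self.dt_per_step!r}")
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise ValueError(f"dose must be non-negative, got {self.dose!r}")
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ValueError(
                f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}, got {self.neighborhood!r}"
            )

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "n_walks": self.n_walks,
            "dt_per_step": self.dt_per_step,
            "dose": self.dose,
            "neighborhood": self.neighborhood,
            "seed": self.seed,
        }


@dataclass
class EncounterSeries:
    """Piecewise-constant influx produced by one walk.

    ``influx[i]`` applies on the interval ``[times[i], times[i+1])``;
    ``walk_path`` holds the visited cells (one more entry than steps).
    """

    times: np.ndarray
    influx: np.ndarray
    walk_path: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.influx = np.asarray(self.influx, dtype=float)
        if self.times.shape[0] != self.influx.shape[0] + 1:
            raise ValueError("times must have one more entry than influx")
        if self.influx.size and self.influx.min() < 0:
            raise ValueError("influx values must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def total_ingested(self) -> float:
        """Integral of f over the walk (dose-weighted colony occupancy)."""
        return float(self.influx.sum() * self.dt)

    def values_at(self, t) -> np.ndarray:
        """Evaluate the piecewise-constant influx at time(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip((t_arr / self.dt).astype(int), 0, self.influx.shape[0] - 1)
        out = self.influx[idx]
        return out if np.ndim(t) else float(out[0])

    def __call__(self, t):
        return self.values_at(t)


def simulate_walk(env: Environment, cfg: WalkConfig, walk_index: int = 0) -> EncounterSeries:
    """Simulate one random-walk sojourn and its encounter series.

    The fly starts at a uniformly random cell and moves to a uniformly
    random neighboring cell each step (toroidal wrap).  The influx on
    step ``i`` is ``dose * colony_count`` of the occupied cell.
    """
    if not 0 <= walk_index < cfg.n_walks:
        raise ValueError(f"walk_index must be in [0, {cfg.n_walks}), got {walk_index}")
    rng = np.random.default_rng([cfg.seed, walk_index])
    size = env.spec.size
    dirs = _NEIGHBORHOODS[cfg.neighborhood]
    start = rng.integers(0, size, size=2)
    moves = dirs[rng.integers(0, len(dirs), size=cfg.n_steps)]
    path = (start + np.vstack([[0, 0], np.cumsum(moves, axis=0)])) % size
    influx = cfg.dose * env.counts[path[:-1, 0], path[:-1, 1]].astype(float)
    times = np.arange(cfg.n_steps + 1) * cfg.dt_per_step
    return EncounterSeries(times=times, influx=influx, walk_path=path)


def _substeps(cfg: WalkConfig, integrator: IntegratorConfig) -> int:
    m = int(round(cfg.dt_per_step / integrator.h))
    if m < 1 or abs(m * integrator.h - cfg.dt_per_step) > 1e-9 * cfg.dt_per_step:
        raise ValueError(
            f"integrator step h={integrator.h} must divide dt_per_step={cfg.dt_per_step} evenly"
        )
    return m


def run_encounter_simulation(
    model: str,
    params,
    env: Environment,
    cfg: WalkConfig,
    integrator: IntegratorConfig | None = None,
    init=None,
) -> pd.DataFrame:
    """Run all walks of a batch and return per-walk time-averaged states.

    Returns a DataFrame indexed by walk with one column per model
    component (nine for the induced model, ``B`` for the constitutive
    one) holding arithmetic time averages over the whole sojourn — the
    inputs to the fitness functions.  Walks are integrated with the
    fixed-step Euler scheme.
    """
    total_time = cfg.n_steps * cfg.dt_per_step
    if integrator is None:
        integrator = IntegratorConfig(t_end=total_time)
    if integrator.method != "euler":
        raise ValueError("stochastic walks use the fixed-step Euler path")
    m = _substeps(cfg, integrator)
    rows = []
    for walk in range(cfg.n_walks):
        series = simulate_walk(env, cfg, walk)
        if model == "induced":
            if not isinstance(params, ImdParameters):
                raise TypeError("induced model requires ImdParameters")
            y0 = ImdState().as_array() if init is None else np.asarray(init, dtype=float)
            means, _, bad_step, bad_comp = _kernels.euler_induced_means(
                y0.copy(), params.packed(), series.influx, m, integrator.h,
                integrator.clip_negative,
            )
            if bad_step >= 0:
                raise IntegrationError(
                    f"walk {walk}: non-finite {COMPONENTS[bad_comp]} at influx step {bad_step}"
                )
            rows.append(dict(zip(COMPONENTS, means)))
        elif model == "constitutive":
            if not isinstance(params, ConstitutiveParameters):
                raise TypeError("constitutive model requires ConstitutiveParameters")
            B0 = 0.0 if init is None else float(init)
            means = _kernels.euler_constitutive_grid_means(
                B0, np.array([params.A]), params.k0, series.influx, m, integrator.h,
                integrator.clip_negative,
            )
            if not np.isfinite(means[0]):
                raise IntegrationError(f"walk {walk}: non-finite bacterial density")
            rows.append({"B": float(means[0])})
        else:
            raise ValueError(f"unknown model {model!r}")
    out = pd.DataFrame(rows)
    out.index.name = "walk"
    return out
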
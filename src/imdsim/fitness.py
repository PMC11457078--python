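"""Fitness of induced and constitutive defense strategies.

Fitness declines exponentially with the summed time-averaged burden of
infection and immunity.  For the induced strategy the full cost is

    F_induced = exp(-(B̄ + N̄ + L̄ + P̄ + S̄ + Ā))

(free peptidoglycan, free receptors and the receptor complex carry no
cost), while the constitutive strategy pays for its constant AMP level:

    F_constitutive = exp(-(B̄ + A)).

An alternative ``amp_only`` mode prices only AMPs and bacteria,
exp(-(wA*Ā + wB*B̄)), for asking whether immunopathology or bacterial
load dominates.  Across a batch of walks the strategy fitness is the
arithmetic mean of per-walk fitness values (not the fitness of mean
components — the exponential makes the order of operations matter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .imd_model import Trajectory

__all__ = [
    "COST_COMPONENTS",
    "FitnessWeights",
    "FitnessResult",
    "time_average",
    "fitness_induced",
    "fitness_constitutive",
    "delta_fitness",
    "induced_fitness_per_walk",
    "mean_induced_fitness",
    "mean_constitutive_fitness",
]

#: Components entering the full-cost induced fitness.
COST_COMPONENTS = ("B", "N", "L", "P", "S", "A")


@dataclass(frozen=True)
class FitnessWeights:
    """Choice of fitness function for the induced strategy.

    ``full_cost`` sums the six costed component means with unit weights.
    ``amp_only`` uses ``exp(-(weight_A*Ā + weight_B*B̄))`` so either the
    immunopathology (A) or the bacterial-load (B) term can be doubled.
    """

    mode: str = "full_cost"
    weight_A: float = 1.0
    weight_B: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("full_cost", "amp_only"):
            raise ValueError(f"mode must be 'full_cost' or 'amp_only', got {self.mode!r}")
        if self.weight_A <= 0 or self.weight_B <= 0:
            raise ValueError("fitness weights must be positive")
        if self.mode == "full_cost" and (self.weight_A != 1.0 or self.weight_B != 1.0):
            raise ValueError("full_cost mode uses unit weights on every component")

    def to_dict(self) -> dict:
        return {"mode": self.mode, "weight_A": self.weight_A, "weight_B": self.weight_B}


@dataclass
class FitnessResult:
    """Paired strategy fitness values and the component means behind them."""

    F_induced: float
    F_constitutive: float
    component_means: dict

    @property
    def delta_F(self) -> float:
        return self.F_constitutive - self.F_induced


def time_average(traj: Trajectory, component: str) -> float:
    """Arithmetic mean of one component over the recorded time points."""
    if traj.times.size == 0:
        raise ValueError("cannot average an empty trajectory")
    return float(traj.component(component).mean())


def _cost(means: Mapping[str, float], weights: FitnessWeights) -> float:
    if weights.mode == "full_cost":
        cost = 0.0
        for name in COST_COMPONENTS:
            value = means[name]
            if value < 0:
                raise ValueError(f"component mean {name} is negative: {value}")
            cost += value
        return cost
    a_bar, b_bar = means["A"], means["B"]
    if a_bar < 0 or b_bar < 0:
        raise ValueError("component means must be non-negative")
    return weights.weight_A * a_bar + weights.weight_B * b_bar


def induced_cost(means: Mapping[str, float], weights: FitnessWeights | None = None) -> float:
    """Summed (weighted) cost of the induced strategy: -log fitness.

    Comparisons on the cost scale stay meaningful where ``exp(-cost)``
    would underflow, which matters to the optimizer.
    """
    return _cost(means, weights or FitnessWeights())


def fitness_induced(means: Mapping[str, float], weights: FitnessWeights | None = None) -> float:
    """Fitness of the induced strategy from its time-averaged components."""
    return math.exp(-induced_cost(means, weights))


def fitness_constitutive(B_mean: float, A_const: float) -> float:
    """Fitness of a constitutive defense: ``exp(-(B̄ + A))``.

    The cost uses the constant AMP level itself — the time average of a
    constant — so no trajectory of A is needed.
    """
    if B_mean < 0 or A_const < 0:
        raise ValueError("B_mean and A_const must be non-negative")
    return math.exp(-(B_mean + A_const))


def delta_fitness(F_constitutive: float, F_induced: float) -> float:
    """Signed fitness difference; negative means the induced strategy wins."""
    return F_constitutive - F_induced


def induced_fitness_per_walk(
    means: pd.DataFrame, weights: FitnessWeights | None = None
) -> np.ndarray:
    """Per-walk induced fitness from a frame of per-walk component means."""
    weights = weights or FitnessWeights()
    if weights.mode == "full_cost":
        cost = means.loc[:, list(COST_COMPONENTS)].sum(axis=1).to_numpy()
    else:
        cost = (
            weights.weight_A * means["A"].to_numpy()
            + weights.weight_B * means["B"].to_numpy()
        )
    if cost.size and cost.min() < 0:
        raise ValueError("component means must be non-negative")
    return np.exp(-cost)


def mean_induced_fitness(means: pd.DataFrame, weights: FitnessWeights | None = None) -> float:
    """Arithmetic mean of per-walk induced fitness across a walk batch."""
    return float(induced_fitness_per_walk(means, weights).mean())


def mean_constitutive_fitness(B_means: Iterable[float], A_const: float) -> float:
    """Arithmetic mean of per-walk constitutive fitness across a batch."""
    b = np.asarray(list(B_means), dtype=float)
    if b.size == 0:
        raise ValueError("need at least one walk")
    if b.min() < 0 or A_const < 0:
        raise ValueError("B means and A_const must be non-negative")
    return float(np.exp(-(b + A_const)).mean())
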
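"""Mechanistic model of the Drosophila Imd immune signaling pathway.

The induced model couples nine state variables through ordinary
differential equations: bacteria in the gut (``B``), free peptidoglycan
(``G``), free cell-surface receptors (``R``), the receptor–peptidoglycan
complex (``C``), active Relish (``N``), the peptidoglycan scavenger
PGRP-LB (``L``), Pirk (``P``), the repressosome complex (``S``), and
antimicrobial peptides (``A``).  Bacteria enter the gut at an externally
supplied rate ``f(t)``, proliferate at rate ``k0`` and are killed by AMPs
at rate ``A*B``.  Relish-dependent transcription is modeled with a
saturating occupancy term ``N/(N + Zn)`` in which the binding energy
``Zn`` is inversely proportional to the binding probability; the
repressosome competes with Relish at the AMP promoter, which adds a
``Zn*S/Zs`` term to the denominator of the AMP production rate.

The constitutive model keeps the AMP level fixed at a constant ``A`` so
only the bacterial equation remains.

Both models are integrated with fixed-step explicit schemes (Euler by
default, classical RK4 as a cross-check) so that discontinuous,
piecewise-constant encounter inputs from random walks are handled
without ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, NamedTuple, Sequence, Union

import numpy as np

from . import _kernels

__all__ = [
    "COMPONENTS",
    "ImdParameters",
    "ConstitutiveParameters",
    "ImdState",
    "Trajectory",
    "IntegratorConfig",
    "IntegrationError",
    "induced_derivatives",
    "constitutive_derivative",
    "integrate",
]

#: Order of the state variables everywhere in the package.
COMPONENTS = ("B", "G", "R", "C", "N", "L", "P", "S", "A")

#: Species subject to the shared degradation rate lambda2.
DEGRADED_SPECIES = ("R", "N", "L", "P", "S", "A")


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state component."""


class ImdState(NamedTuple):
    """Concentrations of the nine pathway variables (arbitrary units)."""

    B: float = 0.0
    G: float = 0.0
    R: float = 0.0
    C: float = 0.0
    N: float = 0.0
    L: float = 0.0
    P: float = 0.0
    S: float = 0.0
    A: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class ImdParameters:
    """Rate constants and binding energies of the induced model.

    Parameters
    ----------
    alpha
        Peptidoglycan release per unit of bacterial proliferation.
    k0
        Bacterial proliferation rate inside the gut (per unit time).
    lambda1
        Degradation rate of free peptidoglycan.
    lambda2
        Shared degradation rate of R, N, L, P, S and A.
    lambda3
        Dissociation rate of the receptor–peptidoglycan complex.
    R0
        Basal receptor production rate.
    beta1 .. beta6
        Production/activation rates: receptor induction by Relish
        (``beta1``), Relish activation by the complex (``beta2``),
        PGRP-LB (``beta3``), Pirk (``beta4``), repressosome (``beta5``)
        and AMP (``beta6``) production.
    Zn, Zs
        Promoter binding energies of Relish and of the repressosome
        (larger energy means weaker binding).
    degradation_rates
        Optional per-species override of ``lambda2``; keys are a subset
        of ``R, N, L, P, S, A``.  The defaults keep the single shared
        rate.
    """

    alpha: float = 2.0
    k0: float = 0.1
    lambda1: float = 0.01
    lambda2: float = 0.1
    lambda3: float = 0.1
    R0: float = 0.1
    beta1: float = 1.0
    beta2: float = 1.0
    beta3: float = 1.0
    beta4: float = 1.0
    beta5: float = 1.0
    beta6: float = 1.0
    Zn: float = 1.0
    Zs: float = 5.0
    degradation_rates: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "degradation_rates":
                continue
            value = getattr(self, f.name)
            # production/activation rates may be knocked out entirely;
            # everything else appears in denominators or decay terms and
            # must stay strictly positive.
            floor_ok = value >= 0 if f.name.startswith("beta") else value > 0
            if not (isinstance(value, (int, float)) and math.isfinite(value) and floor_ok):
                raise ValueError(
                    f"parameter {f.name} must be a finite "
                    f"{'non-negative' if f.name.startswith('beta') else 'positive'} "
                    f"number, got {value!r}"
                )
        if self.degradation_rates is not None:
            for key, value in self.degradation_rates.items():
                if key not in DEGRADED_SPECIES:
                    raise ValueError(f"degradation_rates key {key!r} is not one of {DEGRADED_SPECIES}")
                if not (math.isfinite(value) and value > 0):
                    raise ValueError(f"degradation rate for {key} must be positive, got {value!r}")

    def packed(self) -> np.ndarray:
        """Flat parameter vector consumed by the compiled kernels."""
        lam2 = {s: self.lambda2 for s in DEGRADED_SPECIES}
        if self.degradation_rates:
            lam2.update(self.degradation_rates)
        return np.array(
            [
                self.alpha, self.k0, self.lambda1, self.lambda3, self.R0,
                self.beta1, self.beta2, self.beta3, self.beta4, self.beta5, self.beta6,
                self.Zn, self.Zs,
                lam2["R"], lam2["N"], lam2["L"], lam2["P"], lam2["S"], lam2["A"],
            ],
            dtype=float,
        )

    def replace(self, **changes) -> "ImdParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "degradation_rates"}
        if self.degradation_rates:
            d["degradation_rates"] = dict(self.degradation_rates)
        return d


@dataclass(frozen=True)
class ConstitutiveParameters:
    """Constant AMP level and proliferation rate for the constitutive model."""

    A: float
    k0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and self.A >= 0):
            raise ValueError(f"constitutive AMP level A must be non-negative, got {self.A!r}")
        if not (math.isfinite(self.k0) and self.k0 > 0):
            raise ValueError(f"k0 must be positive, got {self.k0!r}")

    def to_dict(self) -> dict:
        return {"A": self.A, "k0": self.k0}


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integrator settings.

    ``record_stride`` controls how many steps separate recorded points;
    the initial and final states are always recorded.  With
    ``clip_negative`` (the default) every component is floored at zero
    after each step, and the number of clip events is reported on the
    trajectory.
    """

    t_end: float
    h: float = 0.01
    method: str = "euler"
    record_stride: int = 1
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h) and self.h > 0):
            raise ValueError(f"step size h must be positive, got {self.h!r}")
        if not (math.isfinite(self.t_end) and self.t_end >= 0):
            raise ValueError(f"t_end must be non-negative, got {self.t_end!r}")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"method must be 'euler' or 'rk4', got {self.method!r}")
        if self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride!r}")

    @property
    def n_steps(self) -> int:
        n = int(round(self.t_end / self.h))
        if abs(n * self.h - self.t_end) > 1e-8 * max(1.0, self.t_end):
            raise ValueError(
                f"t_end={self.t_end} is not an integer multiple of h={self.h}"
            )
        return n


@dataclass
class Trajectory:
    """Recorded time course of a model integration.

    Attributes
    ----------
    times
        Strictly increasing vector of recorded time points.
    states
        Matrix with one row per time point; columns follow ``columns``.
    input_values
        The encounter input ``f`` evaluated at the recorded times.
    clip_events
        Number of negative-undershoot clips applied during integration.
    """

    times: np.ndarray
    states: np.ndarray
    input_values: np.ndarray
    columns: tuple = COMPONENTS
    clip_events: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must have one row per time point")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def component(self, name: str) -> np.ndarray:
        try:
            idx = self.columns.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}; available: {self.columns}") from None
        return self.states[:, idx]

    def means(self) -> dict:
        """Arithmetic time average of every component over recorded points."""
        return {name: float(m) for name, m in zip(self.columns, self.states.mean(axis=0))}

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times, "f": self.input_values}
        for i, name in enumerate(self.columns):
            data[name] = self.states[:, i]
        return pd.DataFrame(data)


InputFunction = Union[Callable[[np.ndarray], np.ndarray], float, int]


def _input_values(input_fn: InputFunction, ts: np.ndarray) -> np.ndarray:
    """Evaluate an input specification on an array of times."""
    if isinstance(input_fn, (int, float)):
        vals = np.full(ts.shape, float(input_fn))
    else:
        out = input_fn(ts)
        vals = np.asarray(out, dtype=float)
        if vals.shape != ts.shape:  # scalar-only callable
            vals = np.array([float(input_fn(t)) for t in ts])
    if vals.size and vals.min() < 0:
        raise ValueError("encounter input f(t) must be non-negative")
    return vals


def induced_derivatives(state, params: ImdParameters, f_t: float) -> np.ndarray:
    """Instantaneous derivatives of the nine induced-model variables.

    Parameters may be an :class:`ImdState` or any length-9 sequence in
    component order.  Raises ``ValueError`` for negative concentrations
    or influx, which are outside the model's domain.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (9,):
        raise ValueError(f"state must have nine components, got shape {y.shape}")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    if f_t < 0:
        raise ValueError("influx f_t must be non-negative")
    out = np.empty(9)
    _kernels.induced_rhs(y, params.packed(), float(f_t), out)
    return out


def constitutive_derivative(B: float, A_const: float, k0: float, f_t: float) -> float:
    """dB/dt for the constitutive model: ``f + k0*B - A*B``."""
    if B < 0 or A_const < 0 or f_t < 0:
        raise ValueError("B, A_const and f_t must be non-negative")
    return f_t + k0 * B - A_const * B


def _record_steps(n_steps: int, stride: int) -> np.ndarray:
    rec = np.arange(0, n_steps + 1, stride)
    if rec[-1] != n_steps:
        rec = np.append(rec, n_steps)
    return rec


def integrate(
    model: str,
    params,
    input_fn: InputFunction,
    init=None,
    config: IntegratorConfig | None = None,
) -> Trajectory:
    """Integrate the induced or constitutive model with a fixed step.

    Parameters
    ----------
    model
        ``"induced"`` (nine ODEs, ``params`` is :class:`ImdParameters`)
        or ``"constitutive"`` (single bacterial ODE, ``params`` is
        :class:`ConstitutiveParameters`).
    input_fn
        The encounter input ``f``: a scalar for constant influx, or a
        callable accepting a float or numpy array of times.
    init
        Initial state (:class:`ImdState`/length-9 sequence, or a scalar
        ``B(0)`` for the constitutive model).  Defaults to all zeros — a
        naive host with no prior exposure.
    config
        Integrator settings; required.

    Returns
    -------
    Trajectory
        Recorded states including t=0 and t=t_end.
    """
    if config is None:
        raise ValueError("an IntegratorConfig is required")
    n = config.n_steps
    h = config.h
    rec = _record_steps(n, config.record_stride) if n > 0 else np.array([0])
    rec_times = rec * h
    if config.method == "euler":
        f_grid = _input_values(input_fn, np.arange(n) * h)
    else:
        f_grid = _input_values(input_fn, np.arange(2 * n + 1) * (h / 2.0))

    if model == "induced":
        if not isinstance(params, ImdParameters):
            raise TypeError("induced model requires ImdParameters")
        y0 = ImdState().as_array() if init is None else np.asarray(init, dtype=float).copy()
        if y0.shape != (9,):
            raise ValueError("induced initial state must have nine components")
        if np.any(y0 < 0):
            raise ValueError("initial state must be non-negative")
        kern = (
            _kernels.euler_induced_traj if config.method == "euler" else _kernels.rk4_induced_traj
        )
        states, clips, bad_step, bad_comp = kern(
            y0, params.packed(), f_grid, h, rec, config.clip_negative
        )
        if bad_step >= 0:
            raise IntegrationError(
                f"non-finite value in component {COMPONENTS[bad_comp]} at step {bad_step} "
                f"(t={bad_step * h:g})"
            )
        columns = COMPONENTS
    elif model == "constitutive":
        if not isinstance(params, ConstitutiveParameters):
            raise TypeError("constitutive model requires ConstitutiveParameters")
        B0 = 0.0 if init is None else float(init if np.isscalar(init) else np.asarray(init).item())
        if B0 < 0:
            raise ValueError("initial bacterial density must be non-negative")
        kern = (
            _kernels.euler_constitutive_traj
            if config.method == "euler"
            else _kernels.rk4_constitutive_traj
        )
        series, clips, bad_step, _ = kern(
            B0, params.A, params.k0, f_grid, h, rec, config.clip_negative
        )
        if bad_step >= 0:
            raise IntegrationError(
                f"non-finite bacterial density at step {bad_step} (t={bad_step * h:g})"
            )
        states = series[:, None]
        columns = ("B",)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'induced' or 'constitutive'")

    return Trajectory(
        times=rec_times,
        states=states,
        input_values=_input_values(input_fn, rec_times),
        columns=columns,
        clip_events=int(clips),
    )
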
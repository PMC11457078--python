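"""Compiled fixed-step integration kernels.

Everything here is internal plumbing: the public entry points live in
:mod:`imdsim.imd_model`, :mod:`imdsim.encounters` and
:mod:`imdsim.optimization`.

Parameter vectors are packed as a flat float64 array of length 19::

    0 alpha   1 k0      2 lambda1  3 lambda3  4 R0
    5 beta1 .. 10 beta6
    11 Zn     12 Zs
    13..18 degradation rates for R, N, L, P, S, A (all equal to lambda2
           unless a per-species override is configured)

State vectors hold the nine pathway variables in the order
(B, G, R, C, N, L, P, S, A).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# packed-parameter indices
_ALPHA, _K0, _LAM1, _LAM3, _R0 = 0, 1, 2, 3, 4
_B1, _B2, _B3, _B4, _B5, _B6 = 5, 6, 7, 8, 9, 10
_ZN, _ZS = 11, 12
_DR, _DN, _DL, _DP, _DS, _DA = 13, 14, 15, 16, 17, 18

N_STATE = 9


@njit(cache=True)
def induced_rhs(y, p, f, out):
    """Right-hand side of the nine coupled ODEs of the induced model."""
    B = y[0]
    G = y[1]
    R = y[2]
    C = y[3]
    N = y[4]
    L = y[5]
    P = y[6]
    S = y[7]
    A = y[8]
    hill = N / (N + p[_ZN])
    out[0] = f + p[_K0] * B - A * B
    out[1] = p[_ALPHA] * p[_K0] * B - L * G - R * G + P * C + p[_LAM3] * C - p[_LAM1] * G
    out[2] = p[_R0] + p[_B1] * hill - P * R - R * G + p[_LAM3] * C - p[_DR] * R
    out[3] = R * G - P * C - p[_LAM3] * C
    out[4] = p[_B2] * C - p[_DN] * N
    out[5] = p[_B3] * hill - p[_DL] * L
    out[6] = p[_B4] * hill - p[_DP] * P
    out[7] = p[_B5] * hill - p[_DS] * S
    out[8] = p[_B6] * N / (N + p[_ZN] + p[_ZN] * S / p[_ZS]) - p[_DA] * A


@njit(cache=True)
def euler_induced_traj(y0, p, f_left, h, rec_steps, clip):
    """Euler integration of the induced model with recorded snapshots.

    f_left holds the input value at the left endpoint of each step.
    rec_steps is a sorted array of step indices (0..n) to record.
    Returns (states, clip_events, bad_step, bad_component); bad_step is -1
    unless a non-finite value appeared, in which case integration stops.
    """
    n = f_left.shape[0]
    out = np.zeros((rec_steps.shape[0], N_STATE))
    y = y0.copy()
    dy = np.empty(N_STATE)
    clips = 0
    r = 0
    if rec_steps.shape[0] > 0 and rec_steps[0] == 0:
        out[0] = y
        r = 1
    for i in range(n):
        induced_rhs(y, p, f_left[i], dy)
        for k in range(N_STATE):
            v = y[k] + h * dy[k]
            if clip and v < 0.0:
                v = 0.0
                clips += 1
            if not np.isfinite(v):
                return out, clips, i, k
            y[k] = v
        if r < rec_steps.shape[0] and rec_steps[r] == i + 1:
            out[r] = y
            r += 1
    return out, clips, -1, -1


@njit(cache=True)
def rk4_induced_traj(y0, p, f_half, h, rec_steps, clip):
    """Classical RK4 for the induced model.

    f_half holds input values on the half-step grid: f_half[2i] is the
    value at t_i, f_half[2i+1] at t_i + h/2.
    """
    n = (f_half.shape[0] - 1) // 2
    out = np.zeros((rec_steps.shape[0], N_STATE))
    y = y0.copy()
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    tmp = np.empty(N_STATE)
    clips = 0
    r = 0
    if rec_steps.shape[0] > 0 and rec_steps[0] == 0:
        out[0] = y
        r = 1
    for i in range(n):
        induced_rhs(y, p, f_half[2 * i], k1)
        for k in range(N_STATE):
            tmp[k] = y[k] + 0.5 * h * k1[k]
        induced_rhs(tmp, p, f_half[2 * i + 1], k2)
        for k in range(N_STATE):
            tmp[k] = y[k] + 0.5 * h * k2[k]
        induced_rhs(tmp, p, f_half[2 * i + 1], k3)
        for k in range(N_STATE):
            tmp[k] = y[k] + h * k3[k]
        induced_rhs(tmp, p, f_half[2 * i + 2], k4)
        for k in range(N_STATE):
            v = y[k] + (h / 6.0) * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])
            if clip and v < 0.0:
                v = 0.0
                clips += 1
            if not np.isfinite(v):
                return out, clips, i, k
            y[k] = v
        if r < rec_steps.shape[0] and rec_steps[r] == i + 1:
            out[r] = y
            r += 1
    return out, clips, -1, -1


@njit(cache=True)
def euler_induced_means(y0, p, influx, substeps, h, clip):
    """Euler integration returning time-averaged components only.

    influx is piecewise constant: influx[i] applies for `substeps`
    consecutive Euler steps of size h.  The average includes the initial
    state and every post-step state (record stride 1).
    """
    y = y0.copy()
    dy = np.empty(N_STATE)
    sums = y0.copy()
    clips = 0
    for i in range(influx.shape[0]):
        f = influx[i]
        for _ in range(substeps):
            induced_rhs(y, p, f, dy)
            for k in range(N_STATE):
                v = y[k] + h * dy[k]
                if clip and v < 0.0:
                    v = 0.0
                    clips += 1
                if not np.isfinite(v):
                    return sums, clips, i, k
                y[k] = v
                sums[k] += v
    count = 1 + influx.shape[0] * substeps
    return sums / count, clips, -1, -1


@njit(cache=True)
def euler_constitutive_traj(B0, A, k0, f_left, h, rec_steps, clip):
    """Euler integration of dB/dt = f + k0*B - A*B with snapshots."""
    n = f_left.shape[0]
    out = np.zeros(rec_steps.shape[0])
    B = B0
    clips = 0
    r = 0
    if rec_steps.shape[0] > 0 and rec_steps[0] == 0:
        out[0] = B
        r = 1
    for i in range(n):
        B = B + h * (f_left[i] + (k0 - A) * B)
        if clip and B < 0.0:
            B = 0.0
            clips += 1
        if not np.isfinite(B):
            return out, clips, i, 0
        if r < rec_steps.shape[0] and rec_steps[r] == i + 1:
            out[r] = B
            r += 1
    return out, clips, -1, -1


@njit(cache=True)
def rk4_constitutive_traj(B0, A, k0, f_half, h, rec_steps, clip):
    n = (f_half.shape[0] - 1) // 2
    out = np.zeros(rec_steps.shape[0])
    B = B0
    g = k0 - A
    clips = 0
    r = 0
    if rec_steps.shape[0] > 0 and rec_steps[0] == 0:
        out[0] = B
        r = 1
    for i in range(n):
        k1 = f_half[2 * i] + g * B
        k2 = f_half[2 * i + 1] + g * (B + 0.5 * h * k1)
        k3 = f_half[2 * i + 1] + g * (B + 0.5 * h * k2)
        k4 = f_half[2 * i + 2] + g * (B + h * k3)
        B = B + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if clip and B < 0.0:
            B = 0.0
            clips += 1
        if not np.isfinite(B):
            return out, clips, i, 0
        if r < rec_steps.shape[0] and rec_steps[r] == i + 1:
            out[r] = B
            r += 1
    return out, clips, -1, -1


@njit(cache=True)
def euler_constitutive_grid_means(B0, A_grid, k0, influx, substeps, h, clip):
    """Time-averaged B for every AMP level in A_grid under one influx series.

    The bacterial dynamics for the different constitutive levels are
    independent, so they share a single sweep over the influx series.
    """
    nA = A_grid.shape[0]
    B = np.full(nA, B0)
    sums = np.full(nA, B0)
    for i in range(influx.shape[0]):
        f = influx[i]
        for _ in range(substeps):
            for a in range(nA):
                b = B[a] + h * (f + (k0 - A_grid[a]) * B[a])
                if clip and b < 0.0:
                    b = 0.0
                B[a] = b
                sums[a] += b
    count = 1 + influx.shape[0] * substeps
    return sums / count
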
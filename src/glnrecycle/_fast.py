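"""Numba-compiled batched Dormand–Prince 4(5) integrator.

Fitting and bootstrapping evaluate the least-squares objective tens of
thousands of times; each evaluation integrates every treatment scenario of
an experiment.  This module integrates a whole batch of scenarios (same
model, same constants, different initial conditions) in one compiled
adaptive pass, which is what makes the Nelder–Mead/bootstrap loops cheap.

Model codes: 0 = monoculture (state dim 4, 12 constants), 1 = merged
coculture (dim 5, 26 constants: caf 12, cc 12, g, m unused), 2 = stress
coculture (dim 6).  The "normalized" coculture variant is code 1 with the
CAF k2 entry zeroed by the caller.

The step-size controller mirrors the standard embedded 4(5) error estimate
with an RMS norm scaled by ``atol + rtol*|y|`` and safety factor 0.9.
Output times are hit exactly by clamping the step.  Correctness is checked
in the test suite against scipy's solve_ivp and a fixed-step Euler oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand–Prince coefficients (FSAL pair, order 5 propagation)
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B = _A[6].copy()  # 5th-order weights (FSAL: last stage row)
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)

STATUS_OK = 0
STATUS_MAX_STEPS = 1
STATUS_STEP_UNDERFLOW = 2
STATUS_NONFINITE = 3


@njit(cache=True)
def _rhs(code, p, y, out):
    """In-place RHS for a batch ``y`` of shape (n, dim)."""
    n = y.shape[0]
    if code == 0:
        k1 = p[0]; c1 = p[1]; k2 = p[2]; c2 = p[3]; h = p[4]; k3 = p[5]
        r1 = p[6]; K1 = p[7]; r2 = p[8]; K2 = p[9]; d1 = p[10]; d2 = p[11]
        for i in range(n):
            A = y[i, 0]; W = y[i, 1]; R = y[i, 2]; X = y[i, 3]
            fwd = k1 * A * X
            bwd = k2 * W * R * X
            out[i, 0] = -fwd + c2 * bwd
            out[i, 1] = c1 * fwd - bwd + h * X
            out[i, 2] = -bwd - k3 * R * X
            out[i, 3] = (r1 * A / (K1 + A) + r2 * R / (K2 + R) - d1 * W - d2) * X
    else:
        ak1 = p[0]; ac1 = p[1]; ak2 = p[2]; ac2 = p[3]; ah = p[4]; ak3 = p[5]
        ar1 = p[6]; aK1 = p[7]; ar2 = p[8]; aK2 = p[9]; ad1 = p[10]; ad2 = p[11]
        bk1 = p[12]; bc1 = p[13]; bk2 = p[14]; bc2 = p[15]; bh = p[16]; bk3 = p[17]
        br1 = p[18]; bK1 = p[19]; br2 = p[20]; bK2 = p[21]; bd1 = p[22]; bd2 = p[23]
        g = p[24]; m = p[25]
        for i in range(n):
            A = y[i, 0]; W = y[i, 1]; R = y[i, 2]; X = y[i, 3]; Y = y[i, 4]
            fwd_a = ak1 * A * X
            bwd_a = ak2 * W * R * X
            fwd_b = bk1 * A * Y
            bwd_b = bk2 * W * R * Y
            out[i, 0] = -fwd_a + ac2 * bwd_a - fwd_b + bc2 * bwd_b
            out[i, 1] = (
                ac1 * fwd_a - bwd_a + bc1 * fwd_b - bwd_b + ah * X + bh * Y
            )
            out[i, 2] = -bwd_a - bwd_b - ak3 * R * X - bk3 * R * Y
            grow_a = ar1 * A / (aK1 + A) + ar2 * R / (aK2 + R) - ad1 * W - ad2
            grow_b = br1 * A / (bK1 + A) + br2 * R / (bK2 + R) - bd1 * W - bd2
            if code == 2:
                L = y[i, 5]
                kill = m * L * L
                out[i, 3] = (grow_a - kill) * X
                out[i, 4] = (grow_b - kill) * Y
                out[i, 5] = g * X * Y
            else:
                out[i, 3] = grow_a * X
                out[i, 4] = grow_b * Y


@njit(cache=True)
def _error_norm(err, y_old, y_new, rtol, atol):
    n, d = err.shape
    acc = 0.0
    for i in range(n):
        for j in range(d):
            scale = atol + rtol * max(abs(y_old[i, j]), abs(y_new[i, j]))
            e = err[i, j] / scale
            acc += e * e
    return np.sqrt(acc / (n * d))


@njit(cache=True)
def _dp45(code, p, y0, t_out, rtol, atol, max_steps):
    """Integrate a batch from t_out[0], sampling at every t_out.

    Returns (states, status, n_steps) with states of shape
    (len(t_out), n, dim).
    """
    n, d = y0.shape
    nt = t_out.shape[0]
    out = np.empty((nt, n, d))
    y = y0.copy()
    t = t_out[0]
    out[0] = y
    idx = 1
    if idx == nt:
        return out, STATUS_OK, 0

    K = np.empty((7, n, d))
    ytmp = np.empty((n, d))
    _rhs(code, p, y, K[0])

    t_end = t_out[nt - 1]
    h = min(1.0e-2, t_end - t)
    steps = 0
    min_step = 1e-12 * max(1.0, abs(t_end))

    while idx < nt:
        if steps >= max_steps:
            return out, STATUS_MAX_STEPS, steps
        target = t_out[idx]
        clamped = False
        if t + h >= target:
            h = target - t
            clamped = True
        # seven stages (FSAL)
        for s in range(1, 7):
            for i in range(n):
                for j in range(d):
                    acc = 0.0
                    for q in range(s):
                        acc += _A[s, q] * K[q, i, j]
                    ytmp[i, j] = y[i, j] + h * acc
            _rhs(code, p, ytmp, K[s])
        # 5th-order solution is stage-6 input (B == A[6])
        y_new = np.empty((n, d))
        err = np.empty((n, d))
        for i in range(n):
            for j in range(d):
                acc = 0.0
                eacc = 0.0
                for q in range(7):
                    acc += _B[q] * K[q, i, j]
                    eacc += _E[q] * K[q, i, j]
                y_new[i, j] = y[i, j] + h * acc
                err[i, j] = h * eacc
        if not np.all(np.isfinite(y_new)):
            return out, STATUS_NONFINITE, steps
        norm = _error_norm(err, y, y_new, rtol, atol)
        steps += 1
        if norm <= 1.0:
            t = target if clamped else t + h
            y = y_new
            for i in range(n):
                for j in range(d):
                    K[0, i, j] = K[6, i, j]
            if clamped:
                out[idx] = y
                idx += 1
            if norm == 0.0:
                factor = 10.0
            else:
                factor = min(10.0, max(0.2, 0.9 * norm ** (-0.2)))
            h = h * factor
        else:
            h = h * max(0.2, 0.9 * norm ** (-0.2))
            if h < min_step:
                return out, STATUS_STEP_UNDERFLOW, steps
    return out, STATUS_OK, steps


def integrate_batch(
    code: int,
    p: np.ndarray,
    y0: np.ndarray,
    t_out: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_steps: int = 1_000_000,
) -> tuple[np.ndarray, int, int]:
    """Python entry point; see :func:`_dp45`."""
    y0 = np.ascontiguousarray(y0, dtype=np.float64)
    t_out = np.ascontiguousarray(t_out, dtype=np.float64)
    p = np.ascontiguousarray(p, dtype=np.float64)
    return _dp45(code, p, y0, t_out, float(rtol), float(atol), max_steps)


def variant_code(variant) -> int:
    """Map a :class:`~glnrecycle.model.ModelVariant` to a kernel code."""
    from .model import ModelVariant

    v = ModelVariant(variant)
    if v.is_mono:
        return 0
    return 2 if v.has_stress else 1
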
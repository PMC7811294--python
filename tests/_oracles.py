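"""Independent fixed-step explicit-Euler oracle.

Written directly from the model equations with plain vectorized numpy, and
kept independent of the package's solver code paths: it shares no
integrator, RHS kernel or state layout helper with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def euler_mono(p: dict, y0: np.ndarray, t_out, dt: float = 1e-3) -> np.ndarray:
    """Explicit Euler for the single-population model.

    ``y0`` has shape (n, 4) = (A, W, R, X); returns (len(t_out), n, 4).
    """
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_out), *y.shape))
    t = 0.0
    k = 0
    if t_out[0] == 0.0:
        out[0] = y
        k = 1
    n_steps = int(round(t_out[-1] / dt))
    for step in range(n_steps):
        A, W, R, X = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
        dA = -p["k1"] * A * X + p["c2"] * p["k2"] * W * R * X
        dW = p["c1"] * p["k1"] * A * X - p["k2"] * W * R * X + p["h"] * X
        dR = -p["k2"] * W * R * X - p["k3"] * R * X
        dX = (
            p["r1"] * A / (p["K1"] + A)
            + p["r2"] * R / (p["K2"] + R)
            - p["d1"] * W
            - p["d2"]
        ) * X
        y = y + dt * np.stack([dA, dW, dR, dX], axis=1)
        t = (step + 1) * dt
        while k < len(t_out) and abs(t - t_out[k]) < dt / 2:
            out[k] = y
            k += 1
    assert k == len(t_out)
    return out


def euler_co(
    caf: dict,
    cc: dict,
    y0: np.ndarray,
    t_out,
    dt: float = 1e-3,
    g: float | None = None,
    m: float | None = None,
    caf_k2_zero: bool = False,
) -> np.ndarray:
    """Explicit Euler for the coculture models.

    ``y0`` has shape (n, 6) = (A, W, R, X, Y, L); pass ``g`` and ``m`` for
    the stress extension (otherwise L stays 0).  ``caf_k2_zero`` disables
    the CAF ammonium-to-glutamine conversion (renormalized fibroblasts).
    """
    y = np.array(y0, dtype=float)
    caf = dict(caf)
    if caf_k2_zero:
        caf["k2"] = 0.0
    out = np.empty((len(t_out), *y.shape))
    k = 0
    if t_out[0] == 0.0:
        out[0] = y
        k = 1
    n_steps = int(round(t_out[-1] / dt))
    for step in range(n_steps):
        A, W, R, X, Y, L = (y[:, j] for j in range(6))
        dA = (
            -caf["k1"] * A * X + caf["c2"] * caf["k2"] * W * R * X
            - cc["k1"] * A * Y + cc["c2"] * cc["k2"] * W * R * Y
        )
        dW = (
            caf["c1"] * caf["k1"] * A * X - caf["k2"] * W * R * X
            + cc["c1"] * cc["k1"] * A * Y - cc["k2"] * W * R * Y
            + caf["h"] * X + cc["h"] * Y
        )
        dR = (
            -caf["k2"] * W * R * X - cc["k2"] * W * R * Y
            - caf["k3"] * R * X - cc["k3"] * R * Y
        )
        grow_caf = (
            caf["r1"] * A / (caf["K1"] + A)
            + caf["r2"] * R / (caf["K2"] + R)
            - caf["d1"] * W - caf["d2"]
        )
        grow_cc = (
            cc["r1"] * A / (cc["K1"] + A)
            + cc["r2"] * R / (cc["K2"] + R)
            - cc["d1"] * W - cc["d2"]
        )
        if g is not None:
            kill = m * L**2
            dX = (grow_caf - kill) * X
            dY = (grow_cc - kill) * Y
            dL = g * X * Y
        else:
            dX = grow_caf * X
            dY = grow_cc * Y
            dL = np.zeros_like(L)
        y = y + dt * np.stack([dA, dW, dR, dX, dY, dL], axis=1)
        t = (step + 1) * dt
        while k < len(t_out) and abs(t - t_out[k]) < dt / 2:
            out[k] = y
            k += 1
    assert k == len(t_out)
    return out
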
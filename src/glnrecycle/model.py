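"""Right-hand sides of the glutamine/ammonium exchange models.

Three deterministic ODE model families share one metabolic environment:

* **Monoculture** — one cell population ``X`` together with glutamine ``A``
  (mM), ammonium ``W`` (mM) and a composite alternative energy pool ``R``
  (mM, seeded at 20 mM and never replenished within a run)::

      dA/dt = -k1*A*X + c2*k2*W*R*X
      dW/dt =  c1*k1*A*X - k2*W*R*X + h*X
      dR/dt = -k2*W*R*X - k3*R*X
      dX/dt = (r1*A/(K1+A) + r2*R/(K2+R) - d1*W - d2) * X

  Cells catabolize Gln to NH4+ (glutaminolysis, rate k1, yield c1) and run
  the reverse NH4+→Gln conversion (rate k2, yield c2) at the cost of the
  alternative energy pool.  Growth saturates in each substrate (Monod
  kinetics); ammonium is toxic (death rate d1 per mM).

* **Merged coculture** — CAFs ``X`` and cancer cells ``Y`` contribute their
  own conversion, production and consumption terms to the shared A, W, R;
  each population grows and dies with its own constants (cancer cells
  cannot grow on R: r2 = 0).

* **Stress coculture** — the merged model plus a dimensionless stress
  factor ``L`` produced jointly by the two populations (dL/dt = g*X*Y,
  L(0) = 0) that kills both at rate m*L^2, capturing the sharp decline of
  the population after 48 h.

All terms are proportional to a live-cell count, so every derivative
vanishes in the absence of cells, and each state component's derivative is
nonnegative on the boundary where that component is zero: trajectories
started nonnegative stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError
from .params import CocultureParams, MonocultureParams


class ModelVariant(str, Enum):
    """Which model family (and therefore which state layout) is in force."""

    CAF_MONO = "caf_mono"
    CC_MONO = "cc_mono"
    COCULTURE_MERGED = "coculture_merged"
    COCULTURE_STRESS = "coculture_stress"
    #: merged model with the CAF NH4+→Gln conversion disabled (caf.k2 = 0)
    COCULTURE_NORMALIZED = "coculture_normalized"

    @property
    def is_mono(self) -> bool:
        return self in (ModelVariant.CAF_MONO, ModelVariant.CC_MONO)

    @property
    def has_stress(self) -> bool:
        return self is ModelVariant.COCULTURE_STRESS

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.is_mono:
            return ("A", "W", "R", "X")
        if self.has_stress:
            return ("A", "W", "R", "X", "Y", "L")
        return ("A", "W", "R", "X", "Y")

    @property
    def ndim(self) -> int:
        return len(self.state_names)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous values of the shared metabolic environment.

    A: Gln (mM); W: NH4+ (mM); R: alternative energy (mM); X: live CAF (or
    single-population) count; Y: live cancer-cell count (coculture only);
    L: stress factor (dimensionless, stress variant only).
    """

    A: float
    W: float
    R: float
    X: float
    Y: float | None = None
    L: float | None = None

    def validate(self) -> None:
        for name in ("A", "W", "R", "X", "Y", "L"):
            value = getattr(self, name)
            if value is None:
                continue
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"state component {name} must be >= 0, got {value!r}")

    def as_array(self, variant: ModelVariant) -> np.ndarray:
        names = variant.state_names
        values = []
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(
                    f"variant {variant.value} requires state component {name}"
                )
            values.append(value)
        return np.array(values, dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, variant: ModelVariant) -> "SystemState":
        return cls(**dict(zip(variant.state_names, np.asarray(values, float))))


def _mono_terms(A, W, R, X, p: MonocultureParams):
    forward = p.k1 * A * X          # glutaminolysis flux
    backward = p.k2 * W * R * X     # NH4+ -> Gln recycling flux
    dA = -forward + p.c2 * backward
    dW = p.c1 * forward - backward + p.h * X
    dR = -backward - p.k3 * R * X
    growth = p.r1 * A / (p.K1 + A) + p.r2 * R / (p.K2 + R) - p.d1 * W - p.d2
    return dA, dW, dR, growth


def monoculture_rhs(state: SystemState, params: MonocultureParams) -> SystemState:
    """Time derivative (per hour) of the monoculture model."""
    state.validate()
    dA, dW, dR, growth = _mono_terms(state.A, state.W, state.R, state.X, params)
    return SystemState(A=dA, W=dW, R=dR, X=growth * state.X)


def coculture_rhs(
    state: SystemState, params: CocultureParams, variant: ModelVariant
) -> SystemState:
    """Time derivative (per hour) of a coculture model variant.

    The merged model is the union of the two monoculture equation sets over
    the shared (A, W, R); the normalized variant evaluates the CAF k2 terms
    as zero; the stress variant adds dL/dt = g*X*Y and a -m*L^2 loss in both
    growth equations.
    """
    if variant.is_mono:
        raise ConfigurationError("use monoculture_rhs for monoculture variants")
    state.validate()
    if state.Y is None:
        raise ConfigurationError("coculture state requires Y")
    caf = params.caf
    if variant is ModelVariant.COCULTURE_NORMALIZED:
        caf = caf.replace(k2=0.0)
    dA_c, dW_c, dR_c, growth_caf = _mono_terms(state.A, state.W, state.R, state.X, caf)
    dA_t, dW_t, dR_t, growth_cc = _mono_terms(
        state.A, state.W, state.R, state.Y, params.cc
    )
    # cancer cells never grow on R; honour the r2 = 0 convention regardless
    dA = dA_c + dA_t
    dW = dW_c + dW_t
    dR = dR_c + dR_t
    if variant.has_stress:
        if not params.has_stress or state.L is None:
            raise ConfigurationError(
                "stress variant requires params.g, params.m and state.L"
            )
        stress_kill = params.m * state.L**2
        return SystemState(
            A=dA,
            W=dW,
            R=dR,
            X=(growth_caf - stress_kill) * state.X,
            Y=(growth_cc - stress_kill) * state.Y,
            L=params.g * state.X * state.Y,
        )
    return SystemState(
        A=dA, W=dW, R=dR, X=growth_caf * state.X, Y=growth_cc * state.Y
    )


def rhs_array(
    y: np.ndarray,
    params: MonocultureParams | CocultureParams,
    variant: ModelVariant,
) -> np.ndarray:
    """Array-in/array-out RHS used by the scipy solver backends.

    ``y`` has the variant's state layout; no validation (hot path).
    """
    if variant.is_mono:
        assert isinstance(params, MonocultureParams)
        A, W, R, X = y
        dA, dW, dR, growth = _mono_terms(A, W, R, X, params)
        return np.array([dA, dW, dR, growth * X])
    assert isinstance(params, CocultureParams)
    caf = params.caf
    if variant is ModelVariant.COCULTURE_NORMALIZED:
        caf = caf.replace(k2=0.0)
    A, W, R, X, Y = y[:5]
    dA_c, dW_c, dR_c, g_caf = _mono_terms(A, W, R, X, caf)
    dA_t, dW_t, dR_t, g_cc = _mono_terms(A, W, R, Y, params.cc)
    if variant.has_stress:
        L = y[5]
        kill = params.m * L**2
        return np.array(
            [
                dA_c + dA_t,
                dW_c + dW_t,
                dR_c + dR_t,
                (g_caf - kill) * X,
                (g_cc - kill) * Y,
                params.g * X * Y,
            ]
        )
    return np.array([dA_c + dA_t, dW_c + dW_t, dR_c + dR_t, g_caf * X, g_cc * Y])


def check_params_variant(
    params: MonocultureParams | CocultureParams, variant: ModelVariant
) -> None:
    """Raise :class:`ConfigurationError` on a params/variant mismatch."""
    if variant.is_mono:
        if not isinstance(params, MonocultureParams):
            raise ConfigurationError(
                f"variant {variant.value} requires MonocultureParams"
            )
        if variant is ModelVariant.CC_MONO and params.r2 != 0.0:
            raise ConfigurationError("cancer-cell monoculture requires r2 = 0")
    else:
        if not isinstance(params, CocultureParams):
            raise ConfigurationError(
                f"variant {variant.value} requires CocultureParams"
            )
        if variant.has_stress and not params.has_stress:
            raise ConfigurationError("stress variant requires g and m")
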
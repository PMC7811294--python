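"""Scenario definitions and trajectory integration.

A :class:`Scenario` captures one culture experiment: the model variant,
initial Gln/NH4+ doses, the alternative-energy pool (20 mM by default, the
order of magnitude of the dosed substrates), seeding counts (8×10⁴ cells
total; 1:1 for cocultures) and the observation grid (0/24/48/72 h).

:func:`simulate` integrates the variant's ODEs.  The default backend is the
package's compiled adaptive Dormand–Prince 4(5) stepper at rtol 1e-8 /
atol 1e-10; any scipy ``solve_ivp`` method (including the implicit Radau /
LSODA stiff fallbacks) can be selected instead.  Time is hours everywhere;
scenario configs expressed in days are rejected rather than converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from . import _fast
from .exceptions import ConfigurationError, IntegrationError
from .model import ModelVariant, check_params_variant, rhs_array
from .params import CocultureParams, MonocultureParams

SCIPY_METHODS = ("RK45", "DOP853", "Radau", "BDF", "LSODA")
DEFAULT_OBS_TIMES = (0.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class Scenario:
    """One culture experiment to integrate.

    Initial conditions are in natural units: mM for A0/W0/R0, cells for
    X0/Y0, hours for the horizon and observation times.
    """

    variant: ModelVariant
    A0: float = 0.0
    W0: float = 0.0
    R0: float = 20.0
    X0: float = 0.0
    Y0: float = 0.0
    horizon: float = 72.0
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES
    scenario_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", ModelVariant(self.variant))
        object.__setattr__(
            self, "obs_times", tuple(float(t) for t in self.obs_times)
        )
        for name in ("A0", "W0", "R0", "X0", "Y0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive (hours)")
        ts = self.obs_times
        if list(ts) != sorted(ts):
            raise ValueError("obs_times must be sorted")
        if len(set(ts)) != len(ts):
            raise ValueError("obs_times must be unique")
        if ts[0] != 0.0:
            raise ValueError("obs_times must include 0")
        if ts[-1] > self.horizon:
            raise ValueError("obs_times must lie within [0, horizon]")
        if not self.variant.is_mono and self.Y0 == 0 and self.X0 == 0:
            # legal but suspicious; leave to the caller
            pass

    def initial_state(self) -> np.ndarray:
        values = {"A": self.A0, "W": self.W0, "R": self.R0, "X": self.X0,
                  "Y": self.Y0, "L": 0.0}
        return np.array([values[n] for n in self.variant.state_names], float)

    def with_id(self, scenario_id: str) -> "Scenario":
        return replace(self, scenario_id=scenario_id)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "A0": self.A0,
            "W0": self.W0,
            "R0": self.R0,
            "X0": self.X0,
            "Y0": self.Y0,
            "horizon": self.horizon,
            "obs_times": list(self.obs_times),
            "scenario_id": self.scenario_id,
        }

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "Scenario":
        bad = [k for k in mapping if "day" in k.lower()]
        if bad:
            raise ConfigurationError(
                f"scenario fields must be in hours, not days: {bad}"
            )
        return cls(**{k: (tuple(v) if k == "obs_times" else v)
                      for k, v in mapping.items()})


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of one scenario.

    ``states`` has shape (len(times), ndim) with columns named by
    ``columns``; ``dense`` marks a solver-native grid rather than the
    scenario's observation grid.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    variant: ModelVariant
    scenario_id: str = ""
    dense: bool = False

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), len(self.columns)):
            raise ValueError("times/states/columns shapes disagree")

    def value(self, column: str) -> np.ndarray:
        """Time series of one state component ('A', 'W', 'R', 'X', 'Y', 'L')."""
        return self.states[:, self.columns.index(column)]

    def at_time(self, t: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} not on trajectory grid")
        return dict(zip(self.columns, self.states[i]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_h, variable, value, scenario_id)."""
        rows = []
        for j, name in enumerate(self.columns):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "variable": name,
                        "value": self.states[:, j],
                        "scenario_id": self.scenario_id,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _effective_arrays(
    scenario_variant: ModelVariant,
    params: MonocultureParams | CocultureParams,
) -> tuple[int, np.ndarray]:
    """Kernel code and flat constant array, with the normalized variant's
    CAF k2 zeroed."""
    code = _fast.variant_code(scenario_variant)
    if scenario_variant.is_mono:
        p = params.as_array()
    else:
        p = params.as_array()
        if scenario_variant is ModelVariant.COCULTURE_NORMALIZED:
            p = p.copy()
            p[2] = 0.0  # caf.k2
    return code, p


def _check_negatives(
    states: np.ndarray, rtol: float, atol: float, label: str
) -> np.ndarray:
    """Clip tiny solver-tolerance negatives to 0; larger excursions error."""
    span = np.max(np.abs(states), axis=tuple(range(states.ndim - 1)))
    threshold = 1e3 * atol + 10.0 * rtol * np.maximum(span, 1.0)
    low = states.min(axis=tuple(range(states.ndim - 1)))
    if np.any(low < -threshold):
        j = int(np.argmin(low + threshold))
        raise IntegrationError(
            f"{label}: state component {j} went below -tolerance "
            f"({low[j]:.3e})"
        )
    return np.clip(states, 0.0, None)


def integrate_scenarios(
    scenarios: Sequence[Scenario],
    params: MonocultureParams | CocultureParams,
    t_out: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Batched fast-path integration of scenarios sharing one variant.

    Returns states of shape (len(t_out), n_scenarios, ndim).  Used by the
    fitting and synthetic-data machinery.
    """
    variant = scenarios[0].variant
    if any(s.variant is not variant for s in scenarios):
        raise ConfigurationError("batched scenarios must share one variant")
    check_params_variant(params, variant)
    code, p = _effective_arrays(variant, params)
    y0 = np.stack([s.initial_state() for s in scenarios])
    states, status, _ = _fast.integrate_batch(
        code, p, y0, np.asarray(t_out, float), rtol=rtol, atol=atol
    )
    if status != _fast.STATUS_OK:
        ids = ", ".join(s.scenario_id or "?" for s in scenarios)
        raise IntegrationError(
            f"solver failed (status {status}) integrating scenarios [{ids}]"
        )
    return _check_negatives(states, rtol, atol, scenarios[0].scenario_id or "batch")


def simulate(
    scenario: Scenario,
    params: MonocultureParams | CocultureParams,
    *,
    method: str = "dp45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dense: bool = False,
    reset_R: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate one scenario and sample it at its observation times.

    Parameters
    ----------
    method:
        ``"dp45"`` (compiled adaptive Dormand–Prince, the default) or a
        scipy ``solve_ivp`` method name; ``"Radau"``/``"LSODA"`` serve as
        stiff fallbacks.
    dense:
        Return the solver-native grid (721-point uniform grid for the
        compiled backend) instead of the observation grid.
    reset_R:
        Optional ``(time_h, new_value_mM)`` medium-replenishment hook: the
        alternative-energy pool is reset to ``new_value_mM`` at ``time_h``
        and integration continues.
    """
    check_params_variant(params, scenario.variant)
    if reset_R is not None:
        return _simulate_with_reset(
            scenario, params, reset_R, method=method, rtol=rtol, atol=atol,
            dense=dense,
        )
    if dense:
        t_out = None if method != "dp45" else np.linspace(
            0.0, scenario.horizon, 721
        )
    else:
        t_out = np.asarray(scenario.obs_times, float)
        if t_out[-1] < scenario.horizon:
            t_out = np.append(t_out, scenario.horizon)

    if method == "dp45":
        states = integrate_scenarios(
            [scenario], params, t_out, rtol=rtol, atol=atol
        )[:, 0, :]
        times = np.asarray(t_out)
    elif method in SCIPY_METHODS:
        sol = solve_ivp(
            lambda t, y: rhs_array(y, params, scenario.variant),
            (0.0, scenario.horizon),
            scenario.initial_state(),
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=None if dense else t_out,
        )
        if not sol.success:
            raise IntegrationError(
                f"scenario {scenario.scenario_id or '?'}: {sol.message}"
            )
        times = sol.t
        states = _check_negatives(
            sol.y.T, rtol, atol, scenario.scenario_id or "?"
        )
    else:
        raise ConfigurationError(
            f"unknown method {method!r}; use 'dp45' or one of {SCIPY_METHODS}"
        )
    if not dense:
        keep = np.isin(times, np.asarray(scenario.obs_times, float))
        times, states = times[keep], states[keep]
    return Trajectory(
        times=np.asarray(times, float),
        states=states,
        columns=scenario.variant.state_names,
        variant=scenario.variant,
        scenario_id=scenario.scenario_id,
        dense=dense,
    )


def _simulate_with_reset(scenario, params, reset_R, *, method, rtol, atol, dense):
    # Two fast-path passes over the raw state vector so that accumulated
    # stress (L) carries through the reset unchanged.
    t_reset, new_R = reset_R
    if not 0.0 < t_reset < scenario.horizon:
        raise ConfigurationError("reset_R time must lie inside (0, horizon)")
    if new_R < 0:
        raise ConfigurationError("reset_R value must be >= 0")
    code, p = _effective_arrays(scenario.variant, params)
    label = scenario.scenario_id or "?"

    def _run(y_start, t_grid):
        states, status, _ = _fast.integrate_batch(
            code, p, y_start[None, :], np.asarray(t_grid, float),
            rtol=rtol, atol=atol,
        )
        if status != _fast.STATUS_OK:
            raise IntegrationError(
                f"solver failed (status {status}) in scenario {label}"
            )
        return _check_negatives(states[:, 0, :], rtol, atol, label)

    pre = [t for t in scenario.obs_times if t <= t_reset]
    if pre[-1] != t_reset:
        pre.append(t_reset)
    states1 = _run(scenario.initial_state(), pre)
    y_mid = states1[-1].copy()
    y_mid[scenario.variant.state_names.index("R")] = new_R
    post = [t_reset] + [t for t in scenario.obs_times if t > t_reset]
    if post[-1] < scenario.horizon:
        post.append(scenario.horizon)
    states2 = _run(y_mid, post)
    times = np.concatenate([np.asarray(pre)[:-1], np.asarray(post)])
    states = np.vstack([states1[:-1], states2])
    keep = np.isin(times, np.asarray(scenario.obs_times, float))
    return Trajectory(
        times=times[keep],
        states=states[keep],
        columns=scenario.variant.state_names,
        variant=scenario.variant,
        scenario_id=scenario.scenario_id,
        dense=False,
    )


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Concatenate trajectories into one tidy table."""
    if not trajectories:
        return pd.DataFrame(columns=["time_h", "variable", "value", "scenario_id"])
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


def save_scenarios(scenarios: Mapping[str, Scenario], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {sid: s.to_dict() for sid, s in scenarios.items()}, fh, sort_keys=True
        )


def load_scenarios(path) -> dict[str, Scenario]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {sid: Scenario.from_dict(d) for sid, d in raw.items()}
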
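"""Synthetic experiment generator.

Emulates the design of the culture experiments the models were fit to:
monocultures seeded at 8×10⁴ cells dosed with Gln ∈ {0, 1, 2, 4} mM or
NH4Cl ∈ {0, 5, 10, 25} mM, cocultures seeded 1:1 at the same total, the
alternative-energy pool at 20 mM, observations at 0/24/48/72 h, and
triplicate-averaged measurements with additive Gaussian noise.

Noise is measurement error only (no process noise), matching the error
model the bootstrap assumes: each simulated replicate adds an independent
N(0, σ²) draw in *weighted* units (mM for concentrations, 10⁴ cells for
counts), is truncated at zero, and the replicates are averaged.  Averaged
cell counts are rounded to whole cells; concentrations are not rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_WEIGHTS, Dataset, stream_from_states, stream_group, \
    streams_for_variant
from .model import ModelVariant
from .params import CocultureParams, MonocultureParams
from .simulate import DEFAULT_OBS_TIMES, Scenario, integrate_scenarios


@dataclass(frozen=True)
class DesignSpec:
    """Design of one synthetic experiment.

    ``noise`` is the measurement σ per error group in weighted units — a
    scalar applies to every group.  Groups are the cell type for
    monocultures and {CAF, CC, medium} for cocultures.
    """

    cell_type: str = "CAF"  # "CAF" | "CC" | "coculture"
    gln_doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    nh4_doses: tuple[float, ...] = (0.0, 5.0, 10.0, 25.0)
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES
    X0_total: float = 8.0e4
    coculture_ratio: float = 0.5  # CC fraction at seeding
    R0: float = 20.0
    noise: float | Mapping[str, float] = 0.2
    n_replicates_averaged: int = 3
    variant: ModelVariant | None = None  # coculture only; default merged

    def __post_init__(self) -> None:
        if self.cell_type not in ("CAF", "CC", "coculture"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if any(d < 0 for d in self.gln_doses + self.nh4_doses):
            raise ValueError("doses must be >= 0")
        if not 0.0 < self.coculture_ratio < 1.0:
            raise ValueError("coculture_ratio must lie in (0, 1)")
        sigmas = (
            [self.noise] if np.isscalar(self.noise) else list(self.noise.values())
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigma must be >= 0")
        if self.n_replicates_averaged < 1:
            raise ValueError("n_replicates_averaged must be >= 1")

    def model_variant(self) -> ModelVariant:
        if self.cell_type == "CAF":
            return ModelVariant.CAF_MONO
        if self.cell_type == "CC":
            return ModelVariant.CC_MONO
        return self.variant or ModelVariant.COCULTURE_MERGED

    def sigma_for(self, group: str) -> float:
        if np.isscalar(self.noise):
            return float(self.noise)
        return float(self.noise[group])


def build_scenarios(design: DesignSpec) -> dict[str, Scenario]:
    """The dosing grid as scenario definitions, keyed gln_<dose>/nh4_<dose>."""
    variant = design.model_variant()
    if variant.is_mono:
        x0, y0 = design.X0_total, 0.0
    else:
        y0 = design.X0_total * design.coculture_ratio
        x0 = design.X0_total - y0

    def _fmt(dose: float) -> str:
        return f"{dose:g}"

    scenarios: dict[str, Scenario] = {}
    for dose in design.gln_doses:
        sid = f"gln_{_fmt(dose)}"
        scenarios[sid] = Scenario(
            variant=variant, A0=dose, W0=0.0, R0=design.R0,
            X0=x0, Y0=y0, obs_times=design.obs_times,
            horizon=max(design.obs_times), scenario_id=sid,
        )
    for dose in design.nh4_doses:
        sid = f"nh4_{_fmt(dose)}"
        scenarios[sid] = Scenario(
            variant=variant, A0=0.0, W0=dose, R0=design.R0,
            X0=x0, Y0=y0, obs_times=design.obs_times,
            horizon=max(design.obs_times), scenario_id=sid,
        )
    return scenarios


def noiseless_records(
    design: DesignSpec,
    truth: MonocultureParams | CocultureParams,
    scenarios: Mapping[str, Scenario] | None = None,
) -> pd.DataFrame:
    """Exact model output on the design grid, as tidy records."""
    scenarios = dict(scenarios or build_scenarios(design))
    variant = design.model_variant()
    order = sorted(scenarios)
    t_out = np.asarray(design.obs_times, float)
    states = integrate_scenarios(
        [scenarios[sid] for sid in order], truth, t_out
    )  # (nt, n_scen, dim)
    rows = []
    for j, sid in enumerate(order):
        for stream in streams_for_variant(variant):
            values = stream_from_states(states[:, j, :], variant, stream)
            rows.append(
                pd.DataFrame(
                    {
                        "scenario_id": sid,
                        "time_h": t_out,
                        "stream": stream,
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate(
    design: DesignSpec,
    truth: MonocultureParams | CocultureParams,
    seed: int | None = 0,
) -> Dataset:
    """Simulate the design, add triplicate-averaged measurement noise.

    Reproducible bit-for-bit given ``seed``.  The returned dataset carries
    ``truth`` for recovery scoring.
    """
    records = noiseless_records(design, truth)
    rng = np.random.default_rng(seed)
    n_rep = design.n_replicates_averaged
    sigma = records["stream"].map(
        lambda s: design.sigma_for(stream_group(s, design.cell_type))
    ).to_numpy()
    scale = records["stream"].map(DEFAULT_WEIGHTS).to_numpy()
    clean = records["value"].to_numpy()
    # replicate-level draws: truncate each simulated replicate at zero, then
    # average, mimicking triplicate averaging of physical measurements
    noise = rng.standard_normal((n_rep, len(records))) * (sigma * scale)
    reps = np.clip(clean[None, :] + noise, 0.0, None)
    values = reps.mean(axis=0)
    # counts are reported as whole cells; a zero-noise record passes through
    # untouched so that sigma=0 reproduces the model output exactly
    is_count = records["stream"].str.startswith("cells").to_numpy()
    values = np.where(is_count & (sigma > 0), np.round(values), values)
    noisy = records.assign(value=values)
    return Dataset(
        records=noisy,
        scenarios=build_scenarios(design),
        cell_type=design.cell_type,
        truth=truth,
    )
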
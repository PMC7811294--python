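"""End-to-end computational experiment suites and reporting.

These functions reproduce the study's simulation campaigns from the
packaged published constants alone: monoculture dose responses for each
cell type, the merged and stress-factor cocultures with composition
tracking, and the counterfactual "renormalized fibroblast" comparison in
which CAFs lose the NH4+→Gln conversion (caf.k2 = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data import stream_from_states
from .model import ModelVariant
from .params import (
    CocultureParams,
    MonocultureParams,
    caf_params,
    cc_params,
    coculture_params,
)
from .simulate import Scenario, Trajectory, simulate

_FLOAT_FMT = "%.10g"


def _dose_scenarios(
    variant: ModelVariant,
    gln_doses: Sequence[float],
    nh4_doses: Sequence[float],
    X0: float,
    Y0: float,
) -> dict[str, Scenario]:
    scenarios = {}
    for dose in gln_doses:
        sid = f"gln_{dose:g}"
        scenarios[sid] = Scenario(
            variant=variant, A0=dose, X0=X0, Y0=Y0, scenario_id=sid
        )
    for dose in nh4_doses:
        sid = f"nh4_{dose:g}"
        scenarios[sid] = Scenario(
            variant=variant, W0=dose, X0=X0, Y0=Y0, scenario_id=sid
        )
    return scenarios


def run_monoculture_suite(
    cell_type: str,
    params: MonocultureParams | None = None,
    gln_doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
    nh4_doses: Sequence[float] = (0.0, 5.0, 10.0, 25.0),
    *,
    method: str = "dp45",
) -> dict:
    """Dose-response simulations for one cell type grown alone.

    Returns ``{"trajectories": {scenario_id: Trajectory}, "summary":
    DataFrame}``; the summary lists Gln, NH4+ and the live-cell count at
    each observation time per dosing scenario.
    """
    if cell_type == "CAF":
        variant = ModelVariant.CAF_MONO
        params = caf_params() if params is None else params
    elif cell_type == "CC":
        variant = ModelVariant.CC_MONO
        params = cc_params() if params is None else params
    else:
        raise ValueError(f"unknown monoculture cell type {cell_type!r}")
    scenarios = _dose_scenarios(variant, gln_doses, nh4_doses, X0=8.0e4, Y0=0.0)
    trajectories = {
        sid: simulate(s, params, method=method) for sid, s in scenarios.items()
    }
    rows = []
    for sid in sorted(trajectories):
        traj = trajectories[sid]
        for i, t in enumerate(traj.times):
            rows.append(
                {
                    "scenario_id": sid,
                    "time_h": t,
                    "Gln_mM": traj.states[i, 0],
                    "NH4_mM": traj.states[i, 1],
                    "cells": traj.value("X")[i],
                }
            )
    return {"trajectories": trajectories, "summary": pd.DataFrame(rows)}


def run_coculture_suite(
    params: CocultureParams | None = None,
    variant: ModelVariant | str = ModelVariant.COCULTURE_MERGED,
    nh4_doses: Sequence[float] = (5.0, 10.0, 25.0),
    gln_doses: Sequence[float] = (4.0,),
    *,
    method: str = "dp45",
) -> dict:
    """1:1 coculture simulations with composition tracking.

    The merged variant defaults to the published growth-rate overrides;
    the stress variant reverts both growth rates to their monoculture
    values and adds the stress constants.  The composition table reports
    the live cancer-cell percentage %CC = Y/(X+Y) at the observation
    times.
    """
    variant = ModelVariant(variant)
    if variant.is_mono:
        raise ValueError("run_coculture_suite requires a coculture variant")
    if params is None:
        params = coculture_params(variant.value)
    scenarios = _dose_scenarios(variant, gln_doses, nh4_doses, X0=4.0e4, Y0=4.0e4)
    trajectories = {
        sid: simulate(s, params, method=method) for sid, s in scenarios.items()
    }
    rows = []
    for sid in sorted(trajectories):
        traj = trajectories[sid]
        X, Y = traj.value("X"), traj.value("Y")
        total = X + Y
        for i, t in enumerate(traj.times):
            rows.append(
                {
                    "scenario_id": sid,
                    "time_h": t,
                    "cells_CAF": X[i],
                    "cells_CC": Y[i],
                    "cells_total": total[i],
                    "pct_cc": 100.0 * Y[i] / total[i] if total[i] > 0 else np.nan,
                }
            )
    return {"trajectories": trajectories, "composition": pd.DataFrame(rows)}


def run_renormalization_comparison(
    params: CocultureParams | None = None,
    dose: float = 5.0,
    *,
    method: str = "dp45",
) -> dict:
    """Merged coculture vs the "renormalized fibroblast" counterfactual.

    Normalizing the CAFs (caf.k2 = 0) removes their NH4+→Gln recycling;
    with only the cancer cells converting, Gln stays lower and the total
    population declines faster.  Simulated at one NH4+ dose (5 mM by
    default).
    """
    if params is None:
        params = coculture_params("coculture_merged")
    sid = f"nh4_{dose:g}"
    merged = simulate(
        Scenario(
            variant=ModelVariant.COCULTURE_MERGED, W0=dose, X0=4.0e4, Y0=4.0e4,
            scenario_id=f"{sid}_merged",
        ),
        params,
        method=method,
    )
    normalized = simulate(
        Scenario(
            variant=ModelVariant.COCULTURE_NORMALIZED, W0=dose, X0=4.0e4,
            Y0=4.0e4, scenario_id=f"{sid}_normalized",
        ),
        params,
        method=method,
    )
    rows = []
    for i, t in enumerate(merged.times):
        tm = merged.value("X")[i] + merged.value("Y")[i]
        tn = normalized.value("X")[i] + normalized.value("Y")[i]
        rows.append(
            {
                "time_h": t,
                "total_merged": tm,
                "total_normalized": tn,
                "delta_total": tn - tm,
                "gln_merged": merged.value("A")[i],
                "gln_normalized": normalized.value("A")[i],
            }
        )
    return {
        "merged": merged,
        "normalized": normalized,
        "delta": pd.DataFrame(rows),
    }


@dataclass(frozen=True)
class SuiteConfig:
    """Configuration of a full simulation campaign."""

    monocultures: tuple[str, ...] = ("CAF", "CC")
    coculture_variants: tuple[str, ...] = (
        "coculture_merged",
        "coculture_stress",
    )
    renormalization_dose: float | None = 5.0
    seed: int | None = None
    out_dir: str | None = None


def run_suite(config: SuiteConfig = SuiteConfig()) -> dict[str, pd.DataFrame]:
    """Run the configured campaigns; tables keyed by a stable name."""
    tables: dict[str, pd.DataFrame] = {}
    for cell_type in config.monocultures:
        result = run_monoculture_suite(cell_type)
        tables[f"monoculture_{cell_type}"] = result["summary"]
    for variant in config.coculture_variants:
        result = run_coculture_suite(variant=variant)
        tables[f"composition_{variant}"] = result["composition"]
    if config.renormalization_dose is not None:
        comparison = run_renormalization_comparison(
            dose=config.renormalization_dose
        )
        tables["renormalization"] = comparison["delta"]
    if config.out_dir is not None:
        report(tables, config.out_dir, seed=config.seed)
    return tables


def report(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> Path:
    """Write tables as tidy TSVs plus a machine-readable run manifest.

    Deterministic: fixed column order (as given), fixed float formatting,
    sorted manifest keys and no timestamps, so reruns with the same inputs
    are byte-identical.  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for name in sorted(tables):
        table = tables[name]
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        manifest_rows.append({"table": name, "rows": len(table)})
    manifest = pd.DataFrame(manifest_rows, columns=["table", "rows"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    info = {
        "package": "glnrecycle",
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else None,
        "versions": _library_versions(),
    }
    with open(out / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
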
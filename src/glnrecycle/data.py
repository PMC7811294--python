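"""Tidy observation container shared by the synthetic generator and the
fitting machinery.

A :class:`Dataset` is the triplicate-averaged time-course table of one
experiment: records of (scenario_id, time_h, stream, value) plus the
:class:`~glnrecycle.simulate.Scenario` definitions needed to simulate each
scenario.  Streams are ``Gln_mM``/``NH4_mM`` (medium concentrations, mM)
and ``cells_CAF``/``cells_CC``/``cells_total`` (live counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .model import ModelVariant
from .params import CocultureParams, MonocultureParams
from .simulate import Scenario, load_scenarios, save_scenarios

STREAMS = ("Gln_mM", "NH4_mM", "cells_CAF", "cells_CC", "cells_total")

#: Default stream scales for the least-squares objective: counts are
#: expressed in units of 10^4 cells so that residual magnitudes are
#: comparable with millimolar concentrations.  ``unweighted_weights`` gives
#: the literal unscaled sum of squares instead.
DEFAULT_WEIGHTS: Mapping[str, float] = {
    "Gln_mM": 1.0,
    "NH4_mM": 1.0,
    "cells_CAF": 1.0e4,
    "cells_CC": 1.0e4,
    "cells_total": 1.0e4,
}

RECORD_COLUMNS = ("scenario_id", "time_h", "stream", "value")


def unweighted_weights() -> dict[str, float]:
    """All-ones stream weights: the literal unscaled squared-residual sum."""
    return {s: 1.0 for s in STREAMS}


def streams_for_variant(variant: ModelVariant) -> tuple[str, ...]:
    """The observable streams an experiment with this variant produces."""
    if variant is ModelVariant.CAF_MONO:
        return ("Gln_mM", "NH4_mM", "cells_CAF")
    if variant is ModelVariant.CC_MONO:
        return ("Gln_mM", "NH4_mM", "cells_CC")
    return ("Gln_mM", "NH4_mM", "cells_CAF", "cells_CC")


def stream_from_states(
    states: np.ndarray, variant: ModelVariant, stream: str
) -> np.ndarray:
    """Extract one observation stream from state vectors (..., ndim)."""
    names = variant.state_names
    if stream == "Gln_mM":
        return states[..., names.index("A")]
    if stream == "NH4_mM":
        return states[..., names.index("W")]
    if stream == "cells_CAF":
        if variant is ModelVariant.CC_MONO:
            raise ConfigurationError("CC monoculture has no CAF count stream")
        return states[..., names.index("X")]
    if stream == "cells_CC":
        if variant is ModelVariant.CAF_MONO:
            raise ConfigurationError("CAF monoculture has no CC count stream")
        idx = names.index("X") if variant.is_mono else names.index("Y")
        return states[..., idx]
    if stream == "cells_total":
        if variant.is_mono:
            return states[..., names.index("X")]
        return states[..., names.index("X")] + states[..., names.index("Y")]
    raise KeyError(f"unknown stream {stream!r}")


def stream_group(stream: str, cell_type: str) -> str:
    """Error group of one stream under the per-cell-type noise model.

    Monoculture experiments have a single group (all observations of that
    cell type); coculture counts split by cell type and the shared medium
    concentrations form their own group.
    """
    if cell_type in ("CAF", "CC"):
        return cell_type
    if stream == "cells_CAF":
        return "CAF"
    if stream == "cells_CC":
        return "CC"
    return "medium"


@dataclass
class Dataset:
    """Observed time courses of one experiment.

    ``records`` columns: scenario_id, time_h, stream, value.  ``truth``
    optionally carries the generating parameters of a synthetic dataset for
    recovery scoring.
    """

    records: pd.DataFrame
    scenarios: dict[str, Scenario]
    cell_type: str  # "CAF" | "CC" | "coculture"
    truth: MonocultureParams | CocultureParams | None = None

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if self.cell_type not in ("CAF", "CC", "coculture"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        self.records = self.records.reset_index(drop=True)
        unknown = set(self.records["scenario_id"]) - set(self.scenarios)
        if unknown:
            raise ValueError(f"records reference undefined scenarios {sorted(unknown)}")
        if (self.records["value"] < 0).any():
            raise ValueError("observed values must be >= 0")
        bad = set(self.records["stream"]) - set(STREAMS)
        if bad:
            raise ValueError(f"unknown streams {sorted(bad)}")
        dup = self.records.duplicated(["scenario_id", "time_h", "stream"])
        if dup.any():
            raise ValueError("duplicate (scenario, time, stream) records")

    @property
    def variant(self) -> ModelVariant:
        variants = {s.variant for s in self.scenarios.values()}
        if len(variants) != 1:
            raise ConfigurationError("dataset mixes model variants")
        return variants.pop()

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> pd.Series:
        """Error-group label of each record (per-cell-type grouping)."""
        return self.records["stream"].map(
            lambda s: stream_group(s, self.cell_type)
        )

    def write(self, records_path, scenarios_path) -> None:
        """Tidy TSV of records plus a YAML scenario config."""
        out = self.records.loc[:, list(RECORD_COLUMNS)].copy()
        out.to_csv(records_path, sep="\t", index=False, float_format="%.17g")
        save_scenarios(self.scenarios, scenarios_path)

    @classmethod
    def read(cls, records_path, scenarios_path, cell_type: str) -> "Dataset":
        records = pd.read_csv(records_path, sep="\t")
        scenarios = load_scenarios(scenarios_path)
        return cls(records=records, scenarios=scenarios, cell_type=cell_type)
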
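"""Kinetic parameter containers and the packaged published parameter tables.

The monoculture model has 12 constants (k1, c1, k2, c2, h, k3, r1, K1, r2,
K2, d1, d2); the coculture model carries one full set per cell type plus the
optional stress constants (g, m).  Parameters are stored in natural units
(mM, cells, hours) so published table values drop in verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

#: Canonical ordering of the monoculture constants, used by every array path.
PARAM_NAMES: tuple[str, ...] = (
    "k1", "c1", "k2", "c2", "h", "k3", "r1", "K1", "r2", "K2", "d1", "d2",
)

#: Units of each monoculture constant (hours / mM / cells throughout).
PARAM_UNITS: Mapping[str, str] = {
    "k1": "1/(cell*h)",
    "c1": "dimensionless",
    "k2": "1/(cell*mM*h)",
    "c2": "dimensionless",
    "h": "mM/(cell*h)",
    "k3": "1/(cell*h)",
    "r1": "1/h",
    "K1": "mM",
    "r2": "1/h",
    "K2": "mM",
    "d1": "1/(mM*h)",
    "d2": "1/h",
}


@dataclass(frozen=True)
class MonocultureParams:
    """Kinetic constants of the single-cell-type model.

    ``r2`` is the maximal growth rate on the alternative energy pool R; for
    cancer cells it is fixed to 0 (they cannot grow on R), which renders
    ``K2`` inert.
    """

    k1: float   # Gln -> NH4+ conversion rate, 1/(cell*h)
    c1: float   # NH4+ yield per Gln, dimensionless
    k2: float   # NH4+ -> Gln conversion rate, 1/(cell*mM*h)
    c2: float   # Gln yield per NH4+, dimensionless
    h: float    # basal NH4+ production, mM/(cell*h)
    k3: float   # alternative-energy consumption, 1/(cell*h)
    r1: float   # maximal growth rate on Gln, 1/h
    K1: float   # half-saturation for Gln, mM
    r2: float   # maximal growth rate on R, 1/h
    K2: float   # half-saturation for R, mM
    d1: float   # NH4+-induced death, 1/(mM*h)
    d2: float   # background death, 1/h

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"parameter {name} must be finite and >= 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """The 12 constants as a float array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "MonocultureParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "MonocultureParams":
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def replace(self, **changes: float) -> "MonocultureParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CocultureParams:
    """One full constant set per cell type, plus optional stress constants.

    ``g`` (stress production, 1/(h*cell^2)) and ``m`` (stress kill
    coefficient, 1/h) are required by the stress variant and ignored by the
    merged and normalized variants; ``None`` means "not provided".
    """

    caf: MonocultureParams
    cc: MonocultureParams
    g: float | None = None
    m: float | None = None

    def __post_init__(self) -> None:
        for name in ("g", "m"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def has_stress(self) -> bool:
        return self.g is not None and self.m is not None

    def as_array(self) -> np.ndarray:
        """caf constants, cc constants, then (g, m) — 26 floats.

        Missing stress constants are encoded as 0 so the merged-model
        kernels can share one layout; callers must check :attr:`has_stress`
        before selecting the stress variant.
        """
        return np.concatenate([
            self.caf.as_array(),
            self.cc.as_array(),
            [self.g or 0.0, self.m or 0.0],
        ])

    def replace(self, **changes: float) -> "CocultureParams":
        """Replace dotted names ('caf.k1', 'cc.r1') or 'g'/'m'."""
        caf_changes: dict[str, float] = {}
        cc_changes: dict[str, float] = {}
        top: dict[str, float] = {}
        for key, value in changes.items():
            if key.startswith("caf."):
                caf_changes[key[4:]] = value
            elif key.startswith("cc."):
                cc_changes[key[3:]] = value
            elif key in ("g", "m"):
                top[key] = value
            else:
                raise KeyError(f"unknown coculture parameter {key!r}")
        return CocultureParams(
            caf=self.caf.replace(**caf_changes) if caf_changes else self.caf,
            cc=self.cc.replace(**cc_changes) if cc_changes else self.cc,
            g=top.get("g", self.g),
            m=top.get("m", self.m),
        )

    def to_dict(self) -> dict[str, float]:
        out = {f"caf.{n}": v for n, v in self.caf.to_dict().items()}
        out.update({f"cc.{n}": v for n, v in self.cc.to_dict().items()})
        if self.g is not None:
            out["g"] = self.g
        if self.m is not None:
            out["m"] = self.m
        return out


def param_names(params: MonocultureParams | CocultureParams) -> tuple[str, ...]:
    """Flat names addressing every constant of a parameter object."""
    if isinstance(params, MonocultureParams):
        return PARAM_NAMES
    names = tuple(f"caf.{n}" for n in PARAM_NAMES) + tuple(
        f"cc.{n}" for n in PARAM_NAMES
    )
    return names + (("g", "m") if params.has_stress else ())


def get_value(params: MonocultureParams | CocultureParams, name: str) -> float:
    if isinstance(params, MonocultureParams):
        return getattr(params, name)
    if name.startswith("caf."):
        return getattr(params.caf, name[4:])
    if name.startswith("cc."):
        return getattr(params.cc, name[3:])
    if name in ("g", "m"):
        value = getattr(params, name)
        if value is None:
            raise KeyError(f"{name} not set on this parameter object")
        return value
    raise KeyError(name)


def with_values(
    params: MonocultureParams | CocultureParams, values: Mapping[str, float]
):
    """A copy of ``params`` with the named constants replaced."""
    return params.replace(**dict(values))


# ---------------------------------------------------------------------------
# Packaged published tables
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "CAF": "caf_monoculture.yaml",
    "CC": "cc_monoculture.yaml",
    "coculture": "coculture_adjustments.yaml",
    "stress": "stress_factor.yaml",
}


def _load_yaml(filename: str) -> dict:
    path = resources.files("glnrecycle.tables").joinpath(filename)
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_table(name: str) -> dict:
    """Raw contents of one packaged parameter table ('CAF', 'CC',
    'coculture', 'stress')."""
    try:
        return _load_yaml(_TABLE_FILES[name])
    except KeyError:
        raise KeyError(f"unknown table {name!r}; options: {sorted(_TABLE_FILES)}")


def caf_params() -> MonocultureParams:
    """Published CAF monoculture constants."""
    table = load_table("CAF")
    return MonocultureParams.from_dict(
        {n: table["parameters"][n]["value"] for n in PARAM_NAMES}
    )


def cc_params() -> MonocultureParams:
    """Published cancer-cell monoculture constants (r2 = 0)."""
    table = load_table("CC")
    params = MonocultureParams.from_dict(
        {n: table["parameters"][n]["value"] for n in PARAM_NAMES}
    )
    if params.r2 != 0.0:
        raise ConfigurationError("cancer-cell table must have r2 = 0")
    return params


def coculture_params(variant: str = "coculture_merged") -> CocultureParams:
    """Published coculture constants for a coculture model variant.

    * ``coculture_merged`` — monoculture constants with the two growth-rate
      overrides refit on the coculture data.
    * ``coculture_stress`` — monoculture growth rates reverted, plus the
      stress constants (g, m).
    * ``coculture_normalized`` — merged constants with the CAF NH4+→Gln
      conversion removed (caf.k2 = 0), the counterfactual "renormalized
      fibroblast" therapy scenario.
    """
    base = CocultureParams(caf=caf_params(), cc=cc_params())
    if variant == "coculture_stress":
        stress = load_table("stress")["parameters"]
        return base.replace(g=stress["g"]["value"], m=stress["m"]["value"])
    overrides = load_table("coculture")["overrides"]
    merged = base.replace(**{k: v["value"] for k, v in overrides.items()})
    if variant == "coculture_merged":
        return merged
    if variant == "coculture_normalized":
        return merged.replace(**{"caf.k2": 0.0})
    raise ConfigurationError(f"unknown coculture variant {variant!r}")


def published_ci_table(cell_type: str) -> pd.DataFrame:
    """Published point estimates and 95% CIs as a tidy table.

    Columns: parameter, estimate, ci_low, ci_high, unit.  Parameters with no
    published interval (the fixed r2 and inert K2 of the cancer cells) are
    omitted.  Suitable input for
    :func:`glnrecycle.fit.sensitivity_table`.
    """
    table = load_table(cell_type)["parameters"]
    rows = []
    for name in PARAM_NAMES:
        entry = table[name]
        if entry.get("ci") is None:
            continue
        rows.append(
            {
                "parameter": name,
                "estimate": float(entry["value"]),
                "ci_low": float(entry["ci"][0]),
                "ci_high": float(entry["ci"][1]),
                "unit": entry["unit"],
            }
        )
    return pd.DataFrame(rows)


def save_params(params: MonocultureParams | CocultureParams, path) -> None:
    """Serialize a parameter object as a flat key→value YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_params(path) -> MonocultureParams | CocultureParams:
    """Inverse of :func:`save_params`; infers mono vs coculture from keys."""
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    if any(k.startswith("caf.") for k in flat):
        caf = MonocultureParams.from_dict(
            {n: flat[f"caf.{n}"] for n in PARAM_NAMES}
        )
        cc = MonocultureParams.from_dict({n: flat[f"cc.{n}"] for n in PARAM_NAMES})
        return CocultureParams(caf=caf, cc=cc, g=flat.get("g"), m=flat.get("m"))
    return MonocultureParams.from_dict(flat)


def iter_param_items(
    params: MonocultureParams | CocultureParams,
) -> Iterator[tuple[str, float]]:
    for name in param_names(params):
        yield name, get_value(params, name)
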
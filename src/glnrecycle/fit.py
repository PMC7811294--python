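"""Least-squares estimation of the kinetic constants.

The objective is the summed squared deviation between the ODE solution and
the observed time courses over *all* scenarios of one experiment (every
dose of Gln and NH4+ jointly),

    F(theta) = sum_k | u(t_k; theta) - w(t_k) |^2 ,

with each stream first divided by its scale weight.  By default counts are
expressed in units of 10^4 cells and concentrations in mM, so both kinds
of residual carry comparable magnitude; ``unweighted_weights()`` restores
the literal unscaled sum.  Minimization uses the Nelder–Mead simplex over
log-transformed free parameters (which enforces positivity), starting from
a simplex whose edges perturb each coordinate by a factor 1.05.

Uncertainty comes from a parametric bootstrap: residual variances are
estimated per error group (per cell type by default, matching the assumed
error model eps = (eps_CAF, eps_CC) with independent centred Gaussians),
synthetic data sets are simulated at the fitted constants plus Gaussian
noise, each is refit, and 95% percentile intervals are taken over the
replicate estimates.  Narrow normalized intervals flag the constants the
data pins down most tightly (sensitivity ranking).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _fast
from .data import DEFAULT_WEIGHTS, Dataset, stream_group
from .exceptions import ConfigurationError
from .model import ModelVariant
from .params import (
    PARAM_NAMES,
    CocultureParams,
    MonocultureParams,
    get_value,
    param_names,
    with_values,
)
from .simulate import _effective_arrays

#: Finite objective value returned when the ODE solver fails under a trial
#: parameter vector, so the simplex can retreat from pathological regions.
PENALTY = 1.0e12

_LOG_EDGE = np.log(1.05)  # initial simplex edge: multiply one coordinate by 1.05


def _flat_index(name: str) -> int:
    """Index of a flat parameter name in the kernel constant array."""
    if name in PARAM_NAMES:
        return PARAM_NAMES.index(name)
    if name.startswith("caf."):
        return PARAM_NAMES.index(name[4:])
    if name.startswith("cc."):
        return 12 + PARAM_NAMES.index(name[3:])
    if name == "g":
        return 24
    if name == "m":
        return 25
    raise KeyError(name)


def default_free(
    params: MonocultureParams | CocultureParams,
) -> tuple[str, ...]:
    """All constants that are positive and identifiable a priori.

    Zero-valued constants cannot be log-transformed and stay pinned; a K2
    paired with r2 = 0 is inert (the R-growth term vanishes) and is pinned
    as well.
    """
    names = []
    for name in param_names(params):
        value = get_value(params, name)
        if value <= 0:
            continue
        base = name.split(".")[-1]
        if base == "K2":
            r2_name = name.replace("K2", "r2")
            if get_value(params, r2_name) == 0:
                continue
        names.append(name)
    return tuple(names)


class _Predictor:
    """Precompiled map from a flat constant array to weighted predictions.

    Builds the batched initial-condition stack and the record-to-state
    index arrays once, so each objective evaluation is a single compiled
    integrator call plus fancy indexing.
    """

    def __init__(
        self,
        dataset: Dataset,
        weights=None,
        rtol: float = 1e-7,
        atol: float = 1e-9,
    ) -> None:
        self.dataset = dataset
        self.variant = dataset.variant
        self.weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
        self.rtol = float(rtol)
        self.atol = float(atol)

        order = sorted(dataset.scenarios)
        self.scenario_order = order
        scen_idx = {sid: j for j, sid in enumerate(order)}
        self.y0 = np.stack(
            [dataset.scenarios[sid].initial_state() for sid in order]
        )
        records = dataset.records
        times = np.unique(
            np.concatenate([[0.0], records["time_h"].to_numpy(float)])
        )
        self.t_out = times
        time_idx = {t: i for i, t in enumerate(times)}

        names = self.variant.state_names
        iX = names.index("X")
        iY = names.index("Y") if "Y" in names else -1

        def _cols(stream: str) -> tuple[int, int]:
            if stream == "Gln_mM":
                return names.index("A"), -1
            if stream == "NH4_mM":
                return names.index("W"), -1
            if stream == "cells_CAF":
                if self.variant is ModelVariant.CC_MONO:
                    raise ConfigurationError("CC monoculture has no CAF stream")
                return iX, -1
            if stream == "cells_CC":
                return (iX, -1) if self.variant.is_mono else (iY, -1)
            if stream == "cells_total":
                return (iX, -1) if self.variant.is_mono else (iX, iY)
            raise ConfigurationError(f"unknown stream {stream!r}")

        missing = set(records["stream"]) - set(self.weights)
        if missing:
            raise ConfigurationError(f"no weight for streams {sorted(missing)}")

        self.rec_time = records["time_h"].map(time_idx).to_numpy(np.intp)
        self.rec_scen = records["scenario_id"].map(scen_idx).to_numpy(np.intp)
        cols = np.array([_cols(s) for s in records["stream"]], dtype=np.intp)
        self.rec_col, self.rec_col2 = cols[:, 0], cols[:, 1]
        self.has_second = self.rec_col2 >= 0
        self.rec_weight = records["stream"].map(self.weights).to_numpy(float)
        self.obs = records["value"].to_numpy(float)
        self.obs_weighted = self.obs / self.rec_weight
        self.code, _ = _effective_arrays(self.variant, _any_params(dataset))
        self.zero_caf_k2 = self.variant is ModelVariant.COCULTURE_NORMALIZED

    def predict_natural(self, p: np.ndarray) -> np.ndarray:
        """Model predictions for every record, natural units.

        Raises on solver failure (callers in the optimizer loop catch and
        return :data:`PENALTY`).
        """
        p = np.asarray(p, float)
        if self.zero_caf_k2:
            p = p.copy()
            p[2] = 0.0
        states, status, _ = _fast.integrate_batch(
            self.code, p, self.y0, self.t_out, rtol=self.rtol, atol=self.atol
        )
        if status != _fast.STATUS_OK:
            raise FloatingPointError(f"solver status {status}")
        states = np.clip(states, 0.0, None)
        pred = states[self.rec_time, self.rec_scen, self.rec_col]
        if self.has_second.any():
            second = states[self.rec_time, self.rec_scen, self.rec_col2]
            pred = np.where(self.has_second, pred + second, pred)
        return pred

    def sse(self, p: np.ndarray, obs_weighted: np.ndarray | None = None) -> float:
        """Weighted sum of squared residuals; PENALTY on solver failure."""
        if obs_weighted is None:
            obs_weighted = self.obs_weighted
        try:
            pred = self.predict_natural(p)
        except FloatingPointError:
            return PENALTY
        resid = pred / self.rec_weight - obs_weighted
        value = float(np.dot(resid, resid))
        return value if np.isfinite(value) else PENALTY

    def weighted_residuals(self, p: np.ndarray) -> np.ndarray:
        return self.obs_weighted - self.predict_natural(p) / self.rec_weight


def _any_params(dataset: Dataset):
    """A syntactically valid parameter object for the dataset's variant,
    used only to derive the kernel code/layout."""
    if dataset.truth is not None:
        return dataset.truth
    zero = MonocultureParams.from_array(np.zeros(12))
    if dataset.variant.is_mono:
        return zero
    return CocultureParams(caf=zero, cc=zero, g=0.0, m=0.0)


def _full_array(params: MonocultureParams | CocultureParams) -> np.ndarray:
    if isinstance(params, MonocultureParams):
        return params.as_array()
    return params.as_array()


def objective(
    params: MonocultureParams | CocultureParams,
    dataset: Dataset,
    weights=None,
    *,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """F(theta): weighted squared deviation of the model from the data."""
    predictor = _Predictor(dataset, weights=weights, rtol=rtol, atol=atol)
    return predictor.sse(_full_array(params))


@dataclass(frozen=True)
class FitResult:
    """Point estimate from one Nelder–Mead minimization."""

    params: MonocultureParams | CocultureParams
    objective: float
    n_evals: int
    converged: bool
    free: tuple[str, ...]
    init: MonocultureParams | CocultureParams

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "estimate": get_value(self.params, name),
                "free": name in self.free,
            }
            for name in param_names(self.params)
        ]
        return pd.DataFrame(rows)


def _run_nelder_mead(
    fz, z0: np.ndarray, *, maxfev: int, xatol: float, fatol: float,
    restarts: int, edge0: float = _LOG_EDGE,
):
    """Nelder–Mead with optional simplex re-inflation restarts."""
    best_z, best_f = z0.copy(), fz(z0)
    n_evals = 1
    success = False
    edge = edge0
    for round_no in range(restarts + 1):
        budget = maxfev - n_evals
        if budget <= 0:
            break
        simplex = np.vstack([best_z] + [best_z + edge * e
                                        for e in np.eye(len(z0))])
        res = minimize(
            fz,
            best_z,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": budget,
                "xatol": xatol,
                "fatol": fatol,
                "adaptive": True,
            },
        )
        n_evals += res.nfev
        improved = res.fun < best_f - max(fatol, 1e-12 * abs(best_f))
        if res.fun < best_f:
            best_z, best_f = np.asarray(res.x, float), float(res.fun)
        success = bool(res.success)
        edge = np.log(1.005)
        if not improved and round_no > 0:
            break
    return best_z, best_f, n_evals, success


def fit(
    data: Dataset,
    init: MonocultureParams | CocultureParams,
    free: tuple[str, ...] | None = None,
    *,
    weights=None,
    maxfev: int = 100_000,
    xatol: float = 1e-6,
    fatol: float = 1e-10,
    restarts: int = 2,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> FitResult:
    """Joint Nelder–Mead fit over every scenario of the dataset.

    ``free`` names the constants to optimize (flat names, e.g. ``"r1"`` or
    ``"caf.r1"``); all others stay pinned at their ``init`` values exactly.
    Free constants must be positive at ``init`` (the optimizer works in log
    space).  Deterministic given (data, init, free, options).
    """
    if free is None:
        free = default_free(init)
    free = tuple(free)
    if not free:
        raise ConfigurationError("no free parameters")
    for name in free:
        if get_value(init, name) <= 0:
            raise ConfigurationError(
                f"free parameter {name} must be positive at init"
            )
    predictor = _Predictor(data, weights=weights, rtol=rtol, atol=atol)
    base = _full_array(init)
    free_idx = np.array([_flat_index(n) for n in free], dtype=np.intp)
    if len(set(free_idx.tolist())) != len(free):
        raise ConfigurationError("duplicate free parameters")

    def fz(z):
        p = base.copy()
        p[free_idx] = np.exp(np.clip(z, -700.0, 700.0))
        return predictor.sse(p)

    z0 = np.log(base[free_idx])
    best_z, best_f, n_evals, success = _run_nelder_mead(
        fz, z0, maxfev=maxfev, xatol=xatol, fatol=fatol, restarts=restarts
    )
    fitted = with_values(init, dict(zip(free, np.exp(best_z))))
    return FitResult(
        params=fitted,
        objective=best_f,
        n_evals=n_evals,
        converged=success and n_evals < maxfev,
        free=free,
        init=init,
    )


def estimate_sigmas(
    fit_result: FitResult | MonocultureParams | CocultureParams,
    data: Dataset,
    grouping: str = "cell_type",
    weights=None,
    *,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> dict[str, float]:
    """Unbiased per-group variance of the weighted residuals.

    ``grouping="cell_type"`` pools all streams of each cell type (the
    default error model); ``grouping="stream"`` estimates one variance per
    observation stream.
    """
    params = (
        fit_result.params if isinstance(fit_result, FitResult) else fit_result
    )
    predictor = _Predictor(data, weights=weights, rtol=rtol, atol=atol)
    resid = predictor.weighted_residuals(_full_array(params))
    if grouping == "cell_type":
        labels = data.groups()
    elif grouping == "stream":
        labels = data.records["stream"]
    else:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    out: dict[str, float] = {}
    for group, idx in labels.groupby(labels).groups.items():
        values = resid[np.asarray(idx, dtype=np.intp)]
        if len(values) < 2:
            raise ValueError(
                f"error group {group!r} has fewer than 2 residuals"
            )
        out[str(group)] = float(np.var(values, ddof=1))
    return out


@dataclass(frozen=True)
class BootstrapResult:
    """Parametric-bootstrap replicate estimates and percentile intervals."""

    replicates: pd.DataFrame  # one row per simulated data set, columns = free
    estimates: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    sigma_estimates: dict[str, float]
    n_replicates: int
    level: float
    seed: int | None
    n_failures: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "estimate": self.estimates[name],
                "ci_low": self.ci_low[name],
                "ci_high": self.ci_high[name],
            }
            for name in self.replicates.columns
        ]
        return pd.DataFrame(rows)


def bootstrap_ci(
    fit_result: FitResult,
    data: Dataset,
    n_replicates: int = 300,
    level: float = 0.95,
    seed: int | None = 0,
    *,
    grouping: str = "cell_type",
    weights=None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    maxfev: int = 20_000,
    xatol: float = 1e-4,
    fatol: float = 1e-9,
    restarts: int = 0,
) -> BootstrapResult:
    """Parametric bootstrap around a converged fit.

    Each replicate simulates the model at the fitted constants, adds
    independent centred Gaussian noise per error group (variances from
    :func:`estimate_sigmas`), truncates negative observations at zero,
    and refits the free constants starting from the fitted values.  The
    ``level`` percentile interval is taken per parameter.  Bit-reproducible
    given ``seed``.  Aborts if more than 10% of replicate refits fail.
    """
    if not fit_result.converged:
        raise ConfigurationError("bootstrap requires a converged fit")
    predictor = _Predictor(data, weights=weights, rtol=rtol, atol=atol)
    sigmas = estimate_sigmas(
        fit_result, data, grouping=grouping, weights=weights,
        rtol=rtol, atol=atol,
    )
    if grouping == "cell_type":
        labels = data.groups()
    else:
        labels = data.records["stream"]
    sigma_rec = labels.map(sigmas).to_numpy(float) ** 0.5

    base = _full_array(fit_result.params)
    free = fit_result.free
    free_idx = np.array([_flat_index(n) for n in free], dtype=np.intp)
    z_hat = np.log(base[free_idx])
    pred_weighted = predictor.predict_natural(base) / predictor.rec_weight

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_replicates, len(pred_weighted)))

    rows = np.full((n_replicates, len(free)), np.nan)
    n_failures = 0
    for b in range(n_replicates):
        obs_b = np.clip(pred_weighted + sigma_rec * noise[b], 0.0, None)

        def fz(z):
            p = base.copy()
            p[free_idx] = np.exp(np.clip(z, -700.0, 700.0))
            return predictor.sse(p, obs_weighted=obs_b)

        z_b, f_b, _, _ = _run_nelder_mead(
            fz, z_hat, maxfev=maxfev, xatol=xatol, fatol=fatol,
            restarts=restarts,
        )
        if f_b >= PENALTY:
            n_failures += 1
            continue
        rows[b] = np.exp(z_b)
    if n_failures > 0.1 * n_replicates:
        raise RuntimeError(
            f"{n_failures}/{n_replicates} bootstrap refits failed; "
            "check the fit and noise estimates"
        )
    replicates = pd.DataFrame(rows, columns=list(free)).dropna()
    alpha = (1.0 - level) / 2.0
    lows = replicates.quantile(alpha)
    highs = replicates.quantile(1.0 - alpha)
    estimates = {n: get_value(fit_result.params, n) for n in free}
    return BootstrapResult(
        replicates=replicates,
        estimates=estimates,
        ci_low={n: float(lows[n]) for n in free},
        ci_high={n: float(highs[n]) for n in free},
        sigma_estimates=sigmas,
        n_replicates=n_replicates,
        level=level,
        seed=seed,
        n_failures=n_failures,
    )


def sensitivity_table(
    boot: BootstrapResult | pd.DataFrame,
) -> pd.DataFrame:
    """Rank constants by normalized 95%-interval width.

    Each interval is divided by its point estimate (normalizing the
    estimate to 1); narrow relative intervals mark constants the objective
    is most sensitive to.  Accepts a :class:`BootstrapResult` or a tidy
    table with columns (parameter, estimate, ci_low, ci_high) — e.g. the
    packaged published intervals.  Constants with a zero point estimate are
    flagged rather than divided and sort last.  Output ordering is
    invariant under permutations of the input rows.
    """
    if isinstance(boot, BootstrapResult):
        table = boot.summary()
    else:
        table = boot.loc[:, ["parameter", "estimate", "ci_low", "ci_high"]].copy()
    est = table["estimate"].to_numpy(float)
    zero = est == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        low_rel = np.where(zero, np.nan, table["ci_low"] / est)
        high_rel = np.where(zero, np.nan, table["ci_high"] / est)
    out = pd.DataFrame(
        {
            "parameter": table["parameter"],
            "estimate": est,
            "low_over_est": low_rel,
            "high_over_est": high_rel,
            "rel_width": high_rel - low_rel,
            "flagged_zero_estimate": zero,
        }
    )
    out = out.sort_values(
        ["flagged_zero_estimate", "rel_width", "parameter"],
        ascending=[True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
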
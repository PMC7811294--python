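"""Objective, Nelder–Mead fitting and residual-variance estimation."""

import numpy as np
import pandas as pd
import pytest

import glnrecycle as gr
from glnrecycle.exceptions import ConfigurationError
from glnrecycle.fit import default_free
from glnrecycle.model import ModelVariant
from glnrecycle.simulate import Scenario


def _toy_dataset(observations, A0=1.0):
    """Constant-model dataset: all rates zero, so predicted Gln stays A0."""
    sc = Scenario(
        variant=ModelVariant.CAF_MONO, A0=A0, X0=8e4,
        obs_times=(0.0, 24.0, 48.0), horizon=48.0, scenario_id="toy",
    )
    records = pd.DataFrame(
        [
            {"scenario_id": "toy", "time_h": t, "stream": "Gln_mM", "value": v}
            for t, v in observations
        ]
    )
    return gr.Dataset(records, {"toy": sc}, "CAF")


def test_objective_zero_on_matched_noiseless_data(caf, caf_noiseless):
    # same solver settings as the generator -> residuals vanish identically
    assert gr.objective(caf, caf_noiseless, rtol=1e-8, atol=1e-10) <= 1e-12


def test_objective_hand_arithmetic():
    zero = gr.MonocultureParams.from_array(np.zeros(12))
    ds = _toy_dataset([(24.0, 2.0), (48.0, 3.0)])  # residuals 1 and 2
    assert gr.objective(zero, ds) == pytest.approx(5.0, rel=1e-12)


def test_objective_record_order_invariance(caf, caf_noisy):
    shuffled = gr.Dataset(
        caf_noisy.records.sample(frac=1.0, random_state=9),
        caf_noisy.scenarios,
        "CAF",
    )
    assert gr.objective(caf, caf_noisy) == pytest.approx(
        gr.objective(caf, shuffled), rel=1e-12
    )


def test_perturbing_a_fitted_parameter_increases_objective(caf, caf_noiseless):
    base = gr.objective(caf, caf_noiseless, rtol=1e-8, atol=1e-10)
    for name in ("r1", "d1", "k1"):
        bumped = caf.replace(**{name: getattr(caf, name) * 1.1})
        assert gr.objective(bumped, caf_noiseless, rtol=1e-8, atol=1e-10) > base


def test_unweighted_mode_dominated_by_counts(caf, caf_noisy):
    weighted = gr.objective(caf, caf_noisy)
    literal = gr.objective(caf, caf_noisy, weights=gr.unweighted_weights())
    assert literal > 1e3 * weighted


def test_missing_stream_weight_rejected(caf, caf_noisy):
    with pytest.raises(ConfigurationError):
        gr.objective(caf, caf_noisy, weights={"Gln_mM": 1.0})


def test_default_free_pins_zero_and_inert_parameters(caf, cc):
    assert default_free(caf) == tuple(
        n for n in ("k1", "c1", "k2", "c2", "h", "k3", "r1", "K1", "r2", "K2",
                    "d1", "d2")
    )
    # r2 = 0 cannot be log-scaled and leaves K2 unidentifiable
    free_cc = default_free(cc)
    assert "r2" not in free_cc and "K2" not in free_cc
    assert len(free_cc) == 10


def test_fit_from_truth_returns_truth(caf, caf_noiseless):
    res = gr.fit(caf_noiseless, caf, restarts=0)
    assert res.objective <= 1e-10
    # flat directions (r2 is tiny, so K2 is barely identified) may wander
    # within the numerical floor; the identified constants must not
    for name in ("r1", "d1", "k1", "c1", "c2", "K1", "k2", "h", "k3", "d2"):
        assert getattr(res.params, name) == pytest.approx(
            getattr(caf, name), rel=1e-3
        )


def test_fit_is_deterministic(caf, caf_noisy):
    a = gr.fit(caf_noisy, caf, free=("r1", "d1"), restarts=0)
    b = gr.fit(caf_noisy, caf, free=("r1", "d1"), restarts=0)
    assert a.params == b.params and a.objective == b.objective


def test_pinned_parameters_unchanged_bit_for_bit(merged, caf_noisy, stress):
    """The coculture refit strategy: free only the two growth rates and
    every other constant passes through bit-identically."""
    design = gr.DesignSpec(
        cell_type="coculture", gln_doses=(4.0,), nh4_doses=(5.0,), noise=0.1
    )
    ds = gr.generate(design, merged, seed=2)
    res = gr.fit(ds, merged, free=("caf.r1", "cc.r1"), restarts=0)
    for name in (
        "caf.k1", "caf.d1", "caf.K2", "cc.k1", "cc.d1", "cc.d2",
    ):
        assert gr.params.get_value(res.params, name) == gr.params.get_value(
            merged, name
        )


def test_noiseless_fit_beats_perturbed_start_by_many_orders(caf, caf_noiseless):
    init = caf.replace(r1=caf.r1 * 1.5, d1=caf.d1 * 1.5, k1=caf.k1 * 1.5)
    start = gr.objective(init, caf_noiseless)
    res = gr.fit(caf_noiseless, init, free=("r1", "d1", "k1"), restarts=1)
    assert res.objective <= 1e-6 * start


def test_free_parameter_must_be_positive(cc, cc_noiseless):
    with pytest.raises(ConfigurationError):
        gr.fit(cc_noiseless, cc, free=("r2",))


class TestEstimateSigmas:
    def test_exact_data_gives_zero_variances(self, caf, caf_noiseless):
        sig = gr.estimate_sigmas(caf, caf_noiseless, rtol=1e-8, atol=1e-10)
        assert set(sig) == {"CAF"}
        assert sig["CAF"] <= 1e-20

    def test_hand_arithmetic_plus_minus_one(self):
        zero = gr.MonocultureParams.from_array(np.zeros(12))
        ds = _toy_dataset([(24.0, 2.0), (48.0, 0.0)])  # residuals -1, +1
        sig = gr.estimate_sigmas(zero, ds)
        assert sig["CAF"] == pytest.approx(2.0, rel=1e-12)

    def test_single_residual_group_rejected(self):
        zero = gr.MonocultureParams.from_array(np.zeros(12))
        ds = _toy_dataset([(24.0, 2.0)])
        with pytest.raises(ValueError):
            gr.estimate_sigmas(zero, ds)

    def test_per_stream_grouping(self, caf, caf_noisy):
        sig = gr.estimate_sigmas(caf, caf_noisy, grouping="stream")
        assert set(sig) == {"Gln_mM", "NH4_mM", "cells_CAF"}

    def test_injected_noise_recovered(self, caf):
        """sigma estimated from residuals tracks the injected noise level
        (sigma/sqrt(3) after triplicate averaging) across seeded draws."""
        sigma = 0.5
        target = sigma / np.sqrt(3)
        design = gr.DesignSpec(cell_type="CAF", noise=sigma)
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            ds = gr.generate(design, caf, seed=seed)
            est = np.sqrt(gr.estimate_sigmas(caf, ds)["CAF"])
            hits += 0.8 * target <= est <= 1.2 * target
        assert hits >= 0.9 * n_runs
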
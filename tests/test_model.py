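"""Unit and property tests of the model right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glnrecycle as gr
from glnrecycle.exceptions import ConfigurationError
from glnrecycle.model import ModelVariant, SystemState, rhs_array


def _d(state: SystemState) -> dict:
    return {k: getattr(state, k) for k in ("A", "W", "R", "X", "Y", "L")}


class TestMonocultureRHS:
    def test_no_cells_no_dynamics(self, caf):
        d = gr.monoculture_rhs(SystemState(A=3.0, W=7.0, R=20.0, X=0.0), caf)
        assert (d.A, d.W, d.R, d.X) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_substitution_at_zero_substrates(self, caf):
        # A=W=0: only basal NH4+ production and energy consumption remain
        d = gr.monoculture_rhs(SystemState(A=0.0, W=0.0, R=20.0, X=8e4), caf)
        assert d.A == 0.0
        assert d.W == pytest.approx(1.28e-3, rel=1e-12)
        assert d.R == pytest.approx(-0.336, rel=1e-12)

    def test_perfect_conversion_conserves_total_nitrogen_pool(self, caf):
        # with unit yields and no basal production, Gln + NH4+ is conserved
        p = caf.replace(c1=1.0, c2=1.0, h=0.0)
        d = gr.monoculture_rhs(SystemState(A=2.5, W=8.0, R=13.0, X=5e4), p)
        assert d.A + d.W == pytest.approx(0.0, abs=1e-18)

    def test_negative_state_rejected(self, caf):
        with pytest.raises(ValueError):
            gr.monoculture_rhs(SystemState(A=-0.1, W=0.0, R=20.0, X=1e4), caf)


class TestCocultureRHS:
    def test_reduces_to_caf_monoculture_without_cancer_cells(self, merged):
        state = SystemState(A=1.2, W=4.0, R=17.0, X=6e4, Y=0.0)
        d = gr.coculture_rhs(state, merged, ModelVariant.COCULTURE_MERGED)
        mono = gr.monoculture_rhs(
            SystemState(A=1.2, W=4.0, R=17.0, X=6e4), merged.caf
        )
        assert (d.A, d.W, d.R, d.X) == (mono.A, mono.W, mono.R, mono.X)
        assert d.Y == 0.0

    def test_reduces_to_cc_monoculture_without_cafs(self, merged):
        state = SystemState(A=1.2, W=4.0, R=17.0, X=0.0, Y=6e4)
        d = gr.coculture_rhs(state, merged, ModelVariant.COCULTURE_MERGED)
        mono = gr.monoculture_rhs(
            SystemState(A=1.2, W=4.0, R=17.0, X=6e4), merged.cc
        )
        assert (d.A, d.W, d.R, d.Y) == (mono.A, mono.W, mono.R, mono.X)
        assert d.X == 0.0

    def test_stress_production_hand_substitution(self, stress):
        state = SystemState(A=0.0, W=5.0, R=20.0, X=4e4, Y=4e4, L=0.0)
        d = gr.coculture_rhs(state, stress, ModelVariant.COCULTURE_STRESS)
        assert d.L == pytest.approx(1120.0, rel=1e-12)

    def test_zero_stress_level_matches_merged_growth(self, stress):
        state = SystemState(A=2.0, W=5.0, R=20.0, X=4e4, Y=4e4, L=0.0)
        d_stress = gr.coculture_rhs(state, stress, ModelVariant.COCULTURE_STRESS)
        d_merged = gr.coculture_rhs(state, stress, ModelVariant.COCULTURE_MERGED)
        assert d_stress.X == d_merged.X
        assert d_stress.Y == d_merged.Y

    def test_normalized_variant_removes_caf_recycling(self, merged):
        state = SystemState(A=0.0, W=5.0, R=20.0, X=4e4, Y=0.0)
        d = gr.coculture_rhs(state, merged, ModelVariant.COCULTURE_NORMALIZED)
        # without CAF k2 and without cancer cells, no Gln source remains
        assert d.A == 0.0

    def test_stress_variant_requires_constants(self, merged):
        state = SystemState(A=0.0, W=5.0, R=20.0, X=4e4, Y=4e4, L=0.0)
        with pytest.raises(ConfigurationError):
            gr.coculture_rhs(state, merged, ModelVariant.COCULTURE_STRESS)

    def test_mono_variant_rejected(self, merged):
        with pytest.raises(ConfigurationError):
            gr.coculture_rhs(
                SystemState(A=0, W=0, R=20, X=1e4), merged, ModelVariant.CAF_MONO
            )


# -- boundary nonnegativity: each component's derivative is >= 0 whenever
#    that component is 0 and the rest of the state is nonnegative ---------

_conc = st.floats(0.0, 30.0, allow_nan=False)
_count = st.floats(0.0, 3e5, allow_nan=False)
_pos = st.floats(1e-10, 1.0, allow_nan=False)


@st.composite
def _mono_params(draw):
    vals = {
        "k1": draw(_pos) * 1e-6, "c1": draw(_pos) * 2, "k2": draw(_pos) * 1e-7,
        "c2": draw(_pos), "h": draw(_pos) * 1e-6, "k3": draw(_pos) * 1e-6,
        "r1": draw(_pos) * 0.1, "K1": draw(_pos) * 5, "r2": draw(_pos) * 1e-5,
        "K2": draw(_pos) * 10, "d1": draw(_pos) * 1e-2, "d2": draw(_pos) * 1e-3,
    }
    return gr.MonocultureParams.from_dict(vals)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(params=_mono_params(), A=_conc, W=_conc, R=_conc, X=_count)
def test_monoculture_boundary_derivatives_nonnegative(params, A, W, R, X):
    base = SystemState(A=A, W=W, R=R, X=X)
    for zeroed in ("A", "W", "R", "X"):
        state = SystemState(**{**_mono_state_dict(base), zeroed: 0.0})
        d = gr.monoculture_rhs(state, params)
        assert getattr(d, zeroed) >= 0.0


def _mono_state_dict(state):
    return {k: getattr(state, k) for k in ("A", "W", "R", "X")}


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    caf_p=_mono_params(), cc_p=_mono_params(),
    A=_conc, W=_conc, R=_conc, X=_count, Y=_count,
    L=st.floats(0.0, 1e4, allow_nan=False),
)
def test_stress_coculture_boundary_derivatives_nonnegative(
    caf_p, cc_p, A, W, R, X, Y, L
):
    params = gr.CocultureParams(caf=caf_p, cc=cc_p, g=7e-7, m=1e-11)
    base = {"A": A, "W": W, "R": R, "X": X, "Y": Y, "L": L}
    for zeroed in base:
        state = SystemState(**{**base, zeroed: 0.0})
        d = gr.coculture_rhs(state, params, ModelVariant.COCULTURE_STRESS)
        assert getattr(d, zeroed) >= 0.0
    # monotone reservoirs: R only drains, L only accumulates
    d = gr.coculture_rhs(SystemState(**base), params, ModelVariant.COCULTURE_STRESS)
    assert d.R <= 0.0
    assert d.L >= 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(params=_mono_params(), A=_conc, W=_conc, R=_conc, X=_count)
def test_perfect_conversion_invariant_holds_for_any_state(params, A, W, R, X):
    p = params.replace(c1=1.0, c2=1.0, h=0.0)
    d = gr.monoculture_rhs(SystemState(A=A, W=W, R=R, X=X), p)
    scale = max(abs(d.A), abs(d.W), 1e-30)
    assert abs(d.A + d.W) <= 1e-12 * scale


def test_rhs_array_agrees_with_reference(stress):
    y = np.array([1.5, 6.0, 18.0, 5e4, 3e4, 100.0])
    d = rhs_array(y, stress, ModelVariant.COCULTURE_STRESS)
    ref = gr.coculture_rhs(
        SystemState(A=1.5, W=6.0, R=18.0, X=5e4, Y=3e4, L=100.0),
        stress,
        ModelVariant.COCULTURE_STRESS,
    )
    np.testing.assert_allclose(
        d, [ref.A, ref.W, ref.R, ref.X, ref.Y, ref.L], rtol=1e-14
    )
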
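import numpy as np
import pytest

import glnrecycle as gr


@pytest.fixture(scope="session")
def caf():
    return gr.caf_params()


@pytest.fixture(scope="session")
def cc():
    return gr.cc_params()


@pytest.fixture(scope="session")
def merged():
    return gr.coculture_params("coculture_merged")


@pytest.fixture(scope="session")
def stress():
    return gr.coculture_params("coculture_stress")


@pytest.fixture(scope="session")
def caf_noiseless(caf):
    """Noiseless synthetic CAF experiment on the standard dosing design."""
    return gr.generate(gr.DesignSpec(cell_type="CAF", noise=0.0), caf, seed=0)


@pytest.fixture(scope="session")
def cc_noiseless(cc):
    return gr.generate(gr.DesignSpec(cell_type="CC", noise=0.0), cc, seed=0)


@pytest.fixture(scope="session")
def caf_noisy(caf):
    """CAF experiment with the default triplicate-averaged noise."""
    return gr.generate(gr.DesignSpec(cell_type="CAF", noise=0.2), caf, seed=11)


def params_to_dict(p: gr.MonocultureParams) -> dict:
    return p.to_dict()


@pytest.fixture(scope="session", autouse=True)
def _warm_compiled_kernels(caf, merged, stress):
    """Trigger numba compilation once so timings elsewhere are honest."""
    sc = gr.Scenario(variant=gr.ModelVariant.CAF_MONO, A0=1.0, X0=1e4)
    gr.simulate(sc, caf)
    for variant, params in (
        (gr.ModelVariant.COCULTURE_MERGED, merged),
        (gr.ModelVariant.COCULTURE_STRESS, stress),
    ):
        gr.simulate(
            gr.Scenario(variant=variant, W0=5.0, X0=1e4, Y0=1e4), params
        )
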
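import numpy as np
import pytest

from cellsizer.presets import build_default_genome
from cellsizer.theory import TheoryInputs


@pytest.fixture(scope="session")
def default_model():
    """Calibrated reference genome and its global parameters."""
    genome, params = build_default_genome()
    return genome, params


@pytest.fixture(scope="session")
def theory_inputs(default_model):
    genome, params = default_model
    return TheoryInputs.from_genome(genome, params)


@pytest.fixture(scope="session")
def fig_panel_model():
    """Multi-regulator parameter point: 10 activators, 10 inhibitors,
    strong inhibitor promoters (K = 1000 um^-3)."""
    genome, params = build_default_genome(g_act=10, g_inh=10, K_inh=1000.0)
    return genome, params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
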
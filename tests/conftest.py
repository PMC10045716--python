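import numpy as np
import pytest

import hemotherm.circulation as circ
import hemotherm.parameters as par
from hemotherm.fitting import ForwardModel


@pytest.fixture(scope="session")
def perfusion_table() -> par.PerfusionTable:
    return par.load_perfusion_table()


@pytest.fixture(scope="session")
def delta(perfusion_table) -> par.PerfusionFractions:
    return par.perfusion_fractions(perfusion_table)


@pytest.fixture(scope="session")
def default_params() -> circ.CVSParameters:
    return circ.CVSParameters.default()


@pytest.fixture(scope="session")
def default_sim(default_params) -> circ.SimulationResult:
    """Tightly converged periodic steady state of the default circuit,
    shared across tests (the simulation is deterministic)."""
    return circ.simulate_cvs(default_params, tol_pss=0.01, n_max_cycles=300)


@pytest.fixture(scope="session")
def forward_model() -> ForwardModel:
    return ForwardModel()
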
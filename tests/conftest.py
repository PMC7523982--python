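import pytest

from migsflow import CavityProblem, EyeParameters, get_device, solve_cavity


@pytest.fixture
def xen45():
    return get_device("XEN 45")


@pytest.fixture
def xen63():
    return get_device("XEN 63")


@pytest.fixture
def preserflo():
    return get_device("PreserFlo")


@pytest.fixture
def eye30():
    return EyeParameters(p_g=30.0)


@pytest.fixture(scope="session")
def cavity_solution():
    """Shared pure-convection solve at moderate resolution."""
    problem = CavityProblem(grid=(64, 32), inflow_ul_min=0.0)
    return solve_cavity(problem)
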
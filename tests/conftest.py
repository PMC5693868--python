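import numpy as np
import pytest

from furrowsim.force_schedule import build_schedule
from furrowsim.geometry import GeometryConfig, assign_domains, build_embryo
from furrowsim.solver import Simulator, SolverConfig


@pytest.fixture(scope="session")
def mesh84():
    return build_embryo()


@pytest.fixture(scope="session")
def labels84(mesh84):
    return assign_domains(mesh84)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarser, faster ring for integrator-level tests."""
    return build_embryo(GeometryConfig(n_cells=28))


@pytest.fixture(scope="session")
def small_labels(small_mesh):
    return assign_domains(small_mesh)


def _run(genotype):
    mesh = build_embryo()
    labels = assign_domains(mesh)
    sim = Simulator(mesh, labels, build_schedule(genotype), SolverConfig())
    return sim.run()


@pytest.fixture(scope="session")
def wt_trajectory():
    """Full wild-type run at default settings."""
    return _run("wildtype")


@pytest.fixture(scope="session")
def neur_trajectory():
    return _run("neur")


@pytest.fixture(scope="session")
def brd_trajectory():
    return _run("brd")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
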
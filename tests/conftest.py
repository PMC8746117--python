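import numpy as np
import pytest

from corticonn.connectome import DistanceMatrix, FLNMatrix
from corticonn.network import NetworkSpec, PopulationSpec, run_simulation
from corticonn.synthetic import (
    SyntheticConnectomeParams,
    generate_distances,
    generate_fln,
)


@pytest.fixture(scope="session")
def fln19():
    return generate_fln(SyntheticConnectomeParams(n_areas=19, seed=7))


@pytest.fixture(scope="session")
def tiny_spec():
    """2 areas x 300 neurons, 2 s: a fast but fully wired network."""
    fln = FLNMatrix(np.array([[0.0, 0.4], [0.3, 0.0]]))
    dist = DistanceMatrix(np.array([[0.0, 7.0], [7.0, 0.0]]))
    pop = PopulationSpec(N_E=240, N_I=60)
    return NetworkSpec(fln=fln, distances=dist, duration=2.0, seed=5, population=pop)


@pytest.fixture(scope="session")
def tiny_run(tiny_spec):
    return run_simulation(tiny_spec)
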
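import numpy as np
import pytest

from ripchip.preprocess import build_expression_matrix
from ripchip.simulate import SimulationParams, generate_experiment


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_probes=3000, seed=11, n_gene_sets=12,
                            set_size_range=(10, 40))


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return generate_experiment(small_params)


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    scans, _ = small_experiment
    return build_expression_matrix(scans)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
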
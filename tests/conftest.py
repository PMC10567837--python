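import numpy as np
import pytest

from polyff.descriptors import DescriptorConfig
from polyff.model import QRNNHyper, QRNNModel
from polyff.oracle import OracleCalculator, build_liquid_cell, generate_chain, oracle_label
from polyff.system import AtomicSystem, Dataset


def random_cluster(rng, n, elements=("H", "C", "O"), min_dist=0.75, scale=2.0):
    """Random well-separated cluster for numeric checks."""
    from scipy.spatial.distance import pdist
    species = list(rng.choice(elements, size=n))
    pos = rng.normal(scale=scale, size=(n, 3))
    while n > 1 and pdist(pos).min() < min_dist:
        pos = rng.normal(scale=scale * 1.1, size=(n, 3))
    return AtomicSystem(species, pos)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_model():
    """Small untrained QRNN (random weights) for structural checks."""
    return QRNNModel(DescriptorConfig.desk_scale(),
                     QRNNHyper(chi_hidden=(16,), energy_hidden=(16,)), seed=7)


@pytest.fixture(scope="session")
def monomer_chain():
    return generate_chain(1, seed=11)


@pytest.fixture(scope="session")
def dimer_chain():
    return generate_chain(2, seed=5)


@pytest.fixture(scope="session")
def small_cell():
    """Packed monomer liquid cell (≈80 atoms) shared by sampler/scan tests."""
    return build_liquid_cell(8, 1, 0.5, seed=3)


@pytest.fixture(scope="session")
def _tiny_samples(small_cell):
    from polyff.sampler import SamplingPlan, build_training_pool
    cell, topo = small_cell
    pool = build_training_pool([(cell, topo, 1)],
                               SamplingPlan(n_conformational=30, n_decomposed=6,
                                            seed=2))
    return [oracle_label(p.system, p.topology, provenance=p.provenance)
            for p in pool]


@pytest.fixture
def tiny_dataset(_tiny_samples):
    """A small labeled cluster dataset; fresh container per test (tests may
    assign splits or append samples)."""
    return Dataset(list(_tiny_samples))
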
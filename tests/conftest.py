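import numpy as np
import pytest

from progsig.io_data import ExpressionMatrix, PhenotypeTable
from progsig.network import PPINetwork
from progsig.synthetic_data import SimulationConfig, simulate_dataset


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(tuple(genes), tuple(samples), values)


def make_pheno(labels, survival=None, samples=None) -> PhenotypeTable:
    n = len(labels)
    samples = samples or [f"s{i}" for i in range(n)]
    if survival is None:
        survival = [7.0 if l == "GP" else 0.5 for l in labels]
    return PhenotypeTable(tuple(samples), np.array(labels, dtype=object), np.array(survival))


@pytest.fixture
def star_network():
    """Hub H with interactors A..E plus one interactor-interactor edge A-B."""
    return PPINetwork([("H", c) for c in "ABCDE"] + [("A", "B")])


@pytest.fixture(scope="session")
def default_sim():
    """The default planted-signal simulation, shared across expensive tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_sim():
    """A no-signal simulation (all plants disabled)."""
    return simulate_dataset(
        SimulationConfig(seed=3, n_de_genes=0, n_de_sets=0, n_flip_hubs=0)
    )
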
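import numpy as np
import pandas as pd
import pytest

from synpas.io import GeneNetwork, PathwayCollection
from synpas.simulate import SimulationConfig, simulate_inputs

# A deliberately small configuration for fast unit tests (not the reference
# study conditions, which live in SimulationConfig's defaults).
SMALL_CONFIG = SimulationConfig(
    n_genes=300,
    n_cell_lines=8,
    n_pathways=30,
    pathway_size_range=(5, 12),
    n_drugs=6,
    targets_per_drug=2,
    n_causal_pathways=2,
    n_experiments=80,
    network_edge_density=0.01,
    driver_pool_size=40,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """A small but complete simulated input bundle shared across tests."""
    network, pathways, expression, drivers, targets, experiments, truth = (
        simulate_inputs(SMALL_CONFIG)
    )
    return {
        "network": network,
        "pathways": pathways,
        "expression": expression,
        "drivers": drivers,
        "targets": targets,
        "experiments": experiments,
        "truth": truth,
    }


@pytest.fixture()
def chain_network():
    """a -> b -> t -> c -> d, the reference chain for partition tests."""
    return GeneNetwork.from_edges([("a", "b"), ("b", "t"), ("t", "c"), ("c", "d")])


@pytest.fixture()
def toy_pathways():
    return PathwayCollection(
        entries={
            "P1": frozenset({"a", "b", "t"}),
            "P2": frozenset({"c", "d"}),
        }
    )
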
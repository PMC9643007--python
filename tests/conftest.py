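import numpy as np
import pandas as pd
import pytest

from netpert import (
    InteractionNetwork,
    SimConfig,
    build_perturbation,
    differential_edge_test,
    select_representative_network,
    simulate_cohort,
    tumor_variability,
)

GENES4 = ["g1", "g2", "g3", "g4"]
EDGES4 = [("g1", "g2"), ("g2", "g3"), ("g3", "g4")]


@pytest.fixture()
def toy_net() -> InteractionNetwork:
    """Four genes on a path: the worked example network."""
    return InteractionNetwork.from_edges(EDGES4)


@pytest.fixture()
def toy_normals() -> pd.DataFrame:
    return pd.DataFrame({"N1": [1.0, 2, 3, 4], "N2": [3.0, 4, 1, 2]}, index=GENES4)


@pytest.fixture()
def toy_tumor() -> pd.DataFrame:
    return pd.DataFrame({"T1": [5.0, 1, 3, 2]}, index=GENES4)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator at its default study conditions (seed 1)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pert(default_cohort):
    return build_perturbation(
        default_cohort.expr, default_cohort.phenotype, default_cohort.net
    )


@pytest.fixture(scope="session")
def default_selection(default_cohort, default_pert):
    stats = differential_edge_test(default_pert, default_cohort.phenotype)
    var = tumor_variability(default_pert, default_cohort.phenotype)
    sel = select_representative_network(stats, var, default_cohort.net)
    return stats, var, sel


@pytest.fixture(scope="session")
def mini_cohort():
    """Small cohort for the reduced-panel classifier chain."""
    return simulate_cohort(
        SimConfig(n_genes=300, edges_per_subtype=2, n_tumors=300, n_normals=30, seed=1)
    )


def incident_edges(cohort, edge_index):
    """Edges touching a swapped gene but not planted (genuinely perturbed)."""
    planted = set(cohort.all_perturbed_edges)
    swapped = set(cohort.all_informative_genes)
    out = set()
    for eid in edge_index:
        a, _, b = eid.partition("|")
        if (a in swapped or b in swapped) and eid not in planted:
            out.add(eid)
    return out
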
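import numpy as np
import pytest

import vennrank as vr
from vennrank.ppi_network import PpiGraph, TransitionMatrix, column_normalize


@pytest.fixture(scope="session")
def default_fixture() -> vr.Fixture:
    """The default synthetic dataset (300-gene universe, planted C2->C1 link)."""
    return vr.generate(vr.FixtureSpec())


@pytest.fixture(scope="session")
def fixture_dir(default_fixture, tmp_path_factory):
    """Default fixture written out as a ready-to-run directory."""
    out = tmp_path_factory.mktemp("fixture")
    paths = default_fixture.write(out)
    return paths


def random_experiments(rng: np.random.Generator, n: int, universe: int):
    """Random experiments for partition oracle tests: each gene joins each
    experiment independently with probability 1/2."""
    genes = [f"g{i}" for i in range(universe)]
    exps = []
    for j in range(n):
        member = [g for g in genes if rng.random() < 0.5]
        exps.append(
            vr.Experiment(
                name=f"E{j + 1}",
                records=[vr.DegRecord(f"t{j}.{g}", g) for g in member],
            )
        )
    return exps


def random_transition(rng: np.random.Generator, n_nodes: int, p: float = 0.05):
    """Column-normalized transition matrix of an Erdos-Renyi graph."""
    upper = rng.random((n_nodes, n_nodes)) < p
    A = np.triu(upper, k=1)
    A = (A | A.T).astype(float)
    graph = PpiGraph(nodes=[f"n{i:04d}" for i in range(n_nodes)], adjacency=A)
    return graph, column_normalize(graph)
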
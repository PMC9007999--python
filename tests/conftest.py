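import itertools

import numpy as np
import pandas as pd
import pytest

from oncodag.graphs import Graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_frame():
    """X -> Y -> Z with strong coefficients and small noise (n=500)."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=500)
    y = x + 0.1 * rng.normal(size=500)
    z = y + 0.1 * rng.normal(size=500)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})


@pytest.fixture
def collider_frame():
    """A -> C <- B with strong coefficients (n=500)."""
    rng = np.random.default_rng(11)
    a = rng.normal(size=500)
    b = rng.normal(size=500)
    c = a + b + 0.2 * rng.normal(size=500)
    return pd.DataFrame({"A": a, "B": b, "C": c})


@pytest.fixture
def independent_frame():
    rng = np.random.default_rng(13)
    return pd.DataFrame(rng.normal(size=(500, 4)), columns=list("ABCD"))


def all_dags(nodes):
    """Every DAG over the given nodes (for brute-force oracles)."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = Graph(nodes)
        for (a, b), st in zip(pairs, states):
            if st == 1:
                g.arcs.add((a, b))
            elif st == 2:
                g.arcs.add((b, a))
        if g.is_acyclic():
            yield g


def random_dag(nodes, density, rng):
    g = Graph(nodes)
    order = list(nodes)
    rng.shuffle(order)
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if rng.random() < density:
                g.arcs.add((a, b))
    return g
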
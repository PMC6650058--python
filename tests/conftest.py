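"""Shared fixtures: small hand-built alignments and cached simulated datasets."""

import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.seqio import Alignment
from barcodelim.simulate import frozen_fixture


@pytest.fixture(scope="session")
def clean_dataset():
    return frozen_fixture("clean")


@pytest.fixture(scope="session")
def discordant_dataset():
    return frozen_fixture("discordant")


@pytest.fixture(scope="session")
def synonym_dataset():
    return frozen_fixture("synonym")


@pytest.fixture
def toy_alignment():
    """4 sequences x 12 columns with one informative and one singleton site."""
    return Alignment(
        ids=["a", "b", "c", "d"],
        sequences=[
            "AAAAAAAAAAAA",
            "AAAAAAAAAAAA",
            "AGAAAAAAAAAA",
            "AGATAAAAAAAA",
        ],
        locus_name="toy",
    )


def random_additive_matrix(n: int, rng: np.random.Generator):
    """Random unrooted binary tree -> exact additive distance matrix.

    Built by sequential leaf attachment onto random edges (independent of the
    NJ implementation); returns (DistanceMatrix, adjacency dict).
    """
    adj: dict[int, list[tuple[int, float]]] = {}

    def connect(a, b, l):
        adj.setdefault(a, []).append((b, l))
        adj.setdefault(b, []).append((a, l))

    c = n
    connect(0, c, rng.uniform(0.05, 1.0))
    connect(1, c, rng.uniform(0.05, 1.0))
    connect(2, c, rng.uniform(0.05, 1.0))
    for leaf in range(3, n):
        all_edges = [(a, b, l) for a in adj for b, l in adj[a] if a < b]
        a, b, l = all_edges[rng.integers(len(all_edges))]
        c += 1
        adj[a] = [(x, l2) for x, l2 in adj[a] if x != b]
        adj[b] = [(x, l2) for x, l2 in adj[b] if x != a]
        f = rng.uniform(0.2, 0.8)
        connect(a, c, l * f)
        connect(b, c, l * (1 - f))
        connect(leaf, c, rng.uniform(0.05, 1.0))

    D = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        for t in range(n):
            D[s, t] = dist[t]
    ids = [f"T{i}" for i in range(n)]
    return (
        DistanceMatrix(ids=ids, d=D, defined=np.ones((n, n), dtype=bool)),
        adj,
    )
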
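from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from centrality_cosdist import SeedSet, compute_centrality_matrix, fixture


@pytest.fixture
def triangle() -> nx.Graph:
    return fixture("triangle")


@pytest.fixture
def path3() -> nx.Graph:
    return fixture("path3")


@pytest.fixture
def two_blocks_tiny():
    return fixture("two_blocks_tiny")


@pytest.fixture
def diamond_demo():
    return fixture("diamond_demo")


@pytest.fixture
def triangle_matrix(triangle):
    return compute_centrality_matrix(triangle, SeedSet("s", ("a",)))


def random_graph(n_nodes: int, p: float, seed: int, ensure_edge: bool = True) -> nx.Graph:
    """Seeded G(n, p) with string node labels (any connectivity)."""
    rng = np.random.default_rng(seed)
    names = [f"v{i:02d}" for i in range(n_nodes)]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                G.add_edge(names[i], names[j])
    if ensure_edge and G.number_of_edges() == 0:
        G.add_edge(names[0], names[1])
    return G


def frame(vectors: dict[str, list[float]], columns: list[str] | None = None) -> pd.DataFrame:
    """Feature matrix from literal node->vector mappings (sorted row order)."""
    ids = sorted(vectors)
    ncol = len(next(iter(vectors.values())))
    cols = columns or [f"f{i}" for i in range(ncol)]
    return pd.DataFrame(
        [vectors[i] for i in ids], index=pd.Index(ids, name="node_id"), columns=cols
    )
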
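"""Planted-seed-module benchmark networks and small named fixtures.

Real effector-target seed sets sit inside co-expression/PPI communities
that are denser and more central than background. The generator emulates
exactly that structure with a stochastic block model (SBM): a small dense
block (the seed module) plus larger sparse background block(s). A fraction
of the dense block is handed out as seeds; the remainder is the held-out
ground truth a ranker should recover.

Node identifiers are zero-padded integers assigned to blocks by a random
permutation drawn from the generator's rng, so lexicographic order carries
no information about block membership. Edges are sampled one Bernoulli
draw per node pair from ``numpy.random.default_rng(rng_seed)`` (PCG64),
making every graph bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import SeedSet

__all__ = ["PlantedNetworkSpec", "generate_planted_network", "fixture", "FIXTURES"]


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-module benchmark.

    block_sizes — nodes per block; the first block is the seed module.
    p_in / p_out — within- and between-block edge probabilities
    (dimensionless; requires 0 ≤ p_out ≤ p_in ≤ 1 so the planted module is
    assortative). seed_fraction — fraction of the first block revealed as
    seeds. rng_seed — generator seed.
    """

    block_sizes: tuple[int, ...] = (30, 120)
    p_in: float = 0.25
    p_out: float = 0.02
    seed_fraction: float = 1.0 / 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must be positive integers")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if not 0.0 < self.seed_fraction <= 1.0:
            raise ValueError("seed_fraction must be in (0, 1]")


def generate_planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[nx.Graph, SeedSet, list[str]]:
    """Sample an SBM graph, a seed set and the held-out module members.

    Returns ``(graph, seeds, held_out)`` where seeds ∪ held_out is exactly
    the first block. Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = sum(spec.block_sizes)
    width = len(str(n - 1))
    names = [f"n{i:0{width}d}" for i in range(n)]
    # random assignment of identifiers to blocks: label order is uninformative
    perm = rng.permutation(n)
    block_of = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        block_of[perm[start : start + size]] = b
        start += size

    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if block_of[i] == block_of[j] else spec.p_out
            if rng.random() < p:
                G.add_edge(names[i], names[j])
    if G.number_of_edges() == 0:
        raise ValueError("generated graph has zero edges; raise p_in/p_out or sizes")

    first_block = sorted(names[i] for i in range(n) if block_of[i] == 0)
    n_seeds = max(1, round(spec.seed_fraction * len(first_block)))
    seed_ids = first_block[:n_seeds]
    held_out = first_block[n_seeds:]
    return G, SeedSet(name="planted", members=tuple(seed_ids)), held_out


def _triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


def _path3() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c")])


def _star4() -> nx.Graph:
    return nx.Graph([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


def _two_blocks_tiny() -> tuple[nx.Graph, SeedSet]:
    """Two K4 blocks joined by one bridge; one block's corner pair as seeds."""
    G = nx.Graph()
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    for grp in (a, b):
        for i in range(4):
            for j in range(i + 1, 4):
                G.add_edge(grp[i], grp[j])
    G.add_edge("a0", "b0")
    return G, SeedSet(name="tiny", members=("a1", "a2"))


def _diamond_demo() -> tuple[nx.Graph, SeedSet]:
    """Module-expansion demo: x touches both seeds, y one seed + 2 outsiders."""
    G = nx.Graph(
        [
            ("s1", "x"),
            ("s2", "x"),
            ("s1", "y"),
            ("y", "o1"),
            ("y", "o2"),
            ("o1", "o2"),
        ]
    )
    return G, SeedSet(name="diamond_demo", members=("s1", "s2"))


FIXTURES = {
    "triangle": _triangle,
    "path3": _path3,
    "star4": _star4,
    "two_blocks_tiny": _two_blocks_tiny,
    "diamond_demo": _diamond_demo,
}


def fixture(name: str):
    """Return a named example graph (some come with a companion seed set)."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()
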
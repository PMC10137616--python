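"""Comparator rankers: random walk with restart and DIAMOnD.

Both are re-implemented from their standard published definitions and emit
the same ranking-table schema as the cosine ranker, so they plug directly
into the seed-rank evaluation and top-k overlap analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .graph_io import SeedSet

__all__ = ["WalkParameters", "rwr", "diamond"]


@dataclass(frozen=True)
class WalkParameters:
    """Knobs of the restart walk.

    restart_probability — probability of teleporting back to the seeds at
    each step (dimensionless, in (0, 1]); 0.5 is a common prioritization
    default. tolerance — L1 convergence threshold on successive iterates.
    """

    restart_probability: float = 0.5
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability <= 1.0:
            raise ValueError("restart_probability must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


class ConvergenceError(RuntimeError):
    """Iteration did not reach tolerance within the allowed step count."""


def _ranking_frame(nodes: list[str], scores: np.ndarray, seeds: SeedSet) -> pd.DataFrame:
    df = pd.DataFrame({"node_id": nodes, "score": scores})
    df = df.sort_values(
        ["score", "node_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_seed"] = df["node_id"].isin(set(seeds))
    return df


def rwr(
    network: nx.Graph,
    seeds: SeedSet,
    params: WalkParameters = WalkParameters(),
    *,
    weighted: bool = False,
) -> pd.DataFrame:
    """Random walk with restart from the seed set.

    Iterates p ← (1−r)·Wᵀp + r·e from p₀ = e, where W is the
    column-normalised adjacency and e is uniform over the seeds, until the
    L1 change drops below tolerance. Dangling (degree-zero) columns hand
    their mass to the restart vector so the scores remain a probability
    distribution. Nodes unreachable from every seed score 0.
    """
    nodes = sorted(network.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    present = [s for s in seeds if s in index]
    if not present:
        raise ValueError("no seeds present in the network")
    n = len(nodes)
    r = params.restart_probability

    A = nx.to_scipy_sparse_array(
        network, nodelist=nodes, weight="weight" if weighted else None, format="csc"
    ).astype(float)
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    dangling = col_sums == 0.0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, col_sums))
    W = A @ sparse.diags(inv)  # column-stochastic where defined

    e = np.zeros(n)
    e[[index[s] for s in present]] = 1.0 / len(present)
    p = e.copy()
    for _ in range(params.max_iterations):
        leaked = p[dangling].sum()
        p_next = (1.0 - r) * (W @ p + leaked * e) + r * e
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < params.tolerance:
            break
    else:
        raise ConvergenceError(
            f"RWR did not converge in {params.max_iterations} iterations "
            f"(residual {delta:.3e})"
        )
    return _ranking_frame(nodes, p, seeds)


def _hypergeom_tail(N: int, s0: int, k: int, k_s: int) -> Fraction:
    """Tail probability P(X >= k_s) for X ~ Hypergeom(N, s0, k).

    Exact rational arithmetic: candidate selection must break ties by the
    true ordering, and float tails (e.g. scipy's sf) can rank two
    mathematically equal p-values unequally.
    """
    numer = sum(
        math.comb(s0, i) * math.comb(N - s0, k - i)
        for i in range(k_s, min(s0, k) + 1)
        if k - i <= N - s0
    )
    return Fraction(numer, math.comb(N, k))


def diamond(network: nx.Graph, seeds: SeedSet, n_added: int) -> pd.DataFrame:
    """Iterative module expansion by hypergeometric connectivity significance.

    Starting from the seed module, repeatedly add the candidate node whose
    number of links into the current module is most significant under a
    hypergeometric null (population = network size, successes = current
    module size, draws = node degree, tail P(X ≥ links-to-module)). Ties
    go to the higher link count, then lexicographic node id. The returned
    table lists added nodes in addition order (rank 1 = first added) with
    their p-value at addition time as ``score``.
    """
    if n_added < 0:
        raise ValueError("n_added must be non-negative")
    missing = [s for s in seeds if not network.has_node(s)]
    if missing:
        raise ValueError(f"seeds not in network: {missing}")
    candidates_total = network.number_of_nodes() - len(set(seeds))
    if n_added > candidates_total:
        raise ValueError(
            f"n_added={n_added} exceeds the {candidates_total} non-seed node(s)"
        )
    N = network.number_of_nodes()
    module: set[str] = set(seeds)
    # only nodes touching the module can ever win; track their module-link counts
    links: dict[str, int] = {}
    for s in module:
        for nb in network.neighbors(s):
            if nb not in module:
                links[nb] = links.get(nb, 0) + 1

    added_rows = []
    for step in range(n_added):
        s0 = len(module)
        best = None
        if links:
            scored = [
                (_hypergeom_tail(N, s0, network.degree(v), ks), -ks, v)
                for v, ks in links.items()
            ]
            best = min(scored)
        else:
            # module is saturated within its component(s): fall back to the
            # remaining disconnected candidates, ranked lexicographically
            leftovers = sorted(set(network.nodes) - module, key=str)
            best = (Fraction(1), 0, leftovers[0])
        pval, neg_ks, v = best
        module.add(v)
        links.pop(v, None)
        for nb in network.neighbors(v):
            if nb not in module:
                links[nb] = links.get(nb, 0) + 1
        added_rows.append(
            {"node_id": v, "score": float(pval), "rank": step + 1, "is_seed": False}
        )
    return pd.DataFrame(
        added_rows, columns=["node_id", "score", "rank", "is_seed"]
    )
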
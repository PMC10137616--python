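"""Per-node centrality feature vectors.

Every node of a network is encoded as a vector of centrality measures; the
default set has nine entries so each node lives in a 9-dimensional feature
space:

    degree, betweenness, closeness, eigenvector, pagerank,
    personalized_pagerank, information, eigenvector_dup,
    clustering_coefficient

``eigenvector_dup`` is a literal copy of the eigenvector column, keeping
the default dimensionality at nine; pass ``dedupe_eigenvector=True`` for
the 8-dimensional de-duplicated variant.

Definitions (all dimensionless, all finite for every node):

* degree — deg(v)/(n−1).
* betweenness — shortest-path betweenness, pair-normalised.
* closeness — component-scaled (Wasserman–Faust) variant
  ((r−1)/Σd)·((r−1)/(n−1)) with r the number of reachable nodes, so values
  are comparable across components.
* eigenvector — principal eigenvector of the adjacency matrix of the
  largest connected component, unit L2 norm (power iteration, tol 1e-6,
  max 1000 iterations); 0 outside that component.
* pagerank — damping 0.85, uniform teleport.
* personalized_pagerank — damping 0.85, teleport uniform over the seeds.
* information — current-flow closeness 1/Σ_t r(v,t) (r = effective
  resistance), computed per connected component; 0 on singleton components.
* clustering_coefficient — triangles/(k choose 2); 0 for degree < 2.

All measures are computed on the unweighted topology by default; set
``weighted=True`` to use edge weights where the measure defines them
(shortest paths, PageRank transition probabilities, weighted triangles).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import SeedSet

logger = logging.getLogger("centrality_cosdist")

__all__ = ["MEASURES", "compute_centrality_matrix", "feature_subset"]

#: Fixed, documented column order of the default feature space.
MEASURES: tuple[str, ...] = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "pagerank",
    "personalized_pagerank",
    "information",
    "eigenvector_dup",
    "clustering_coefficient",
)

_PAGERANK_DAMPING = 0.85
_EIG_TOL = 1e-10  # tight enough that scores are accurate to well below 1e-6
_EIG_MAX_ITER = 1000


class CentralityError(RuntimeError):
    """A centrality computation failed (e.g. power iteration did not converge)."""


def _eigenvector_with_fallback(G: nx.Graph, weight: str | None) -> dict[str, float]:
    """Eigenvector centrality on the largest connected component, 0 elsewhere."""
    components = list(nx.connected_components(G))
    scores = {v: 0.0 for v in G}
    lcc = max(components, key=lambda c: (len(c), sorted(c)[0]))
    if len(components) > 1:
        logger.warning(
            "graph has %d components; eigenvector centrality computed on the "
            "largest (%d nodes), 0 elsewhere",
            len(components),
            len(lcc),
        )
    sub = G.subgraph(lcc)
    try:
        ev = nx.eigenvector_centrality(
            sub, tol=_EIG_TOL, max_iter=_EIG_MAX_ITER, weight=weight
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise CentralityError(
            f"eigenvector centrality: power iteration failed to converge "
            f"within {_EIG_MAX_ITER} iterations"
        ) from exc
    scores.update(ev)
    return scores


def _information_per_component(G: nx.Graph, weight: str | None) -> dict[str, float]:
    """Current-flow closeness per connected component; 0 for singletons."""
    scores: dict[str, float] = {}
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            scores[next(iter(comp))] = 0.0
            continue
        sub = G.subgraph(comp)
        scores.update(nx.information_centrality(sub, weight=weight))
    return scores


def compute_centrality_matrix(
    network: nx.Graph,
    seeds: SeedSet,
    *,
    weighted: bool = False,
    dedupe_eigenvector: bool = False,
) -> pd.DataFrame:
    """Assemble the nodes × measures feature matrix.

    Rows are ordered lexicographically by node identifier; columns follow
    :data:`MEASURES`. Seeds are needed for the personalised-PageRank
    teleport distribution and must all be present in the network.

    Returns a :class:`pandas.DataFrame` indexed by node id.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if len(seeds) == 0:
        raise ValueError("seed set is empty; personalized PageRank is undefined")
    missing = [s for s in seeds if not network.has_node(s)]
    if missing:
        raise ValueError(f"seeds not in network: {missing}")

    w = "weight" if weighted else None
    nodes = sorted(network.nodes, key=str)

    personalization = {s: 1.0 / len(seeds) for s in seeds}
    eig = _eigenvector_with_fallback(network, w)
    columns = {
        "degree": nx.degree_centrality(network),
        "betweenness": nx.betweenness_centrality(network, normalized=True, weight=w),
        "closeness": nx.closeness_centrality(
            network, distance=w, wf_improved=True
        ),
        "eigenvector": eig,
        "pagerank": nx.pagerank(
            network, alpha=_PAGERANK_DAMPING, weight=w, tol=1e-12, max_iter=1000
        ),
        "personalized_pagerank": nx.pagerank(
            network,
            alpha=_PAGERANK_DAMPING,
            personalization=personalization,
            weight=w,
            tol=1e-12,
            max_iter=1000,
        ),
        "information": _information_per_component(network, w),
        "clustering_coefficient": nx.clustering(network, weight=w),
    }
    columns["eigenvector_dup"] = columns["eigenvector"]

    order = [m for m in MEASURES if not (dedupe_eigenvector and m == "eigenvector_dup")]
    matrix = pd.DataFrame(
        {m: [columns[m][v] for v in nodes] for m in order}, index=pd.Index(nodes, name="node_id")
    )
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise CentralityError("non-finite centrality value produced")
    return matrix


def feature_subset(matrix: pd.DataFrame, exclude: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Drop the named measure columns, preserving the order of the rest.

    Raises ``KeyError`` on an unknown label and ``ValueError`` if nothing
    would remain.
    """
    unknown = [m for m in exclude if m not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown measure label(s): {unknown}")
    keep = [m for m in matrix.columns if m not in set(exclude)]
    if not keep:
        raise ValueError("cannot exclude every measure: empty feature space")
    return matrix[keep]
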
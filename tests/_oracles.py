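"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit path
enumeration, dense linear algebra, exact combinatorics) and deliberately
shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import numpy as np


def _bfs_shortest_paths(G: nx.Graph, s):
    """Distances and shortest-path counts from s via BFS."""
    dist = {s: 0}
    sigma = {s: 1.0}
    preds: dict = {s: []}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in G.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds


def bf_degree(G: nx.Graph) -> dict:
    n = G.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in G}
    return {v: G.degree(v) / (n - 1) for v in G}


def bf_betweenness(G: nx.Graph) -> dict:
    """Pair-normalised betweenness by explicit enumeration of all shortest paths."""
    nodes = list(G.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t, preds):
        # reconstruct every shortest path backwards from t
        if t == s:
            return [[s]]
        paths = []
        stack = [[t]]
        while stack:
            partial = stack.pop()
            head = partial[-1]
            if head == s:
                paths.append(list(reversed(partial)))
                continue
            for p in preds[head]:
                stack.append(partial + [p])
        return paths

    for s in nodes:
        dist, sigma, preds = _bfs_shortest_paths(G, s)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = all_shortest_paths(s, t, preds)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    # each unordered pair counted twice
    for v in score:
        score[v] /= 2.0
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        for v in score:
            score[v] *= scale
    return score


def bf_closeness(G: nx.Graph) -> dict:
    """Component-scaled (Wasserman-Faust) closeness from BFS distances."""
    n = G.number_of_nodes()
    out = {}
    for v in G:
        dist, _, _ = _bfs_shortest_paths(G, v)
        r = len(dist)
        total = sum(dist.values())
        if r > 1 and n > 1:
            out[v] = ((r - 1) / total) * ((r - 1) / (n - 1))
        else:
            out[v] = 0.0
    return out


def largest_component(G: nx.Graph):
    comps = list(nx.connected_components(G))
    return max(comps, key=lambda c: (len(c), sorted(c)[0]))


def bf_eigenvector(G: nx.Graph) -> dict:
    """Principal adjacency eigenvector (dense eigh) on the largest component."""
    out = {v: 0.0 for v in G}
    lcc = sorted(largest_component(G))
    if len(lcc) == 1:
        out[lcc[0]] = 1.0
        return out
    A = nx.to_numpy_array(G.subgraph(lcc), nodelist=lcc)
    vals, vecs = np.linalg.eigh(A)
    vec = vecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector is non-negative on a connected graph
    vec = vec / np.linalg.norm(vec)
    for v, x in zip(lcc, vec):
        out[v] = float(x)
    return out


def bf_pagerank(G: nx.Graph, alpha=0.85, personalization=None, tol=1e-14) -> dict:
    """Dense power iteration with the standard dangling-to-teleport rule."""
    nodes = sorted(G.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = nx.to_numpy_array(G, nodelist=nodes)
    deg = A.sum(axis=1)
    if personalization is None:
        tele = np.full(n, 1.0 / n)
    else:
        tele = np.zeros(n)
        for v, w in personalization.items():
            tele[idx[v]] = w
        tele = tele / tele.sum()
    dangling = deg == 0
    T = np.zeros((n, n))
    for i in range(n):
        if deg[i] > 0:
            T[i] = A[i] / deg[i]
    x = tele.copy()
    for _ in range(100000):
        x_new = alpha * (x @ T + x[dangling].sum() * tele) + (1 - alpha) * tele
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[idx[v]]) for v in nodes}


def bf_information(G: nx.Graph) -> dict:
    """Current-flow closeness 1/sum_t r(v,t) via the Laplacian pseudoinverse."""
    out = {}
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        if len(comp) == 1:
            out[comp[0]] = 0.0
            continue
        sub = G.subgraph(comp)
        L = nx.laplacian_matrix(sub, nodelist=comp).toarray().astype(float)
        Lp = np.linalg.pinv(L)
        m = len(comp)
        for i, v in enumerate(comp):
            s = sum(Lp[i, i] + Lp[j, j] - 2 * Lp[i, j] for j in range(m))
            out[v] = 1.0 / s
    return out


def bf_clustering(G: nx.Graph) -> dict:
    out = {}
    for v in G:
        nbrs = list(G.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if G.has_edge(nbrs[i], nbrs[j])
        )
        out[v] = tri / (k * (k - 1) / 2)
    return out


ORACLES = {
    "degree": bf_degree,
    "betweenness": bf_betweenness,
    "closeness": bf_closeness,
    "eigenvector": bf_eigenvector,
    "pagerank": lambda G: bf_pagerank(G),
    "information": bf_information,
    "clustering_coefficient": bf_clustering,
}


def bf_rwr_dense(G: nx.Graph, seed_nodes, r):
    """Fixed point of p = (1-r)(W + e d^T) p + r e by dense linear solve."""
    nodes = sorted(G.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = nx.to_numpy_array(G, nodelist=nodes)
    deg = A.sum(axis=0)
    W = np.zeros((n, n))
    for j in range(n):
        if deg[j] > 0:
            W[:, j] = A[:, j] / deg[j]
    e = np.zeros(n)
    for s in seed_nodes:
        e[idx[s]] = 1.0 / len(seed_nodes)
    d = (deg == 0).astype(float)
    M = W + np.outer(e, d)
    p = np.linalg.solve(np.eye(n) - (1 - r) * M, r * e)
    return {v: float(p[idx[v]]) for v in nodes}


def exact_hypergeom_tail(N: int, K: int, k: int, x: int):
    """P(X >= x) for X ~ Hypergeom(N, K, k) by exact combinatorial summation."""
    from fractions import Fraction

    total = math.comb(N, k)
    acc = 0
    for i in range(x, min(K, k) + 1):
        if k - i > N - K:
            continue
        acc += math.comb(K, i) * math.comb(N - K, k - i)
    return Fraction(acc, total)


def bf_diamond(G: nx.Graph, seed_nodes, n_added: int):
    """Naive module expansion scanning every non-module node each round."""
    from fractions import Fraction

    N = G.number_of_nodes()
    module = set(seed_nodes)
    added = []
    for _ in range(n_added):
        s0 = len(module)
        best = None
        for v in sorted(set(G.nodes) - module, key=str):
            k = G.degree(v)
            ks = sum(1 for nb in G.neighbors(v) if nb in module)
            p = exact_hypergeom_tail(N, s0, k, ks) if ks > 0 else Fraction(1)
            key = (p, -ks, v)
            if best is None or key < best:
                best = key
        p, neg_ks, v = best
        module.add(v)
        added.append((v, float(p)))
    return added
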
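"""CentralityCosDist core: cosine-similarity ranking against a seed set.

The method scores every node by the arithmetic mean of its cosine
similarities (in centrality-vector space) to the seed nodes, then ranks
all nodes by that score, descending. The steps are:

1. compute the centrality matrix (see :mod:`.centrality`);
2. compute seed–seed cosine similarities;
3. optionally prune seeds that are dissimilar to the bulk of the set;
4–5. compute each node's mean cosine similarity to the (retained) seeds;
6. rank nodes by the mean score, ties broken lexicographically.

Cosine is applied to raw centrality vectors by default, matching the
method as published; ``zscore=True`` standardises each column first,
which makes the ranking invariant to per-column affine rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .graph_io import SeedSet

logger = logging.getLogger("centrality_cosdist")

__all__ = [
    "cosine_similarity",
    "seed_seed_similarity",
    "prune_seeds",
    "mean_seed_similarity",
    "rank_nodes",
    "rank_by_cosdist",
    "top_k",
    "evaluate_seed_ranks",
    "top_k_overlap",
]

DEFAULT_TOP_K = 10


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (‖u‖‖v‖), clipped into [−1, 1].

    Raises ``ValueError`` for a zero-magnitude vector, where the angle is
    undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-magnitude vector")
    # exact short-circuits: identical (or antipodal) vectors must score
    # exactly +/-1 regardless of floating-point rounding in the quotient
    if np.array_equal(u, v):
        return 1.0
    if np.array_equal(u, -v):
        return -1.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column standardisation; constant columns map to all-zero."""
    arr = matrix.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=matrix.index, columns=matrix.columns)


def seed_seed_similarity(matrix: pd.DataFrame, seeds: SeedSet) -> pd.DataFrame:
    """Square symmetric table of pairwise seed cosine similarities."""
    missing = [s for s in seeds if s not in matrix.index]
    if missing:
        raise KeyError(f"seeds not in centrality matrix: {missing}")
    vecs = matrix.loc[list(seeds)].to_numpy(dtype=float)
    sim = np.clip(_sk_cosine(vecs), -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    ids = list(seeds)
    return pd.DataFrame(sim, index=ids, columns=ids)


def prune_seeds(
    matrix: pd.DataFrame, seeds: SeedSet, tau: float | None = None
) -> tuple[SeedSet, list[str]]:
    """Drop seeds whose mean similarity to the other seeds falls below ``tau``.

    With ``tau=None`` the threshold defaults to the mean off-diagonal
    seed–seed similarity minus two standard deviations. At least one seed
    is always retained: if all fall below the threshold, the single
    highest-scoring one is kept with a warning.
    """
    if len(seeds) < 2:
        logger.warning("prune_seeds: single seed, nothing to prune")
        return seeds, []
    sim = seed_seed_similarity(matrix, seeds).to_numpy()
    n = sim.shape[0]
    off = sim[~np.eye(n, dtype=bool)]
    if tau is None:
        tau = float(off.mean() - 2.0 * off.std())
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    # mean similarity of each seed to the *other* seeds
    mean_off = (sim.sum(axis=1) - 1.0) / (n - 1)
    keep_mask = mean_off >= tau
    members = list(seeds)
    if not keep_mask.any():
        best = int(np.argmax(mean_off))
        logger.warning(
            "prune_seeds: every seed fell below tau=%.4f; keeping only %s",
            tau,
            members[best],
        )
        keep_mask[best] = True
    kept = [m for m, k in zip(members, keep_mask) if k]
    removed = [m for m, k in zip(members, keep_mask) if not k]
    if removed:
        logger.info("prune_seeds: removed %d seed(s): %s", len(removed), removed)
    return SeedSet(name=seeds.name, members=tuple(kept)), removed


def mean_seed_similarity(
    matrix: pd.DataFrame, seeds: SeedSet, *, zscore: bool = False
) -> pd.Series:
    """Mean cosine similarity of every node (seeds included) to the seed set.

    Zero-magnitude node vectors (fully isolated nodes) receive the sink
    score −1 with a warning rather than aborting the run.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    missing = [s for s in seeds if s not in matrix.index]
    if missing:
        raise KeyError(f"seeds not in centrality matrix: {missing}")
    feats = _zscore_columns(matrix) if zscore else matrix
    arr = feats.to_numpy(dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    zero_rows = norms == 0.0
    seed_idx = feats.index.get_indexer(list(seeds))
    seed_vecs = arr[seed_idx]
    seed_norms = norms[seed_idx]
    if (seed_norms == 0.0).any():
        bad = [list(seeds)[i] for i in np.flatnonzero(seed_norms == 0.0)]
        raise ValueError(f"seed(s) with zero-magnitude centrality vector: {bad}")
    safe_norms = np.where(zero_rows, 1.0, norms)
    sim = (arr @ seed_vecs.T) / np.outer(safe_norms, seed_norms)
    scores = np.clip(sim, -1.0, 1.0).mean(axis=1)
    if zero_rows.any():
        nodes = feats.index[zero_rows].tolist()
        logger.warning(
            "%d node(s) with zero centrality vector assigned similarity -1: %s",
            len(nodes),
            nodes,
        )
        scores[zero_rows] = -1.0
    return pd.Series(scores, index=feats.index, name="mean_similarity")


def rank_nodes(scores: pd.Series, seeds: SeedSet) -> pd.DataFrame:
    """Turn per-node scores into the standard ranking table.

    Descending score; ties broken lexicographically by node id; ranks are
    1..n with no gaps. Columns: node_id, score, rank, is_seed.
    """
    df = pd.DataFrame(
        {"node_id": scores.index.astype(str), "score": scores.to_numpy(dtype=float)}
    )
    df = df.sort_values(
        ["score", "node_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    seed_members = set(seeds)
    df["is_seed"] = df["node_id"].isin(seed_members)
    return df


def rank_by_cosdist(
    matrix: pd.DataFrame,
    seeds: SeedSet,
    *,
    zscore: bool = False,
    prune: bool = False,
    tau: float | None = None,
) -> pd.DataFrame:
    """Full steps 2–6 on a precomputed centrality matrix."""
    removed: list[str] = []
    if prune:
        seeds, removed = prune_seeds(matrix, seeds, tau)
    scores = mean_seed_similarity(matrix, seeds, zscore=zscore)
    ranking = rank_nodes(scores, seeds)
    ranking.attrs["pruned_seeds"] = removed
    return ranking


def top_k(ranking: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """First min(k, n) rows of a ranking table."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ranking.head(k).reset_index(drop=True)


@dataclass(frozen=True)
class SeedRankSummary:
    """Distribution summary of the seeds' own positions in a ranking."""

    per_seed: pd.Series  # rank per seed id
    median: float
    q1: float
    q3: float
    n_nodes: int

    def as_frame(self) -> pd.DataFrame:
        df = self.per_seed.rename("rank").rename_axis("node_id").reset_index()
        return df


def evaluate_seed_ranks(ranking: pd.DataFrame, seeds: SeedSet) -> SeedRankSummary:
    """Where do the seeds themselves land in a ranking?"""
    by_node = ranking.set_index("node_id")["rank"]
    missing = [s for s in seeds if s not in by_node.index]
    if missing:
        raise KeyError(f"seeds not present in ranking: {missing}")
    per_seed = by_node.loc[list(seeds)].astype(float)
    return SeedRankSummary(
        per_seed=per_seed,
        median=float(per_seed.median()),
        q1=float(per_seed.quantile(0.25)),
        q3=float(per_seed.quantile(0.75)),
        n_nodes=len(ranking),
    )


def evaluate_seed_ranks_loo(
    matrix: pd.DataFrame, seeds: SeedSet, *, zscore: bool = False
) -> SeedRankSummary:
    """Leave-one-out seed evaluation.

    Each seed's rank is recomputed with itself removed from the seed set,
    removing the self-similarity advantage a seed enjoys in the plain
    evaluation.
    """
    if len(seeds) < 2:
        raise ValueError("leave-one-out evaluation needs at least 2 seeds")
    ranks = {}
    for held_out in seeds:
        rest = SeedSet(
            name=f"{seeds.name}-loo", members=tuple(s for s in seeds if s != held_out)
        )
        ranking = rank_nodes(mean_seed_similarity(matrix, rest, zscore=zscore), rest)
        ranks[held_out] = float(
            ranking.loc[ranking["node_id"] == held_out, "rank"].iloc[0]
        )
    per_seed = pd.Series(ranks, name="rank")
    return SeedRankSummary(
        per_seed=per_seed,
        median=float(per_seed.median()),
        q1=float(per_seed.quantile(0.25)),
        q3=float(per_seed.quantile(0.75)),
        n_nodes=len(matrix),
    )


def top_k_overlap(
    rankings: dict[str, pd.DataFrame], k: int = DEFAULT_TOP_K
) -> pd.DataFrame:
    """Pairwise |top_k(A) ∩ top_k(B)| across named rankings.

    This is the data behind the cross-method chord diagram; externally
    produced rankings load via :func:`.graph_io.load_ranking` and plug in
    unchanged.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to compare")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tops = {
        name: set(top_k(r.sort_values("rank", kind="stable"), k)["node_id"])
        for name, r in rankings.items()
    }
    names = list(tops)
    data = [
        [len(tops[a] & tops[b]) for b in names]
        for a in names
    ]
    return pd.DataFrame(data, index=names, columns=names)
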
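import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centrality_cosdist import SeedSet
from centrality_cosdist.ranking import (
    cosine_similarity,
    evaluate_seed_ranks,
    evaluate_seed_ranks_loo,
    mean_seed_similarity,
    prune_seeds,
    rank_nodes,
    seed_seed_similarity,
    top_k,
    top_k_overlap,
)

from conftest import frame

finite_vec = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=6
)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, 2.0, 5.1])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        v = np.array([1.0, -2.0, 0.5])
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    @settings(deadline=None, derandomize=True)
    @given(finite_vec, st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_positive_rescaling(self, v, alpha):
        u = np.asarray(v)
        if np.linalg.norm(u) < 1e-9:
            return
        w = np.arange(1.0, len(u) + 1.0)
        assert cosine_similarity(alpha * u, w) == pytest.approx(
            cosine_similarity(u, w), abs=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(finite_vec)
    def test_range(self, v):
        u = np.asarray(v)
        if np.linalg.norm(u) < 1e-9:
            return
        w = np.ones(len(u))
        assert -1.0 <= cosine_similarity(u, w) <= 1.0


class TestSeedSeedSimilarity:
    def test_identical_vectors(self):
        m = frame({"s1": [1, 2], "s2": [2, 4], "x": [0, 1]})
        tab = seed_seed_similarity(m, SeedSet("s", ("s1", "s2")))
        assert np.allclose(tab.to_numpy(), 1.0)

    def test_orthogonal_seeds(self):
        m = frame({"s1": [1, 0], "s2": [0, 1]})
        tab = seed_seed_similarity(m, SeedSet("s", ("s1", "s2")))
        assert tab.loc["s1", "s2"] == pytest.approx(0.0)
        assert np.allclose(np.diag(tab), 1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        m = frame({f"s{i}": rng.normal(size=4).tolist() for i in range(5)})
        tab = seed_seed_similarity(m, SeedSet("s", tuple(sorted(m.index))))
        assert np.allclose(tab.to_numpy(), tab.to_numpy().T)

    def test_missing_seed_rejected(self):
        m = frame({"a": [1, 0]})
        with pytest.raises(KeyError):
            seed_seed_similarity(m, SeedSet("s", ("a", "zz")))


class TestPruneSeeds:
    def test_dissimilar_seed_removed(self):
        m = frame({"s1": [1, 0], "s2": [1, 0], "s3": [0, 1]})
        kept, removed = prune_seeds(m, SeedSet("s", ("s1", "s2", "s3")), tau=0.5)
        assert removed == ["s3"] and list(kept) == ["s1", "s2"]

    def test_tau_lower_bound_removes_nothing(self):
        m = frame({"s1": [1, 0], "s2": [0, 1], "s3": [-1, 0]})
        kept, removed = prune_seeds(m, SeedSet("s", ("s1", "s2", "s3")), tau=-1.0)
        assert removed == []

    def test_identical_seeds_never_pruned(self):
        m = frame({"s1": [2, 1], "s2": [4, 2], "s3": [8, 4]})
        kept, removed = prune_seeds(m, SeedSet("s", ("s1", "s2", "s3")), tau=1.0)
        assert removed == []

    def test_single_seed_returned_unchanged(self):
        m = frame({"s1": [1, 0]})
        kept, removed = prune_seeds(m, SeedSet("s", ("s1",)), tau=0.9)
        assert list(kept) == ["s1"] and removed == []

    def test_at_least_one_seed_survives(self):
        m = frame({"s1": [1, 0], "s2": [0, 1], "s3": [-1, -1]})
        kept, _ = prune_seeds(m, SeedSet("s", ("s1", "s2", "s3")), tau=1.0)
        assert len(kept) >= 1

    def test_bad_tau_rejected(self):
        m = frame({"s1": [1, 0], "s2": [0, 1]})
        with pytest.raises(ValueError):
            prune_seeds(m, SeedSet("s", ("s1", "s2")), tau=2.0)


class TestMeanSeedSimilarity:
    def test_node_equal_to_single_seed_scores_one(self):
        m = frame({"s": [1, 2], "x": [2, 4]})
        scores = mean_seed_similarity(m, SeedSet("s", ("s",)))
        assert scores["x"] == pytest.approx(1.0)

    def test_diagonal_node_between_orthogonal_seeds(self):
        m = frame({"s1": [1, 0], "s2": [0, 1], "x": [1, 1]})
        scores = mean_seed_similarity(m, SeedSet("s", ("s1", "s2")))
        assert scores["x"] == pytest.approx(1 / np.sqrt(2))

    def test_seed_self_score_dominates_cross_mean(self):
        rng = np.random.default_rng(1)
        m = frame({f"s{i}": np.abs(rng.normal(size=3)).tolist() for i in range(4)})
        seeds = SeedSet("s", tuple(sorted(m.index)))
        scores = mean_seed_similarity(m, seeds)
        sim = seed_seed_similarity(m, seeds).to_numpy()
        n = len(seeds)
        for i, s in enumerate(seeds):
            cross_mean = (sim[i].sum() - 1.0) / (n - 1)
            assert scores[s] >= cross_mean - 1e-12

    def test_zero_vector_node_gets_sink_score(self, caplog):
        m = frame({"s": [1.0, 0.0], "z": [0.0, 0.0]})
        scores = mean_seed_similarity(m, SeedSet("s", ("s",)))
        assert scores["z"] == -1.0

    def test_empty_seed_set_rejected(self):
        m = frame({"a": [1, 0]})
        with pytest.raises(ValueError):
            mean_seed_similarity(m, SeedSet("s", ()))

    def test_zscore_mode_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(5)
        base = frame({f"n{i}": rng.normal(size=4).tolist() for i in range(8)})
        seeds = SeedSet("s", ("n0", "n1"))
        scaled = base.copy()
        scaled.iloc[:, 2] = scaled.iloc[:, 2] * 1e4 + 17.0
        s1 = mean_seed_similarity(base, seeds, zscore=True)
        s2 = mean_seed_similarity(scaled, seeds, zscore=True)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_raw_mode_can_change_with_column_rescaling(self):
        base = frame({"s": [1.0, 1.0], "x": [0.0, 1.0], "y": [1.0, 0.0]})
        seeds = SeedSet("s", ("s",))
        r1 = rank_nodes(mean_seed_similarity(base, seeds), seeds)
        assert list(r1["node_id"]) == ["s", "x", "y"]  # tie x/y -> lexicographic
        scaled = base.copy()
        scaled.iloc[:, 0] *= 100.0  # first column now dominates the cosine
        r2 = rank_nodes(mean_seed_similarity(scaled, seeds), seeds)
        assert list(r2["node_id"]) == ["s", "y", "x"]


class TestRankNodes:
    def test_ties_broken_lexicographically(self):
        scores = pd.Series({"a": 0.9, "b": 0.5, "c": 0.9})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        assert list(r["node_id"]) == ["a", "c", "b"]
        assert list(r["rank"]) == [1, 2, 3]

    def test_all_equal_scores_sort_lexicographically(self):
        scores = pd.Series({"d": 1.0, "b": 1.0, "a": 1.0, "c": 1.0})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        assert list(r["node_id"]) == ["a", "b", "c", "d"]

    def test_ranks_are_gapless(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=30), index=[f"n{i:02d}" for i in range(30)])
        r = rank_nodes(scores, SeedSet("s", ("n00",)))
        assert list(r["rank"]) == list(range(1, 31))

    def test_is_seed_flag(self):
        scores = pd.Series({"a": 1.0, "b": 0.5})
        r = rank_nodes(scores, SeedSet("s", ("b",)))
        assert r.set_index("node_id")["is_seed"].to_dict() == {"a": False, "b": True}


class TestTopK:
    def test_default_k_10(self):
        scores = pd.Series(np.linspace(1, 0, 50), index=[f"n{i:02d}" for i in range(50)])
        r = rank_nodes(scores, SeedSet("s", ("n00",)))
        assert len(top_k(r)) == 10

    def test_k_exceeding_n_returns_all(self):
        scores = pd.Series({"a": 1.0, "b": 0.5})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        assert len(top_k(r, 99)) == 2

    def test_k_equal_n_is_identity(self):
        scores = pd.Series({"a": 1.0, "b": 0.5})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        assert top_k(r, 2).equals(r)

    def test_k_below_one_rejected(self):
        scores = pd.Series({"a": 1.0})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        with pytest.raises(ValueError):
            top_k(r, 0)


class TestEvaluateSeedRanks:
    def test_median_of_top_three(self):
        scores = pd.Series(np.linspace(1, 0.1, 10), index=[f"n{i}" for i in range(10)])
        seeds = SeedSet("s", ("n0", "n1", "n2"))
        summary = evaluate_seed_ranks(rank_nodes(scores, seeds), seeds)
        assert summary.median == 2.0

    def test_single_seed_rank_one(self):
        scores = pd.Series({"a": 1.0, "b": 0.0})
        seeds = SeedSet("s", ("a",))
        assert evaluate_seed_ranks(rank_nodes(scores, seeds), seeds).median == 1.0

    def test_loo_identical_seed_vectors_stay_on_top(self):
        # seeds share a direction; the distractor points elsewhere
        m = frame(
            {"s1": [2, 2], "s2": [1, 1], "s3": [3, 3], "x": [1, 0], "y": [0, 1]}
        )
        seeds = SeedSet("s", ("s1", "s2", "s3"))
        summary = evaluate_seed_ranks_loo(m, seeds)
        assert (summary.per_seed <= 3).all()  # never beaten by x or y

    def test_missing_seed_rejected(self):
        scores = pd.Series({"a": 1.0})
        r = rank_nodes(scores, SeedSet("s", ("a",)))
        with pytest.raises(KeyError):
            evaluate_seed_ranks(r, SeedSet("s", ("zz",)))


class TestTopKOverlap:
    @staticmethod
    def _ranking(order):
        return pd.DataFrame(
            {
                "node_id": order,
                "score": np.linspace(1, 0, len(order)),
                "rank": range(1, len(order) + 1),
                "is_seed": False,
            }
        )

    def test_identical_rankings_full_overlap(self):
        order = [f"n{i:02d}" for i in range(20)]
        tab = top_k_overlap({"A": self._ranking(order), "B": self._ranking(order)}, 10)
        assert tab.loc["A", "B"] == 10

    def test_disjoint_top_k(self):
        a = self._ranking([f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        b = self._ranking([f"b{i}" for i in range(10)] + [f"a{i}" for i in range(10)])
        tab = top_k_overlap({"A": a, "B": b}, 10)
        assert tab.loc["A", "B"] == 0

    def test_partial_overlap_counted(self):
        a = self._ranking(["a", "b", "x1", "x2"])
        b = self._ranking(["b", "y1", "a", "y2"])
        tab = top_k_overlap({"A": a, "B": b}, 3)
        assert tab.loc["A", "B"] == 2  # shares exactly {a, b}
        assert tab.equals(tab.T)

    def test_single_ranking_rejected(self):
        with pytest.raises(ValueError):
            top_k_overlap({"A": self._ranking(["a"])}, 1)
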
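import itertools

import numpy as np
import pandas as pd
import pytest

from ibdpd.nhc import GeneCluster
from ibdpd.prioritize import (
    avg_set_distance,
    compare_enrichment,
    distance_to_set,
    importance_scores,
    intersect_methods,
    ora_enrichment,
    overlap_percent,
    pool_candidates,
    resampling_p,
    within_set_distance,
)
from ibdpd.types import DistanceMatrix, GeneSetCollection


def dm_from_array(genes, arr):
    return DistanceMatrix(pd.DataFrame(arr, index=genes, columns=genes, dtype=float))


@pytest.fixture
def toy_distances():
    # hand-filled symmetric 4x4
    genes = ["A", "B", "C", "D"]
    arr = np.array(
        [
            [0.0, 1.0, 4.0, 9.0],
            [1.0, 0.0, 2.0, 8.0],
            [4.0, 2.0, 0.0, 3.0],
            [9.0, 8.0, 3.0, 0.0],
        ]
    )
    return dm_from_array(genes, arr)


class TestPoolCandidates:
    def results_frame(self, genes, ps):
        return pd.DataFrame({"gene": genes, "p_skato": ps})

    def test_union_semantics(self):
        res = self.results_frame(["A", "B", "C"], [0.001, 0.005, 0.5])
        clusters = [
            GeneCluster(1, frozenset(["B", "C"]), 0.9, p=0.01),
            GeneCluster(2, frozenset(["D"]), 0.9, p=0.5),
        ]
        assert pool_candidates(res, clusters) == {"A", "B", "C"}

    def test_control_embedded_clusters_excluded(self):
        res = self.results_frame(["A"], [0.001])
        clusters = [
            GeneCluster(1, frozenset(["X", "Y"]), 0.9, p=0.01, control_embedded=True)
        ]
        assert pool_candidates(res, clusters) == {"A"}


class TestOra:
    def test_matches_exhaustive_enumeration(self):
        # universe of 12, term of 4, set of 5, overlap 3: enumerate all
        # 5-subsets and count those overlapping the term in >= 3 genes
        universe = [f"g{i}" for i in range(12)]
        term = universe[:4]
        gene_set = universe[1:4] + universe[8:10]  # overlap 3
        coll = GeneSetCollection("toy", {"T": ("d", term)})
        row = ora_enrichment(gene_set, coll, universe).iloc[0]
        count = sum(
            1
            for comb in itertools.combinations(universe, 5)
            if len(set(comb) & set(term)) >= 3
        )
        from math import comb as nck

        assert row["overlap"] == 3
        assert row["p"] == pytest.approx(count / nck(12, 5))

    def test_zero_overlap_never_significant(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection("toy", {"T": ("d", universe[:4])})
        out = ora_enrichment(universe[10:15], coll, universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_degenerate_set_equals_universe(self):
        universe = [f"g{i}" for i in range(6)]
        coll = GeneSetCollection("toy", {"T": ("d", universe)})
        out = ora_enrichment(universe, coll, universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection("toy", {"T": ("d", ["A"])})
        with pytest.raises(ValueError):
            ora_enrichment(["A"], coll, [])

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        sets = {
            f"T{k}": ("d", list(rng.choice(universe, size=8, replace=False)))
            for k in range(10)
        }
        coll = GeneSetCollection("toy", sets)
        out = ora_enrichment(universe[:10], coll, universe)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestCompareEnrichment:
    def frame(self, terms, ps):
        return pd.DataFrame({"term_id": terms, "p_adj": ps})

    def test_identical_lists_all_shared(self):
        f = self.frame(["T1", "T2"], [0.01, 0.01])
        out = compare_enrichment({"a": f, "b": f, "c": f})
        assert out["shared_all"] == {"T1", "T2"}
        assert all(not u for u in out["unique"].values())

    def test_disjoint_lists_all_unique(self):
        out = compare_enrichment(
            {
                "a": self.frame(["T1"], [0.01]),
                "b": self.frame(["T2"], [0.01]),
            }
        )
        assert out["shared_all"] == set()
        assert out["unique"] == {"a": {"T1"}, "b": {"T2"}}

    def test_three_way_hand_venn(self):
        out = compare_enrichment(
            {
                "x": self.frame(["T1", "T2", "T3"], [0.01] * 3),
                "y": self.frame(["T2", "T3", "T4"], [0.01] * 3),
                "z": self.frame(["T3", "T5"], [0.01] * 2),
            }
        )
        assert out["shared_all"] == {"T3"}
        assert out["unique"] == {"x": {"T1"}, "y": {"T4"}, "z": {"T5"}}


class TestDistances:
    def test_distance_to_set_min_convention(self, toy_distances):
        assert distance_to_set("A", ["B", "C"], toy_distances) == 1.0
        # self excluded from its own set
        assert distance_to_set("A", ["A", "C"], toy_distances) == 4.0
        assert distance_to_set("A", ["B", "C"], toy_distances, how="mean") == 2.5

    def test_toy_matrix_hand_means(self, toy_distances):
        # candidates {A, D} vs known {B, C}: min dists 1 (A-B) and 3 (D-C)
        assert avg_set_distance(["A", "D"], ["B", "C"], toy_distances) == 2.0
        # within {B, C, D}: B->C 2, C->B 2, D->C 3 -> mean 7/3
        assert within_set_distance(["B", "C", "D"], toy_distances) == pytest.approx(7 / 3)

    def test_candidates_equal_known_coincide(self, toy_distances):
        known = ["B", "C", "D"]
        assert avg_set_distance(known, known, toy_distances) == pytest.approx(
            within_set_distance(known, toy_distances)
        )

    def test_small_known_set_rejected(self, toy_distances):
        with pytest.raises(ValueError):
            within_set_distance(["A"], toy_distances)


class TestResampling:
    def big_matrix(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        arr = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        genes = [f"g{i}" for i in range(n)]
        return dm_from_array(genes, arr)

    def test_minimum_attainable_p(self):
        dm = self.big_matrix()
        known = dm.genes[:5]
        # candidates identical to nearest neighbours of the known set ->
        # d_candidate at or near the minimum; p bounded below by add-one rule
        summ = resampling_p(dm.genes[5:10], known, dm, n_iter=200, seed=1)
        assert summ.p_empirical >= 1 / 201

    def test_reproducible_with_seed(self):
        dm = self.big_matrix()
        s1 = resampling_p(dm.genes[5:15], dm.genes[:5], dm, n_iter=500, seed=7)
        s2 = resampling_p(dm.genes[5:15], dm.genes[:5], dm, n_iter=500, seed=7)
        assert s1.p_empirical == s2.p_empirical
        np.testing.assert_array_equal(s1.d_random, s2.d_random)

    def test_null_p_uniform(self):
        # candidates drawn uniformly from the universe: empirical p ~ U(0,1)
        from scipy.stats import kstest

        dm = self.big_matrix(n=60, seed=3)
        known = dm.genes[:8]
        universe = dm.genes[8:]
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            cand = list(rng.choice(universe, size=10, replace=False))
            ps.append(
                resampling_p(
                    cand, known, dm, universe=universe, n_iter=400,
                    seed=int(rng.integers(2**31)),
                ).p_empirical
            )
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_universe_too_small_rejected(self):
        dm = self.big_matrix(n=10)
        with pytest.raises(ValueError):
            resampling_p(dm.genes[1:9], [dm.genes[0]], dm,
                         universe=dm.genes[1:9], n_iter=10, seed=0)


class TestIntersectAndScores:
    def test_intersection_all_methods(self):
        lists = {
            "m1": ["A", "B", "C"],
            "m2": ["B", "C"],
            "m3": ["B", "C", "D"],
            "m4": ["B", "C"],
        }
        assert intersect_methods(lists) == ["B", "C"]
        assert intersect_methods(lists, k_required=3) == ["B", "C"]

    def test_disjoint_lists_empty(self):
        assert intersect_methods({"a": ["A"], "b": ["B"]}) == []

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            intersect_methods({"a": [], "b": ["B"]})

    def test_importance_counts_and_scaling(self):
        term_genes = {"T1": {"X", "K1", "K2", "K3"}, "T2": {"Y", "K1"}}
        term_p = {"T1": 0.001, "T2": 0.5}  # only T1 significant
        scores = importance_scores(
            ["X", "Y"],
            {"src": ("terms", term_genes, term_p)},
            known_ibd=["K1", "K2", "K3"],
            known_pd=["K9"],
        )
        x = scores.set_index("gene").loc["X"]
        y = scores.set_index("gene").loc["Y"]
        assert x["raw_src_ibd"] == 3  # three known IBD genes share T1
        assert y["raw_src_ibd"] == 0  # T2 is not significant
        assert x["scaled_src_ibd"] == 1.0  # max-normalized
        assert x["score_combined"] >= max(x["score_ibd"], x["score_pd"])

    def test_network_source_neighbors(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("X", "K1", weight=0.9)
        g.add_edge("X", "K2", weight=0.3)  # below cutoff
        scores = importance_scores(
            ["X"], {"net": ("network", g, 0.7)}, ["K1", "K2"], []
        )
        assert scores.iloc[0]["raw_net_ibd"] == 1


def test_overlap_percent_arithmetic():
    cand = [f"c{i}" for i in range(120)]
    known = cand[:7] + [f"k{i}" for i in range(150)]
    assert overlap_percent(cand, known) == pytest.approx(5.83, abs=0.005)
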
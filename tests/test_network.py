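"""Correlation graphs, Markov Clustering and cluster-trait association."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from myolab.network import (
    MCLConfig,
    MODE_PROBE,
    MODE_SAMPLE,
    ClusterAssignment,
    cluster_profiles,
    cluster_trait_association,
    correlation_graph,
    fisher_exact_2x2,
    mcl_cluster,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# correlation graph
# ---------------------------------------------------------------------------

class TestCorrelationGraph:
    def test_identical_vectors_always_connected(self):
        vals = np.vstack([np.array([1.0, 2.0, 3.0, 4.0])] * 2 + [[9, 1, 7, 2.0]])
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.99)
        assert g.has_edge("p0", "p1")
        assert g["p0"]["p1"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_pair_never_connected(self):
        vals = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.85)
        assert not g.has_edge("p0", "p1")

    def test_edges_match_direct_pairwise_pearson(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(4, 10))
        thr = 0.2
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=thr)
        for i, j in itertools.combinations(range(4), 2):
            r = np.corrcoef(vals[i], vals[j])[0, 1]
            assert g.has_edge(f"p{i}", f"p{j}") == (r > thr)
            if r > thr:
                assert g[f"p{i}"][f"p{j}"]["weight"] == pytest.approx(r)

    def test_sample_mode_transposes(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 4))
        g = correlation_graph(make_matrix(vals), MODE_SAMPLE, threshold=-1.1)
        assert set(g.nodes) == {"s0", "s1", "s2", "s3"}
        assert g.number_of_edges() == 6  # threshold below -1: complete graph

    def test_zero_variance_nodes_dropped(self):
        vals = np.vstack([np.ones(5), np.random.default_rng(0).normal(size=(2, 5))])
        with pytest.warns(UserWarning, match="zero-variance"):
            g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.5)
        assert "p0" not in g.nodes


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def planted_blocks_matrix(n_per_block=8, n_blocks=3, n_obs=60, seed=0):
    """Block-structured data: within-block r ~ 0.9, between-block r ~ 0."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blocks):
        shared = rng.normal(size=n_obs)
        for _ in range(n_per_block):
            rows.append(3.0 * shared + rng.normal(size=n_obs))
            truth.append(b)
    return np.array(rows), np.array(truth)


class TestMCL:
    def test_two_disjoint_cliques_recovered(self):
        g = nx.Graph()
        for offset in (0, 10):
            for i, j in itertools.combinations(range(4), 2):
                g.add_edge(offset + i, offset + j, weight=1.0)
        for inflation in (1.2, 2.0, 3.5, 6.0):
            res = mcl_cluster(g, MCLConfig(inflation=inflation))
            assert res.n_clusters == 2
            assert len(set(res.labels[[0, 1, 2, 3]])) == 1
            assert len(set(res.labels[[10, 11, 12, 13]])) == 1

    def test_single_node_single_cluster(self):
        g = nx.Graph()
        g.add_node("only")
        res = mcl_cluster(g, MCLConfig(inflation=2.0))
        assert res.n_clusters == 1
        assert res.labels["only"] == 1

    def test_planted_three_block_structure_recovered(self):
        vals, truth = planted_blocks_matrix(seed=3)
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.5)
        res = mcl_cluster(g, MCLConfig(inflation=2.2))
        labels = res.labels[[f"p{i}" for i in range(len(truth))]].to_numpy()
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_inflation_never_coarsens(self):
        """More inflation gives at least as many clusters on a fixed graph."""
        vals, _ = planted_blocks_matrix(seed=3)
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.5)
        counts = [
            mcl_cluster(g, MCLConfig(inflation=i)).n_clusters
            for i in (1.5, 2.2, 3.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_cluster_ids_ordered_by_size(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(f"a{i}", f"a{j}", weight=1.0)
        for i, j in itertools.combinations(range(3), 2):
            g.add_edge(f"b{i}", f"b{j}", weight=1.0)
        res = mcl_cluster(g, MCLConfig(inflation=2.0))
        assert res.labels["a0"] == 1  # bigger clique is cluster 1
        assert res.labels["b0"] == 2

    def test_deterministic(self):
        vals, _ = planted_blocks_matrix(seed=6)
        g = correlation_graph(make_matrix(vals), MODE_PROBE, threshold=0.4)
        a = mcl_cluster(g, MCLConfig())
        b = mcl_cluster(g, MCLConfig())
        pd.testing.assert_series_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# Fisher's exact / chi-squared
# ---------------------------------------------------------------------------

def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration with rational arithmetic."""
    from fractions import Fraction

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_hand_value_5_0_0_5(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-15)

    def test_all_small_tables_match_enumeration_oracle(self):
        """Every 2×2 table with N ≤ 30 agrees with the exhaustive
        hypergeometric enumeration to 1e-12."""
        checked = 0
        for n in range(2, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                            continue
                        assert fisher_exact_2x2(t) == pytest.approx(
                            fisher_oracle(t), abs=1e-12
                        ), t
                        checked += 1
        assert checked > 10_000

    def test_cross_check_against_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                scipy_fisher(t)[1], rel=1e-9, abs=1e-12
            )


class TestClusterTraitAssociation:
    def _assignment(self, labels):
        s = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))], dtype=int)
        return ClusterAssignment(labels=s, n_clusters=len(set(labels)))

    def _metadata(self, groups):
        return pd.DataFrame(
            {"group": groups}, index=pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id")
        )

    def test_perfect_separation_uses_fisher(self):
        assign = self._assignment([1] * 5 + [2] * 5)
        md = self._metadata(["labour"] * 5 + ["nonlabour"] * 5)
        out = cluster_trait_association(assign, md, "group")
        assert out["test"] == "fisher_exact"
        assert out["pvalue"] == pytest.approx(2 / 252, abs=1e-12)

    def test_no_association_gives_p_one(self):
        # cluster x trait table [[10,10],[5,5]]: expected = observed
        assign = self._assignment([1] * 20 + [2] * 10)
        md = self._metadata((["labour"] * 10 + ["nonlabour"] * 10) + (["labour"] * 5 + ["nonlabour"] * 5))
        out = cluster_trait_association(assign, md, "group")
        assert out["test"] == "chi_squared"
        assert out["pvalue"] == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        assign = self._assignment([1] * 4 + [2] * 4)
        md = self._metadata(["labour"] * 8)
        with pytest.raises(ValueError):
            cluster_trait_association(assign, md, "group")

    def test_rx2_exact_matches_chi2_direction(self):
        # 3 clusters, strong association: exact p must be small
        assign = self._assignment([1] * 6 + [2] * 6 + [3] * 6)
        md = self._metadata(["labour"] * 6 + ["nonlabour"] * 6 + ["labour"] * 3 + ["nonlabour"] * 3)
        out = cluster_trait_association(assign, md, "group")
        assert out["test"] == "fisher_exact"
        assert out["pvalue"] < 0.01


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

class TestClusterProfiles:
    def test_identical_probes_zero_se(self):
        vals = np.vstack([np.array([1.0, 2.0, 3.0])] * 3)
        m = make_matrix(vals)
        assign = ClusterAssignment(
            labels=pd.Series([1, 1, 1], index=["p0", "p1", "p2"]), n_clusters=1
        )
        prof = cluster_profiles(m, assign)[1]
        np.testing.assert_allclose(prof["mean"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(prof["se"], 0.0)

    def test_hand_mean_and_se(self):
        vals = np.array([[1.0, 5.0], [3.0, 5.0]])
        m = make_matrix(vals)
        assign = ClusterAssignment(
            labels=pd.Series([1, 1], index=["p0", "p1"]), n_clusters=1
        )
        prof = cluster_profiles(m, assign)[1]
        assert prof.loc["s0", "mean"] == pytest.approx(2.0)
        assert prof.loc["s0", "se"] == pytest.approx(1.0)

    def test_singleton_cluster_se_zero(self):
        vals = np.array([[1.0, 2.0]])
        m = make_matrix(vals)
        assign = ClusterAssignment(labels=pd.Series([1], index=["p0"]), n_clusters=1)
        prof = cluster_profiles(m, assign)[1]
        np.testing.assert_allclose(prof["se"], 0.0)

    def test_random_cluster_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(6, 4))
        m = make_matrix(vals)
        assign = ClusterAssignment(
            labels=pd.Series([1, 1, 1, 2, 2, 2], index=[f"p{i}" for i in range(6)]),
            n_clusters=2,
        )
        prof = cluster_profiles(m, assign)
        np.testing.assert_allclose(prof[1]["mean"], vals[:3].mean(axis=0))
        np.testing.assert_allclose(prof[2]["se"], vals[3:].std(axis=0, ddof=1) / np.sqrt(3))
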
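import numpy as np
import pytest

from netdesign import (Clustering, CMatchOptions, SimilaritySpec, UnsupportedCombination,
                       build_cluster_graph, cluster_weight, cmatch_design,
                       match_clusters, node_matches)
from netdesign.cmatch import all_cluster_weights, enumerate_option_combinations
from netdesign.graph import EXCLUDED
from tests.conftest import make_planted_graph
from tests.oracles import brute_force_bipartite_matching, brute_force_max_weight_matching


def _two_pair_clusters():
    """Two clusters of two nodes each, with attributes making all cross
    similarities high."""
    X = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1]])
    clu = Clustering(np.array([0, 0, 1, 1]))
    return clu, X


class TestNodeMatches:
    def test_tnm0_matches_every_cross_pair(self):
        clu, X = _two_pair_clusters()
        ms = node_matches(clu, X, rule="tnm0")
        _, _, _, mask = ms.pair_block(0, 1)
        assert mask.all()

    def test_tnm_thresholds_nested(self):
        g = make_planted_graph(k=3, size=10, seed=4)
        clu = Clustering(np.repeat(np.arange(3), 10))
        masks = {}
        for rule in ("tnm1", "tnm3"):
            ms = node_matches(clu, g.X, rule=rule)
            _, _, _, masks[rule] = ms.pair_block(0, 1)
        assert np.all(masks["tnm3"] <= masks["tnm1"])  # stricter threshold matches fewer

    def test_no_within_cluster_matches(self):
        clu, X = _two_pair_clusters()
        ms = node_matches(clu, X, rule="tnm0")
        with pytest.raises(ValueError):
            ms.pair_block(0, 0)

    def test_bnm_asymmetric_chain(self):
        # u's nearest is v, v's nearest is w: both directed matches present
        X = np.array([[0.0], [0.3], [0.45]])
        clu = Clustering(np.array([0, 1, 2]))
        ms = node_matches(clu, X, rule="bnm")
        assert ms.best[0] == 1 and ms.best[1] == 2 and ms.best[2] == 1
        _, _, _, m01 = ms.pair_block(0, 1)
        _, _, _, m12 = ms.pair_block(1, 2)
        assert m01[0, 0] and m12[0, 0]

    def test_bnm_match_is_cross_cluster(self):
        g = make_planted_graph(k=3, size=10, seed=5)
        clu = Clustering(np.repeat(np.arange(3), 10))
        ms = node_matches(clu, g.X, rule="bnm")
        assert np.all(clu.labels[ms.best] != clu.labels)


class TestClusterWeight:
    def test_count_all_four(self):
        clu, X = _two_pair_clusters()
        ms = node_matches(clu, X, rule="tnm0")
        assert cluster_weight(0, 1, "c", ms) == 4.0

    def test_max_count_uses_each_node_once(self):
        clu, X = _two_pair_clusters()
        ms = node_matches(clu, X, rule="tnm0")
        assert cluster_weight(0, 1, "mc", ms) == 2.0

    def test_identical_means_give_zero_e_weight(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        clu = Clustering(np.array([0, 0, 1, 1]))
        ms = node_matches(clu, X, rule="tnm0")
        assert cluster_weight(0, 1, "e", ms) == 0.0

    def test_s_zero_matches_weight_zero(self):
        X = np.array([[-1.0] * 3, [-1.0] * 3, [1.0] * 3, [1.0] * 3])
        clu = Clustering(np.array([0, 0, 1, 1]))
        ms = node_matches(clu, X, rule="tnm3")  # threshold above the cross sims
        assert cluster_weight(0, 1, "s", ms) == 0.0

    def test_bnm_with_matching_weights_unsupported(self):
        clu, X = _two_pair_clusters()
        ms = node_matches(clu, X, rule="bnm")
        for method in ("mc", "ms", "mss"):
            with pytest.raises(UnsupportedCombination):
                cluster_weight(0, 1, method, ms)

    def test_ms_mss_against_bipartite_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X = rng.uniform(-1, 1, (7, 3))
            clu = Clustering(np.array([0, 0, 0, 1, 1, 1, 1]))
            ms = node_matches(clu, X, rule="tnm0")
            _, _, sim, _ = ms.pair_block(0, 1)
            k, w = brute_force_bipartite_matching(sim)
            assert cluster_weight(0, 1, "mss", ms) == pytest.approx(w, abs=1e-9)
            assert cluster_weight(0, 1, "mc", ms) == k

    def test_mc_le_c_and_mss_bound(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            X = rng.uniform(-1, 1, (12, 4))
            clu = Clustering(np.repeat([0, 1], 6))
            ms = node_matches(clu, X, rule="tnm1")
            c = cluster_weight(0, 1, "c", ms)
            mc = cluster_weight(0, 1, "mc", ms)
            mss = cluster_weight(0, 1, "mss", ms)
            _, _, sim, mask = ms.pair_block(0, 1)
            assert mc <= c
            if mask.any():
                assert mss <= c * sim[mask].max() + 1e-12


class TestClusterGraph:
    def test_tcm0_keeps_all(self):
        w = {(0, 1): 1.0, (0, 2): 2.0, (1, 2): 3.0}
        cg = build_cluster_graph(w, rule="tcm0")
        assert cg.candidate_edges == [(0, 1), (0, 2), (1, 2)]

    def test_equal_weights_strict_threshold_empties(self):
        w = {(0, 1): 2.0, (0, 2): 2.0, (1, 2): 2.0}
        cg = build_cluster_graph(w, rule="tcm2")
        assert cg.candidate_edges == []  # beta equals the max weight

    def test_gcm_best_partner_union(self):
        # A's best is B, B's best is A, C's best is A
        w = {(0, 1): 5.0, (0, 2): 3.0, (1, 2): 1.0}
        cg = build_cluster_graph(w, rule="gcm")
        assert cg.candidate_edges == [(0, 1), (0, 2)]


class TestMatchClusters:
    def test_single_candidate(self):
        cg = build_cluster_graph({(0, 1): 2.0}, rule="tcm0")
        assert match_clusters(cg) == [(0, 1)]

    def test_two_pairs_beat_heavy_middle(self):
        w = {(0, 1): 3.0, (2, 3): 3.0, (1, 2): 5.0}
        cg = build_cluster_graph(w, rule="tcm0", g=4)
        pairs = match_clusters(cg)
        assert sorted(pairs) == [(0, 1), (2, 3)]

    @pytest.mark.parametrize("g", [4, 6, 8])
    def test_agrees_with_brute_force(self, g):
        rng = np.random.default_rng(g)
        for _ in range(30):
            pairs = [(i, j) for i in range(g) for j in range(i + 1, g)]
            keep = rng.random(len(pairs)) < 0.6
            w = {p: float(rng.uniform(0, 1)) for p, k in zip(pairs, keep) if k}
            if not w:
                continue
            cg = build_cluster_graph(w, rule="tcm0", g=g)
            got = sum(w[p] for p in match_clusters(cg))
            assert got == pytest.approx(brute_force_max_weight_matching(w), abs=1e-9)

    def test_constraint_each_cluster_once(self):
        rng = np.random.default_rng(5)
        w = {(i, j): float(rng.uniform(0, 1)) for i in range(6) for j in range(i + 1, 6)}
        cg = build_cluster_graph(w, rule="tcm0", g=6)
        pairs = match_clusters(cg)
        used = [c for p in pairs for c in p]
        assert len(used) == len(set(used))


class TestCMatchDesign:
    def test_two_identical_clusters_fully_enrolled(self):
        clu, X = _two_pair_clusters()
        g = make_planted_graph(k=2, size=2, n_out=1, seed=0)
        g = g.with_attributes(X)
        d = cmatch_design(g, clu, CMatchOptions(node_rule="tnm0", weight="c",
                                                cluster_rule="tcm0"), seed=1)
        assert d.excluded.size == 0
        assert set(d.arm[:2]) != set(d.arm[2:])
        assert len(set(d.arm[:2])) == 1 and len(set(d.arm[2:])) == 1

    def test_odd_cluster_count_leaves_one_out(self):
        g = make_planted_graph(k=5, size=8, seed=3)
        clu = Clustering(np.repeat(np.arange(5), 8))
        d = cmatch_design(g, clu, CMatchOptions(node_rule="tnm0", weight="c",
                                                cluster_rule="tcm0"), seed=2)
        assert d.excluded.size == 8  # exactly one whole cluster sits out
        # arms are unions of whole clusters
        for c in range(5):
            assert len(set(d.arm[clu.members(c)])) == 1

    def test_e_weight_pipeline_matches_clusters(self):
        g = make_planted_graph(k=4, size=10, seed=9)
        clu = Clustering(np.repeat(np.arange(4), 10))
        d = cmatch_design(g, clu, CMatchOptions(node_rule=None, weight="e",
                                                cluster_rule="tcm0"), seed=0)
        assert d.excluded.size == 0

    def test_empty_matching_raises(self):
        clu, X = _two_pair_clusters()
        g = make_planted_graph(k=2, size=2, n_out=1, seed=0).with_attributes(X)
        with pytest.raises(ValueError, match="no experiment"):
            # equal weights + strict threshold leave no candidates
            cmatch_design(g, clu, CMatchOptions(node_rule="tnm0", weight="c",
                                                cluster_rule="tcm3"), seed=0)

    def test_cross_arm_edges_below_node_randomization(self):
        """Whole-cluster arms cut fewer edges than node-level randomization on
        a planted-cluster graph."""
        from netdesign import cut_statistics, randomized_design

        g = make_planted_graph(k=4, size=15, seed=21, center_scale=0.4)
        clu = Clustering(np.repeat(np.arange(4), 15))
        opts = CMatchOptions(node_rule="tnm0", weight="c", cluster_rule="tcm0")
        cm, rd = [], []
        for s in range(50):
            cm.append(cut_statistics(g, cmatch_design(g, clu, opts, seed=s))["edge_fraction"])
            rd.append(cut_statistics(g, randomized_design(g, seed=s))["edge_fraction"])
        assert np.mean(cm) <= np.mean(rd)


def test_all_115_option_combinations_enumerate():
    combos = enumerate_option_combinations()
    assert len(combos) == 115
    with pytest.raises(UnsupportedCombination):
        CMatchOptions(node_rule="bnm", weight="mc")
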
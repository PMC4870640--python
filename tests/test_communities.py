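import networkx as nx
import numpy as np
import pytest

from conftest import set_partitions
from coocnet import communities as cm, null_models as nm
from coocnet.errors import InputError


def exhaustive_best(net, gamma=1.0):
    """Oracle: exhaustive search over all partitions (n <= 8)."""
    nodes = list(net)
    best_q, best_p = -np.inf, None
    for p in set_partitions(nodes):
        q = cm.modularity(net, p, gamma)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def two_cliques():
    return nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))


class TestModularity:
    def test_single_community_is_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=0)
        assert cm.modularity(g, {u: 0 for u in g}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = two_cliques()
        part = {i: 0 if i < 3 else 1 for i in g}
        assert cm.modularity(g, part) == pytest.approx(0.5)

    def test_decreasing_in_gamma(self):
        g = two_cliques()
        part = {i: 0 if i < 3 else 1 for i in g}
        qs = [cm.modularity(g, part, gamma) for gamma in (0.5, 1.0, 2.0, 4.0)]
        assert qs == sorted(qs, reverse=True)

    def test_matches_networkx(self):
        for seed in range(5):
            g = nx.gnp_random_graph(12, 0.35, seed=seed)
            if g.number_of_edges() == 0:
                continue
            part = {u: u % 3 for u in g}
            comms = [{u for u in g if u % 3 == c} for c in range(3)]
            assert cm.modularity(g, part) == pytest.approx(
                nx.community.modularity(g, [c for c in comms if c]))

    def test_edgeless_rejected(self):
        with pytest.raises(InputError):
            cm.modularity(nx.empty_graph(3), {0: 0, 1: 0, 2: 0})


class TestLouvain:
    def test_two_cliques_recovered(self):
        g = two_cliques()
        part = cm.louvain(g, seed=0)
        assert part.n_communities == 2
        assert part.Q == pytest.approx(0.5)
        best_q, _ = exhaustive_best(g)
        assert part.Q == pytest.approx(best_q)

    def test_complete_graph_single_community(self):
        part = cm.louvain(nx.complete_graph(6), seed=0)
        assert part.n_communities == 1

    def test_never_below_single_community_baseline(self):
        for seed in range(8):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            baseline = cm.modularity(g, {u: 0 for u in g})
            assert cm.louvain(g, seed=seed).Q >= baseline - 1e-12

    def test_multistart_reaches_exhaustive_optimum(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            g = nx.gnp_random_graph(int(rng.integers(5, 9)),
                                    float(rng.uniform(0.3, 0.7)),
                                    seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            best_q, _ = exhaustive_best(g)
            assert cm.louvain(g, seed=1, n_restarts=10).Q >= best_q - 1e-12

    def test_planted_partition_recovered_across_seeds(self):
        g = nx.planted_partition_graph(4, 10, 0.9, 0.05, seed=0)
        truth = {u: u // 10 for u in g}
        hits = sum(
            cm.rand_index(cm.louvain(g, seed=s).membership, truth) == 1.0
            for s in range(20))
        assert hits >= 19


class TestConsensus:
    def test_identical_runs_short_circuit(self):
        g = two_cliques()
        res = cm.consensus(g, n_runs=20, seed=0)
        assert res.n_consensus_iterations == 0
        assert res.consensus_partition.n_communities == 2
        assert res.Q_sd == pytest.approx(0.0)

    def test_community_count_frequencies_concentrate(self, planted_cohort):
        res = cm.consensus(planted_cohort["net"], n_runs=40, seed=1)
        freq = res.community_count_frequencies
        assert sum(freq.values()) == pytest.approx(1.0)
        assert freq.get(4, 0.0) >= 0.8

    def test_idempotent_on_agreement_structure(self, planted_cohort):
        """Re-running consensus seeded from a stable partition reproduces it:
        the agreement matrix of identical runs is block-binary."""
        net = planted_cohort["net"]
        res = cm.consensus(net, n_runs=25, seed=3)
        agree = res.agreement.to_numpy()
        memb = res.consensus_partition.labels_for(sorted(net))
        same = memb[:, None] == memb[None, :]
        # within consensus blocks agreement is high, across blocks low
        assert agree[same].mean() > 0.9
        assert agree[~same].mean() < 0.2

    def test_invalid_runs_rejected(self):
        with pytest.raises(InputError):
            cm.consensus(two_cliques(), n_runs=0)

    def test_modular_network_beats_rewired_nulls(self, planted_cohort):
        """Q_mean of the planted network exceeds every rewired null's
        (one-sided empirical p < 0.01 at ensemble size 100)."""
        net = planted_cohort["net"]
        q_real = np.mean([cm.louvain(net, seed=s).Q for s in range(10)])
        ens = nm.make_ensemble(net, 100, seed=0)
        null_q = [cm.louvain(m, seed=i).Q for i, m in enumerate(ens.members)]
        p = (1 + sum(q >= q_real for q in null_q)) / (len(null_q) + 1)
        assert p < 0.01


class TestRandIndex:
    def test_identical_partitions(self):
        p = {"a": 0, "b": 0, "c": 1}
        assert cm.rand_index(p, dict(p)) == 1.0

    def test_three_node_hand_case(self):
        assert cm.rand_index({"a": 0, "b": 0, "c": 1},
                             {"a": 0, "b": 1, "c": 1}) == pytest.approx(1 / 3)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(InputError):
            cm.rand_index({"a": 0}, {"b": 0})


class TestRandPermutationTest:
    def test_identical_balanced_partitions_minimal_p(self):
        p = {f"n{i}": i % 3 for i in range(30)}
        out = cm.rand_permutation_test(p, dict(p), n_perm=999, seed=0)
        assert out["p"] == pytest.approx(1 / 1000)
        assert out["observed"] == 1.0

    def test_random_relabeling_calibrated(self):
        rng = np.random.default_rng(0)
        p1 = {f"n{i}": i % 4 for i in range(40)}
        ps = []
        for s in range(20):
            vals = rng.permutation(list(p1.values()))
            p2 = dict(zip(p1, vals.tolist()))
            ps.append(cm.rand_permutation_test(p1, p2, n_perm=199, seed=s)["p"])
        assert 0.05 < np.mean(ps) < 0.95

    def test_null_mean_matches_analytic_expectation(self):
        """Under label permutation E[Rand] has a closed form from the two
        partitions' block sizes."""
        p1 = {f"n{i}": i % 3 for i in range(30)}
        p2 = {f"n{i}": (i // 10) for i in range(30)}
        out = cm.rand_permutation_test(p1, p2, n_perm=2000, seed=1)
        n = 30
        pairs = n * (n - 1) / 2

        def same_prob(p):
            sizes = np.bincount(np.array(list(p.values())))
            return (sizes * (sizes - 1)).sum() / 2 / pairs

        s1, s2 = same_prob(p1), same_prob(p2)
        expected = s1 * s2 + (1 - s1) * (1 - s2)
        se = out["null_sd"] / np.sqrt(2000)
        assert abs(out["null_mean"] - expected) < max(3 * se, 1e-3)

    def test_degenerate_single_community_flagged(self):
        p1 = {f"n{i}": 0 for i in range(20)}
        p2 = {f"n{i}": i % 2 for i in range(20)}
        out = cm.rand_permutation_test(p1, p2, n_perm=100, seed=0)
        assert out["degenerate"]
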
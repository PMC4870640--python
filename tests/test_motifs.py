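import itertools

import networkx as nx
import numpy as np
import pytest

from coocnet import motifs as mo, null_models as nm
from coocnet.errors import InputError

# independent reference graphs for isomorphism-based classification
REFERENCE = {
    3: {"path": nx.path_graph(3), "triangle": nx.complete_graph(3)},
    4: {
        "star": nx.star_graph(3),
        "path": nx.path_graph(4),
        "tadpole": nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)]),
        "cycle": nx.cycle_graph(4),
        "diamond": nx.Graph([(0, 1), (1, 2), (0, 2), (0, 3), (1, 3)]),
        "clique": nx.complete_graph(4),
    },
}


def brute_force_census(net, size):
    """Oracle: test every node subset, classify by isomorphism."""
    counts = dict.fromkeys(mo.MOTIF_CLASSES[size], 0)
    for subset in itertools.combinations(net.nodes, size):
        sub = net.subgraph(subset)
        if not nx.is_connected(sub):
            continue
        for name, ref in REFERENCE[size].items():
            if nx.is_isomorphic(sub, ref):
                counts[name] += 1
                break
    return counts


class TestCensus:
    def test_triangle_graph(self):
        c = mo.census(nx.complete_graph(3), 3)
        assert c.counts == {"triangle": 1, "path": 0}

    def test_triangle_pendant_size4_is_single_tadpole(self, triangle_pendant):
        c = mo.census(triangle_pendant, 4)
        assert c.counts["tadpole"] == 1
        assert c.total() == 1

    def test_triangle_pendant_size3(self, triangle_pendant):
        c = mo.census(triangle_pendant, 3)
        assert c.counts == {"triangle": 1, "path": 2}

    def test_invalid_size_rejected(self, triangle_pendant):
        with pytest.raises(InputError):
            mo.census(triangle_pendant, 5)

    @pytest.mark.parametrize("size", [3, 4])
    def test_matches_brute_force_enumeration(self, size):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(size, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(2**31)))
            assert mo.census(g, size).counts == brute_force_census(g, size)

    @pytest.mark.parametrize("size", [3, 4])
    def test_relabeling_invariance(self, size):
        g = nx.gnp_random_graph(10, 0.4, seed=7)
        mapping = {i: f"node_{(i * 7) % 10}" for i in g}
        assert (mo.census(g, size).counts
                == mo.census(nx.relabel_nodes(g, mapping), size).counts)

    @pytest.mark.parametrize("size", [3, 4])
    def test_participation_sums(self, size):
        """Summed per-node participation for a c-node class = c x count."""
        g = nx.gnp_random_graph(11, 0.35, seed=3)
        c = mo.census(g, size)
        for cls in mo.MOTIF_CLASSES[size]:
            total = sum(p[cls] for p in c.per_node.values())
            assert total == size * c.counts[cls]


class TestSignificance:
    def test_self_null_gives_small_z(self):
        g = nm.rewire_degree_preserving(nx.gnp_random_graph(25, 0.25, seed=0), seed=1)
        ens = nm.make_ensemble(g, 60, seed=2)
        res = mo.census_significance(g, ens, 3)
        assert np.nanmax(np.abs(res["z"])) < 4

    def test_clustered_network_enriches_triangles(self, planted_cohort):
        net = planted_cohort["net"]
        ens = nm.make_ensemble(net, 20, seed=0)
        res = mo.census_significance(net, ens, 3)
        assert res.loc["triangle", "z"] > 2

    def test_singleton_ensemble_p_values(self):
        g = nx.gnp_random_graph(15, 0.35, seed=4)
        ens = nm.make_ensemble(g, 1, seed=0)
        res = mo.census_significance(g, ens, 3)
        assert set(res["p"]).issubset({0.5, 1.0})


class TestProfileCompare:
    def test_identical_censuses_not_significant(self):
        g = nx.gnp_random_graph(15, 0.4, seed=0)
        c = mo.census(g, 4)
        out = mo.profile_compare(c, c, seed=0)
        assert out.p_value > 0.9
        assert out.attribution == []

    def test_single_class_difference_attributed(self):
        """Censuses differing in exactly one class: dropping that class and
        only that class removes the significance."""
        a = mo.MotifCensus(4, {"star": 400, "path": 400, "tadpole": 100,
                               "cycle": 200, "diamond": 200, "clique": 200}, {})
        b = mo.MotifCensus(4, {"star": 400, "path": 400, "tadpole": 300,
                               "cycle": 200, "diamond": 200, "clique": 200}, {})
        out = mo.profile_compare(a, b, seed=0)
        assert out.p_value < 0.05
        assert out.attribution == ["tadpole"]

    def test_size_mismatch_rejected(self):
        a = mo.MotifCensus(3, {"path": 1, "triangle": 1}, {})
        b = mo.MotifCensus(4, dict.fromkeys(mo.MOTIF_CLASSES[4], 1), {})
        with pytest.raises(InputError):
            mo.profile_compare(a, b)

    def test_low_counts_use_simulated_p(self):
        a = mo.MotifCensus(3, {"path": 3, "triangle": 2}, {})
        b = mo.MotifCensus(3, {"path": 2, "triangle": 4}, {})
        out = mo.profile_compare(a, b, seed=0)
        assert out.simulated
        assert 0 < out.p_value <= 1


class TestDegreeAdjustedParticipation:
    def test_exactly_linear_counts_have_zero_residuals(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3)])
        census = mo.MotifCensus(3, {"path": 0, "triangle": 0},
                                {u: {"path": 2 * g.degree[u], "triangle": 0} for u in g})
        res = mo.degree_adjusted_participation(census, g, "path")
        assert np.allclose(res["residual"], 0.0)

    def test_closed_form_ols(self):
        """Degrees (1,2,3), counts (2,4,6): slope 2, intercept 0."""
        g = nx.path_graph(4)
        g.add_edge(1, 3)  # degrees: 1,3,2,2 -> adjust to get 1,2,3 distinct
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        counts = {"a": 4, "b": 4, "c": 6, "d": 2}
        census = mo.MotifCensus(3, {"path": 0, "triangle": 0},
                                {u: {"path": counts[u], "triangle": 0} for u in g})
        # degrees: a=2,b=2,c=3,d=1; counts = 2*degree
        res = mo.degree_adjusted_participation(census, g, "path")
        assert np.allclose(res["residual"], 0.0)
        assert np.allclose(res["expected"], 2 * res["degree"])

    def test_constant_degree_flagged(self):
        g = nx.cycle_graph(5)
        census = mo.census(g, 3)
        res = mo.degree_adjusted_participation(census, g, "path")
        assert res.attrs["degenerate"]

    def test_promoted_hubs_top_differential_ranking(self, hub_core_cohort):
        """Hub species promoted only in the hub-core cohort rank top by
        differential normalized tadpole participation against a plain
        cohort."""
        from coocnet import cooccurrence as co
        from coocnet.synthetic_data import four_module_spec, generate_cohort

        net_hub = hub_core_cohort["net"]
        plain_table, _ = generate_cohort(four_module_spec(120, 120, seed=2))
        net_plain, _ = co.build_network(plain_table)
        net_plain, net_hub = co.harmonize_species_sets(net_plain, net_hub)
        res_plain = mo.degree_adjusted_participation(
            mo.census(net_plain, 4), net_plain, "tadpole")
        res_hub = mo.degree_adjusted_participation(
            mo.census(net_hub, 4), net_hub, "tadpole")
        diff = mo.differential_residuals(res_plain, res_hub)
        hubs = hub_core_cohort["spec"].hub_promotions
        top8 = set(diff.index[:8])  # most hub-enriched (z_plain - z_hub lowest)
        assert len(top8 & hubs) >= 4
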
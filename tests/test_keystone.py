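import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import naive_zi_pi
from rhizonet import keystone


def two_cliques():
    g = nx.Graph()
    g.add_edges_from(
        (f"a{i}", f"a{j}") for i in range(5) for j in range(i + 1, 5)
    )
    g.add_edges_from(
        (f"b{i}", f"b{j}") for i in range(5) for j in range(i + 1, 5)
    )
    g.add_edge("a0", "b0")
    return g


class TestDetectModules:
    def test_two_cliques_two_modules(self):
        partition, q = keystone.detect_modules(two_cliques())
        assert len(set(partition.values())) == 2
        assert len({partition[f"a{i}"] for i in range(5)}) == 1
        assert len({partition[f"b{i}"] for i in range(5)}) == 1
        assert q > 0.3

    def test_complete_graph_single_module(self):
        partition, _ = keystone.detect_modules(nx.complete_graph(6))
        assert set(partition.values()) == {0}

    def test_edgeless_network_singletons_with_warning(self):
        g = nx.empty_graph(4)
        with pytest.warns(UserWarning, match="edgeless"):
            partition, q = keystone.detect_modules(g)
        assert sorted(partition.values()) == [0, 1, 2, 3]
        assert q == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            keystone.detect_modules(nx.Graph())

    def test_module_ids_contiguous(self, demo_bundle):
        from rhizonet import network

        _, table, _, _ = demo_bundle
        net = network.correlation_network(table)
        partition, _ = keystone.detect_modules(net)
        ids = sorted(set(partition.values()))
        assert ids == list(range(len(ids)))

    def test_deterministic_across_runs(self):
        g = two_cliques()
        assert keystone.detect_modules(g) == keystone.detect_modules(g)


class TestZiPi:
    def test_hand_built_module(self):
        # one module, within-degrees (4,2,2,2,2,2): Zi(hub) = 1.667/0.745
        g = nx.Graph(
            [
                ("a0", "a1"), ("a0", "a2"), ("a0", "a3"), ("a0", "a4"),
                ("a1", "a5"), ("a2", "a5"), ("a3", "a4"),
            ]
        )
        partition = {n: 0 for n in g.nodes()}
        zi = keystone.within_module_z(g, partition)
        assert zi["a0"] == pytest.approx((4 - 7 / 3) / 0.745356, abs=1e-4)
        assert zi["a0"] == pytest.approx(2.236, abs=1e-3)

    def test_node_at_module_mean_and_homogeneous_module(self):
        g = nx.cycle_graph(4)  # all within-degrees equal -> sd = 0 -> Zi = 0
        partition = {n: 0 for n in g.nodes()}
        zi = keystone.within_module_z(g, partition)
        assert all(v == 0.0 for v in zi.values())

    def test_participation_split_evenly_over_three_modules(self):
        g = nx.Graph()
        partition = {"x": 0}
        for m in range(3):
            for i in range(2):
                node = f"m{m}n{i}"
                g.add_edge("x", node)
                partition[node] = m
        pi = keystone.participation_coefficient(g, partition)
        assert pi["x"] == pytest.approx(2 / 3)

    def test_all_edges_internal_gives_zero_participation(self):
        g = nx.complete_graph(4)
        partition = {n: 0 for n in g.nodes()}
        pi = keystone.participation_coefficient(g, partition)
        assert all(v == 0.0 for v in pi.values())

    def test_isolated_node_pi_zero(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        partition = {"lonely": 0, "a": 0, "b": 1}
        pi = keystone.participation_coefficient(g, partition)
        assert pi["lonely"] == 0.0

    def test_matches_naive_reference_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
            partition = {
                node: int(rng.integers(0, 4)) for node in g.nodes()
            }
            zi = keystone.within_module_z(g, partition)
            pi = keystone.participation_coefficient(g, partition)
            zi_ref, pi_ref = naive_zi_pi(
                list(g.edges()), list(g.nodes()), partition
            )
            for node in g.nodes():
                assert zi[node] == pytest.approx(zi_ref[node], abs=1e-12)
                assert pi[node] == pytest.approx(pi_ref[node], abs=1e-12)

    def test_edge_conservation(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        partition = {n: n % 3 for n in g.nodes()}
        for node in g.nodes():
            per_module = {}
            for nb in g.neighbors(node):
                per_module[partition[nb]] = per_module.get(partition[nb], 0) + 1
            assert sum(per_module.values()) == g.degree(node)


class TestRoles:
    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.5, "module_hub"),
            (3.0, 0.7, "network_hub"),
            (1.0, 0.7, "connector"),
            (1.0, 0.3, "peripheral"),
            (2.5, 0.62, "peripheral"),  # strict inequalities at both bounds
            (2.5000001, 0.62, "module_hub"),
            (2.5, 0.6200001, "connector"),
        ],
    )
    def test_four_way_rule(self, zi, pi, expected):
        assert keystone.classify_roles(zi, pi) == expected

    @given(
        zi=st.floats(-3, 6, allow_nan=False),
        pi=st.floats(0, 1, allow_nan=False),
        p_star=st.floats(0.1, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_p_threshold_never_creates_connectors(self, zi, pi, p_star):
        base = keystone.classify_roles(zi, pi, p_threshold=p_star)
        higher = keystone.classify_roles(zi, pi, p_threshold=min(p_star + 0.2, 1.0))
        if base != "connector":
            assert higher != "connector"

    def test_keystone_iff_not_peripheral(self):
        g = two_cliques()
        partition, _ = keystone.detect_modules(g)
        roles = keystone.node_roles(g, partition)
        assert (roles["keystone"] == (roles["role"] != "peripheral")).all()


class TestAggregate:
    def _roles_frame(self, rows):
        return pd.DataFrame(rows).set_index("taxon_id")

    def test_all_peripheral_empty_summary(self):
        roles = self._roles_frame(
            [
                {"taxon_id": "t1", "phylum": "Phylum_A", "role": "peripheral"},
                {"taxon_id": "t2", "phylum": "Phylum_B", "role": "peripheral"},
            ]
        )
        assert keystone.aggregate_by_taxon(roles).empty

    def test_single_network_hub_counted(self):
        taxonomy = pd.Series(
            {"t1": "Bacteroidetes;c;o;f;g"}, name="lineage"
        )
        roles = self._roles_frame(
            [{"taxon_id": "t1", "phylum": "Bacteroidetes", "role": "network_hub"}]
        )
        summary = keystone.aggregate_by_taxon(roles, taxonomy)
        assert summary.loc["Bacteroidetes", "network_hub"] == 1

    def test_counts_conserve_non_peripheral_total(self, demo_bundle):
        from rhizonet import network

        _, table, taxonomy, _ = demo_bundle
        net = network.correlation_network(table)
        partition, _ = keystone.detect_modules(net)
        roles = keystone.node_roles(net, partition, taxonomy=taxonomy)
        summary = keystone.aggregate_by_taxon(roles, taxonomy)
        assert summary.to_numpy().sum() == (roles["role"] != "peripheral").sum()

    def test_unannotated_nodes_grouped_as_unidentified(self):
        taxonomy = pd.Series({"known": "Phylum_A;c;o;f;g"}, name="lineage")
        roles = self._roles_frame(
            [
                {"taxon_id": "known", "phylum": "Phylum_A", "role": "connector"},
                {"taxon_id": "mystery", "phylum": "", "role": "connector"},
            ]
        )
        summary = keystone.aggregate_by_taxon(roles, taxonomy)
        assert summary.loc["unidentified", "connector"] == 1
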
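"""Network construction, topology metrics, centrality, keystone criteria."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import micronet as mn
from micronet.sparcc import CorrelationMatrix
from micronet.table import AbundanceTable


def _corr(entries, n=4):
    """CorrelationMatrix with the given {(i, j): rho} off-diagonal entries."""
    rho = np.eye(n)
    for (i, j), v in entries.items():
        rho[i, j] = rho[j, i] = v
    return CorrelationMatrix([f"t{i}" for i in range(n)], rho, np.ones(n))


class TestBuildNetwork:
    def test_strictly_above_threshold_retained(self):
        net = mn.build_network(_corr({(0, 1): 0.76, (1, 2): 0.75, (2, 3): -0.8}))
        assert net.has_edge("t0", "t1")
        assert not net.has_edge("t1", "t2")  # 0.75 exactly is excluded
        assert net.has_edge("t2", "t3")
        assert net.edges["t2", "t3"]["sign"] == -1

    def test_isolates_dropped(self):
        net = mn.build_network(_corr({(0, 1): 0.9}))
        assert set(net.nodes) == {"t0", "t1"}

    def test_core_nested_in_standard_network(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(-1, 1, size=(8, 8))
        rho = np.clip((M + M.T) / 2, -0.999, 0.999)
        np.fill_diagonal(rho, 1.0)
        cm = CorrelationMatrix([f"t{i}" for i in range(8)], rho, np.ones(8))
        edges75 = set(map(frozenset, mn.build_network(cm, 0.75).edges))
        edges95 = set(map(frozenset, mn.core_network(cm).edges))
        assert edges95 <= edges75

    def test_threshold_nesting_property(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(-1, 1, size=(10, 10))
        rho = np.clip((M + M.T) / 2, -0.999, 0.999)
        np.fill_diagonal(rho, 1.0)
        cm = CorrelationMatrix([f"t{i}" for i in range(10)], rho, np.ones(10))
        for t1, t2 in [(0.2, 0.5), (0.5, 0.8), (0.3, 0.9)]:
            e1 = set(map(frozenset, mn.build_network(cm, t1).edges))
            e2 = set(map(frozenset, mn.build_network(cm, t2).edges))
            assert e2 <= e1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            mn.build_network(_corr({}), threshold=1.2)


class TestTopologySummary:
    def test_triangle(self):
        net = mn.make_fixture_graph("complete", 3)
        topo = mn.topology_summary(net)
        assert (topo.n_nodes, topo.n_edges) == (3, 3)
        assert topo.avg_degree == 2
        assert topo.clustering_coefficient == 1
        assert topo.diameter == 1
        assert topo.n_modules == 1

    def test_path_of_five(self):
        net = mn.make_fixture_graph("path", 5)
        topo = mn.topology_summary(net)
        assert topo.diameter == 4
        assert topo.clustering_coefficient == 0

    def test_two_disjoint_triangles_modularity(self):
        # Newman's Q = sum(e_ii - a_i^2) = 2 (1/2 - 1/4) = 0.5
        net = nx.Graph()
        for base in ("a", "b"):
            for u, v in itertools.combinations(range(3), 2):
                net.add_edge(f"{base}{u}", f"{base}{v}", weight=1.0, absweight=1.0, sign=1)
        topo = mn.topology_summary(net)
        assert topo.modularity == pytest.approx(0.5, abs=1e-12)
        assert topo.n_modules == 2

    def test_sign_counts_partition_edges(self):
        net = mn.build_network(_corr({(0, 1): 0.9, (1, 2): -0.8, (2, 3): 0.85}))
        topo = mn.topology_summary(net)
        assert topo.n_positive == 2
        assert topo.n_negative == 1
        assert topo.n_positive + topo.n_negative == topo.n_edges

    def test_diameter_and_clustering_match_brute_force_on_small_graphs(self):
        # exhaustive check against hand-rolled all-pairs BFS + triangle count
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for G in graph_atlas_g()[1:]:
            if G.number_of_nodes() < 2 or G.number_of_nodes() > 6:
                continue
            if G.number_of_edges() == 0:
                continue
            net = nx.Graph()
            net.add_nodes_from(f"n{v}" for v in G.nodes)
            net.add_edges_from((f"n{u}", f"n{v}", {"weight": 1.0, "absweight": 1.0, "sign": 1})
                               for u, v in G.edges)
            topo = mn.topology_summary(net)
            # oracle diameter: BFS within every largest component
            comps = list(nx.connected_components(net))
            lcc_size = max(len(c) for c in comps)
            dia = 0
            for comp in comps:
                if len(comp) != lcc_size:
                    continue
                for s in comp:
                    depth = {s: 0}
                    frontier = [s]
                    while frontier:
                        nxt = []
                        for u in frontier:
                            for w in net[u]:
                                if w not in depth:
                                    depth[w] = depth[u] + 1
                                    nxt.append(w)
                        frontier = nxt
                    dia = max(dia, max(depth.values()))
            assert topo.diameter == dia
            # oracle clustering: triangles / possible wedges per node
            cc = []
            for v in net:
                nbrs = list(net[v])
                k = len(nbrs)
                if k < 2:
                    cc.append(0.0)
                    continue
                links = sum(1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b))
                cc.append(2 * links / (k * (k - 1)))
            assert topo.clustering_coefficient == pytest.approx(np.mean(cc), abs=1e-12)
            checked += 1
        assert checked > 100

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mn.topology_summary(nx.Graph())


class TestEigenvectorCentrality:
    def test_complete_graph_all_ones(self):
        net = mn.make_fixture_graph("complete", 6)
        eig = mn.eigenvector_centrality(net)
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in eig.values())

    def test_star_leaves_at_half(self):
        net = mn.make_fixture_graph("star", 5)
        eig = mn.eigenvector_centrality(net)
        hub = max(eig, key=eig.get)
        assert eig[hub] == pytest.approx(1.0)
        for v, val in eig.items():
            if v != hub:
                assert val == pytest.approx(0.5, abs=1e-8)

    def test_path_of_three(self):
        net = mn.make_fixture_graph("path", 3)
        eig = mn.eigenvector_centrality(net)
        vals = sorted(eig.values(), reverse=True)
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == pytest.approx(1 / np.sqrt(2), abs=1e-8)

    def test_matches_networkx_up_to_normalization(self):
        net = mn.make_fixture_graph("erdos_renyi", 25, param=0.25, seed=7)
        net.remove_nodes_from(list(nx.isolates(net)))
        eig = mn.eigenvector_centrality(net)
        ref = nx.eigenvector_centrality_numpy(net, weight="absweight")
        scale = max(ref.values())
        for v in net:
            assert eig[v] == pytest.approx(ref[v] / scale, abs=1e-6)


def _group_table(counts, group="g1"):
    counts = np.asarray(counts)
    ids = [f"s{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=ids, columns=[f"t{j}" for j in range(counts.shape[1])])
    meta = pd.DataFrame({"group": group, "timepoint": "t", "is_control": False}, index=ids)
    return AbundanceTable(df, meta)


class TestUbiquityAndKeystones:
    def test_ubiquity_requires_presence_in_every_sample(self):
        tab = _group_table([[1, 1, 0], [2, 1, 5], [9, 1, 2]])
        assert mn.ubiquity(tab, "g1") == {"t0", "t1"}  # t2 is absent in one sample

    def test_single_sample_group(self):
        tab = _group_table([[0, 3, 1]])
        assert mn.ubiquity(tab, "g1") == {"t1", "t2"}

    def test_unknown_group_rejected(self):
        tab = _group_table([[1, 2, 3]])
        with pytest.raises(KeyError):
            mn.ubiquity(tab, "nope")

    def test_keystone_triple_intersection_with_boundaries(self):
        # star: hub t0 has eigenvector 1, leaves 0.5 -> vary the other
        # criteria around their cutoffs via a crafted clr matrix
        net = nx.Graph()
        for leaf in ["t1", "t2", "t3", "t4"]:
            net.add_edge("t0", leaf, weight=0.9, absweight=0.9, sign=1)
        counts = np.array([
            [5, 5, 5, 0, 5],
            [5, 5, 5, 5, 5],
        ])
        tab = _group_table(counts)
        clr_vals = pd.DataFrame(
            [[0.40, 0.35, 0.34, 2.0, -3.09],
             [0.40, 0.35, 0.34, 2.0, -3.09]],
            index=tab.sample_ids, columns=tab.taxon_ids,
        )
        clr = mn.ClrMatrix(clr_vals)
        report = mn.keystone_taxa(net, clr, tab, "g1", abund_cut=0.35, eig_cut=0.75)
        # independent construction of each criterion set
        ubiq = mn.ubiquity(tab, "g1")
        eig = mn.eigenvector_centrality(net)
        abund = {t for t in net if clr_vals[t].mean() >= 0.35}
        central = {t for t in net if eig[t] >= 0.75}
        expected = set(net) & ubiq & abund & central
        assert set(report.index[report["is_keystone"]]) == expected
        # boundary semantics: t1 sits exactly at 0.35 but is a leaf (0.5 < 0.75)
        assert report.loc["t1", "mean_clr"] == pytest.approx(0.35)
        assert not report.loc["t1", "is_keystone"]
        # the hub t0: ubiquitous, clr 0.40 >= 0.35, eigenvector 1 -> keystone
        assert report.loc["t0", "is_keystone"]

    def test_missing_clr_taxa_rejected(self):
        net = nx.Graph()
        net.add_edge("tA", "tB", weight=0.9, absweight=0.9, sign=1)
        tab = _group_table([[1, 1], [1, 1]])
        clr = mn.clr_transform(tab)
        with pytest.raises(ValueError, match="missing"):
            mn.keystone_taxa(net, clr, tab, "g1")


class TestGraphExport:
    def test_graphml_roundtrip_preserves_attributes(self, tmp_path):
        net = mn.build_network(_corr({(0, 1): 0.9, (1, 2): -0.8}))
        path = tmp_path / "net.graphml"
        mn.write_graph(net, path)
        back = nx.read_graphml(path)
        assert back.edges[("t0", "t1")]["weight"] == pytest.approx(0.9)
        assert back.edges[("t1", "t2")]["sign"] == -1
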
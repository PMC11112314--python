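"""Attack simulation, connectivity loss, node addition, and their statistics."""

import networkx as nx
import numpy as np
import pytest

import micronet as mn
from micronet.robustness import STRATEGIES
from conftest import brute_force_reachable_pairs


class TestConnectivityLoss:
    def test_no_removal_no_loss(self):
        net = mn.make_fixture_graph("path", 4)
        assert mn.connectivity_loss(net, set()) == 0

    def test_full_removal_total_loss(self):
        net = mn.make_fixture_graph("path", 4)
        assert mn.connectivity_loss(net, set(net.nodes)) == 1

    def test_path_end_removal_closed_form(self):
        # path A-B-C: R0 = 6 ordered pairs; removing A leaves B-C (2 pairs)
        net = mn.make_fixture_graph("path", 3)
        end = [v for v, d in net.degree() if d == 1][0]
        assert mn.connectivity_loss(net, {end}) == pytest.approx(2 / 3)

    def test_unknown_node_rejected(self):
        net = mn.make_fixture_graph("path", 3)
        with pytest.raises(ValueError, match="not in graph"):
            mn.connectivity_loss(net, {"zzz"})

    def test_kn_closed_form(self):
        # complete graph: loss after k removals = 1 - (n-k)(n-k-1)/(n(n-1))
        for n in (4, 6, 9):
            net = mn.make_fixture_graph("complete", n)
            nodes = sorted(net.nodes)
            for k in range(n + 1):
                loss = mn.connectivity_loss(net, set(nodes[:k]))
                expect = 1 - (n - k) * (n - k - 1) / (n * (n - 1))
                assert loss == pytest.approx(expect, abs=1e-12)


class TestAttack:
    def test_star_degree_attack_kills_hub_first(self):
        net = mn.make_fixture_graph("star", 5)
        curve = mn.attack(net, "degree")
        assert curve.loss_at_step[0] == 1.0
        assert curve.fraction_at_target == pytest.approx(0.2)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_k5_all_strategies_closed_form(self, strategy):
        net = mn.make_fixture_graph("complete", 5)
        curve = mn.attack(net, strategy, seed=3)
        assert curve.fraction_at_target == pytest.approx(0.6)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_loss_sequence_monotone_and_exhaustive(self, strategy):
        for seed in range(10):
            net = mn.make_fixture_graph("erdos_renyi", 25, param=0.15, seed=seed)
            net.add_edge("n0", "n1", weight=1.0, absweight=1.0, sign=1)  # ensure an edge
            curve = mn.attack(net, strategy, seed=seed)
            losses = curve.loss_at_step
            assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))
            assert losses[-1] == pytest.approx(1.0)
            assert len(curve.removal_order) == net.number_of_nodes()

    def test_loss_curve_matches_brute_force_oracle(self):
        net = mn.make_fixture_graph("barabasi_albert", 30, param=2, seed=1)
        adj = {v: set(net[v]) for v in net}
        n = net.number_of_nodes()
        r0 = brute_force_reachable_pairs(adj, set(net.nodes))
        curve = mn.attack(net, "cascading")
        alive = set(net.nodes)
        for victim, loss in zip(curve.removal_order, curve.loss_at_step):
            alive.discard(victim)
            expect = 1 - brute_force_reachable_pairs(adj, alive) / r0
            assert loss == pytest.approx(expect, abs=1e-12)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            mn.attack(mn.make_fixture_graph("path", 4), "entropy")


class TestRandomAttackCI:
    def test_k5_ci_degenerate(self):
        net = mn.make_fixture_graph("complete", 5)
        mean, (lo, hi) = mn.random_attack_ci(net, n_boot=30, seed=0)
        assert mean == pytest.approx(0.6)
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_star_random_mean_exceeds_targeted(self):
        # exact expectation over hub positions: hitting the hub first has
        # probability 1/5, so the mean fraction is strictly above 0.2
        net = mn.make_fixture_graph("star", 5)
        mean, (lo, hi) = mn.random_attack_ci(net, n_boot=200, seed=1)
        assert mean > 0.2
        assert lo <= mean <= hi


class TestApl:
    def test_complete_graph(self):
        assert mn.apl(mn.make_fixture_graph("complete", 7)) == pytest.approx(1.0)

    def test_path_of_three(self):
        assert mn.apl(mn.make_fixture_graph("path", 3)) == pytest.approx(4 / 3)

    def test_two_disjoint_edges_count_connected_pairs_only(self):
        net = nx.Graph()
        net.add_edge("a", "b")
        net.add_edge("c", "d")
        assert mn.apl(net) == pytest.approx(1.0)

    def test_edgeless_graph_is_nan(self):
        net = nx.Graph()
        net.add_nodes_from("ab")
        assert np.isnan(mn.apl(net))


class TestAddNodes:
    def test_zero_additions_noop(self):
        net = mn.make_fixture_graph("path", 4)
        grown, trace = mn.add_nodes(net, 0, seed=0)
        assert trace.lcc_size == [] and trace.apl == []
        assert nx.utils.graphs_equal(grown, net)

    def test_uniform_addition_grows_lcc_by_one_each_step(self):
        net = mn.make_fixture_graph("barabasi_albert", 20, param=1, seed=2)
        n0 = net.number_of_nodes()
        grown, trace = mn.add_nodes(net, 100, seed=3)
        assert trace.lcc_size == list(range(n0 + 1, n0 + 101))
        assert grown.number_of_nodes() == n0 + 100

    def test_single_attachment_to_edge_makes_path(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1.0, absweight=1.0, sign=1)
        grown, trace = mn.add_nodes(net, 1, seed=1)
        assert trace.apl[-1] == pytest.approx(4 / 3)
        assert grown.number_of_edges() == 2

    def test_preferential_rule_favors_hubs(self):
        net = mn.make_fixture_graph("star", 11)
        hub = max(dict(net.degree()), key=dict(net.degree()).get)
        hits = 0
        for seed in range(200):
            grown, _ = mn.add_nodes(net, 1, rule="preferential", seed=seed)
            if grown.has_edge("added0000", hub):
                hits += 1
        # hub draw probability (10+1)/31 ~ 0.35; uniform would give ~1/11.
        # 200 trials put the uniform null far below this threshold.
        assert hits > 40

    def test_attach_edges_exceeding_nodes_rejected(self):
        net = nx.Graph()
        net.add_edge("a", "b")
        with pytest.raises(ValueError, match="attach_edges"):
            mn.add_nodes(net, 1, attach_edges=5)


class TestAdditionStats:
    def _traces(self, diffs_lcc, baseline):
        base_lcc = max(len(c) for c in nx.connected_components(baseline))
        traces = []
        for d in diffs_lcc:
            t = mn.AdditionTrace(k_added=1)
            t.lcc_size = [int(base_lcc + d)]
            t.apl = [mn.apl(baseline)]
            traces.append(t)
        return traces

    def test_all_zero_differences_give_p_one(self):
        net = mn.make_fixture_graph("complete", 4)
        stats = mn.addition_stats({1: self._traces([0] * 6, net)}, net)
        assert (stats["p_value"] == 1.0).all()

    def test_six_positive_differences_exact_p(self):
        # signed-rank with all-positive (1..6): two-sided exact p = 2/64
        net = mn.make_fixture_graph("complete", 4)
        stats = mn.addition_stats({1: self._traces([1, 2, 3, 4, 5, 6], net)}, net)
        row = stats[stats["metric"] == "lcc"].iloc[0]
        assert row["p_value"] == pytest.approx(2 / 64)

    def test_too_few_replicates_rejected(self):
        net = mn.make_fixture_graph("complete", 4)
        with pytest.raises(ValueError, match="5 replicates"):
            mn.addition_stats({1: self._traces([1, 2], net)}, net)


class TestBattery:
    def test_report_schema_and_attack_rows(self):
        nets = {
            "g1": mn.make_fixture_graph("barabasi_albert", 25, param=2, seed=4),
            "g2": mn.make_fixture_graph("erdos_renyi", 25, param=0.2, seed=5),
        }
        removal, traces, stats = mn.robustness_battery(
            nets, k_values=(5, 10), n_reps=5, n_boot=10, seed=6
        )
        assert len(removal) == 8  # 4 strategies per network
        assert set(removal["strategy"]) == set(STRATEGIES)
        assert set(removal["network"]) == {"g1", "g2"}
        assert ((removal["fraction_at_target"] > 0) & (removal["fraction_at_target"] <= 1)).all()
        assert len(traces) == 2 * 5 * (5 + 10)  # networks x reps x total iterations
        assert set(stats["metric"]) == {"lcc", "apl"}
        assert (stats["q_value"] >= stats["p_value"] - 1e-12).all()

    def test_denser_networks_resist_cascading_attack_better(self):
        """Removing half the edges of a random graph (same node set) makes
        it easier to dismantle: the cascading removal fraction of the dense
        graph is at least that of its sparser subgraph in >= 80% of trials."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dense = mn.make_fixture_graph("erdos_renyi", 40, param=0.3, seed=seed)
            edges = sorted(dense.edges)
            drop = rng.choice(len(edges), size=len(edges) // 2, replace=False)
            sparse = dense.copy()
            sparse.remove_edges_from([edges[i] for i in drop])
            sparse.remove_nodes_from(list(nx.isolates(sparse)))
            fd = mn.attack(dense, "cascading").fraction_at_target
            fs = mn.attack(sparse, "cascading").fraction_at_target
            wins += fd >= fs
        assert wins >= 16

    def test_battery_deterministic(self):
        nets = {"g": mn.make_fixture_graph("barabasi_albert", 20, param=2, seed=7)}
        r1, t1, s1 = mn.robustness_battery(nets, k_values=(5,), n_reps=5, n_boot=5, seed=8)
        r2, t2, s2 = mn.robustness_battery(nets, k_values=(5,), n_reps=5, n_boot=5, seed=8)
        assert r1.equals(r2) and t1.equals(t2) and s1.equals(s2)
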
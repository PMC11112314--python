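"""Network robustness to node removal and node addition.

Colonization resistance is operationalized as graph robustness: how much of
the network's connectivity survives targeted or random node removal, and
how the largest connected component (LCC) and average path length (APL)
respond when new nodes attach to the existing community.

Connectivity loss after removing a node set is 1 - R/R0, where R0 counts
ordered node pairs mutually reachable in the original graph and R counts
reachable pairs among the survivors (removed nodes contribute full loss).
Four attack strategies are simulated: random order, descending degree
(computed once), descending betweenness (computed once), and cascading
(betweenness recomputed on the surviving graph before every removal).  The
headline statistic is the fraction of nodes that must be removed before
loss first reaches a target (0.80 by default).

Betweenness, components and path lengths inside the simulation loops run
through igraph for speed; graphs are networkx objects at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

__all__ = [
    "AttackCurve",
    "AdditionTrace",
    "connectivity_loss",
    "attack",
    "random_attack_ci",
    "apl",
    "add_nodes",
    "addition_stats",
    "robustness_battery",
]

STRATEGIES = ("random", "degree", "betweenness", "cascading")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(net.nodes)
    index = {v: k for k, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in net.edges])
    return g, nodes

def _reachable_pairs(component_sizes) -> int:
    return int(sum(s * (s - 1) for s in component_sizes))

def _betweenness(net: nx.Graph) -> dict:
    g, nodes = _to_igraph(net)
    return dict(zip(nodes, g.betweenness()))


# ---------------------------------------------------------------------------
# node removal
# ---------------------------------------------------------------------------

def connectivity_loss(original: nx.Graph, removed) -> float:
    """Fraction of originally reachable ordered pairs lost after removal."""
    removed = set(removed)
    extra = removed - set(original.nodes)
    if extra:
        raise ValueError(f"removed nodes not in graph: {sorted(extra)[:5]}")
    r0 = _reachable_pairs(len(c) for c in nx.connected_components(original))
    if r0 == 0:
        return 0.0
    survivors = original.subgraph(set(original.nodes) - removed)
    r = _reachable_pairs(len(c) for c in nx.connected_components(survivors))
    return 1.0 - r / r0


@dataclass
class AttackCurve:
    """Removal sequence and the connectivity-loss trajectory it causes."""

    strategy: str
    removal_order: list
    loss_at_step: list[float]
    target: float
    n_original: int

    @property
    def fraction_at_target(self) -> float:
        """Removed-node fraction at which loss first reaches the target."""
        for k, loss in enumerate(self.loss_at_step, start=1):
            if loss >= self.target - 1e-12:
                return k / self.n_original
        return 1.0


def attack(net: nx.Graph, strategy: str, target: float = 0.80, seed: int = 0) -> AttackCurve:
    """Remove all nodes one by one under a strategy, tracking loss.

    Ties in degree/betweenness are broken by lexicographic node id for
    determinism.  The curve always runs to full removal (final loss 1).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")

    nodes = sorted(net.nodes)
    n = len(nodes)
    g, ignodes = _to_igraph(net)
    r0 = _reachable_pairs(g.connected_components().sizes())

    if strategy == "random":
        rng = np.random.default_rng(seed)
        order = [nodes[i] for i in rng.permutation(n)]
    elif strategy == "degree":
        deg = dict(net.degree())
        order = sorted(nodes, key=lambda v: (-deg[v], v))
    elif strategy == "betweenness":
        bet = _betweenness(net)
        order = sorted(nodes, key=lambda v: (-bet[v], v))
    else:
        order = None  # cascading: chosen step by step

    # igraph working copy; vertex names track identity through deletions
    g.vs["name"] = [str(v) for v in ignodes]
    name_of = {str(v): v for v in ignodes}

    losses: list[float] = []
    removal: list = []
    for step in range(n):
        if strategy == "cascading":
            if g.vcount() == 0:
                break
            bet = g.betweenness()
            names = g.vs["name"]
            best = min(range(g.vcount()), key=lambda k: (-bet[k], names[k]))
            victim_name = names[best]
            victim = name_of[victim_name]
        else:
            victim = order[step]
            victim_name = str(victim)
        g.delete_vertices(g.vs.find(name=victim_name).index)
        removal.append(victim)
        r = _reachable_pairs(g.connected_components().sizes()) if g.vcount() else 0
        losses.append(1.0 - r / r0 if r0 else 1.0)
    return AttackCurve(strategy, removal, losses, target, n)


def random_attack_ci(
    net: nx.Graph, target: float = 0.80, n_boot: int = 100, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Mean fraction-at-target over independent random attacks, with a
    percentile bootstrap 95% interval."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(n_boot, dtype=np.uint32)
    fracs = np.array([
        attack(net, "random", target=target, seed=int(s)).fraction_at_target
        for s in seeds
    ])
    lo, hi = np.percentile(fracs, [2.5, 97.5])
    return float(fracs.mean()), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# node addition
# ---------------------------------------------------------------------------

def apl(net: nx.Graph) -> float:
    """Mean unweighted shortest-path length over mutually reachable ordered
    pairs; NaN when no connected pair exists."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    g, _ = _to_igraph(net)
    return _apl_ig(g)


def _apl_ig(g: ig.Graph) -> float:
    if g.vcount() < 2 or g.ecount() == 0:
        return float("nan")
    val = g.average_path_length(directed=False, unconn=True)
    return float(val) if val is not None else float("nan")


@dataclass
class AdditionTrace:
    """Per-iteration LCC size and APL while k nodes are added."""

    k_added: int
    lcc_size: list[int] = field(default_factory=list)
    apl: list[float] = field(default_factory=list)
    seed: int = 0


def add_nodes(
    net: nx.Graph,
    k: int,
    attach_edges: int = 1,
    rule: str = "uniform",
    seed: int = 0,
) -> tuple[nx.Graph, AdditionTrace]:
    """Grow the network by k new nodes, tracking LCC and APL per addition.

    Each new node attaches by ``attach_edges`` unit-weight edges to
    distinct existing nodes chosen uniformly (default) or by degree-
    preferential sampling; previously added nodes are eligible targets.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if attach_edges < 1:
        raise ValueError("attach_edges must be >= 1")
    if net.number_of_nodes() == 0:
        raise ValueError("net must be nonempty")
    if attach_edges > net.number_of_nodes():
        raise ValueError("attach_edges exceeds current node count")
    if rule not in ("uniform", "preferential"):
        raise ValueError(f"unknown attachment rule {rule!r}")

    rng = np.random.default_rng(seed)
    g, nodes = _to_igraph(net)
    objs = list(nodes)  # igraph vertex index -> node object in the nx graph
    trace = AdditionTrace(k_added=k, seed=seed)

    grown = net.copy()
    for step in range(k):
        cur_n = g.vcount()
        if rule == "uniform":
            targets = rng.choice(cur_n, size=attach_edges, replace=False)
        else:
            deg = np.asarray(g.degree(), dtype=float) + 1.0  # +1 keeps isolates reachable
            p = deg / deg.sum()
            targets = rng.choice(cur_n, size=attach_edges, replace=False, p=p)
        new_name = f"added{step:04d}"
        g.add_vertex()
        g.add_edges([(cur_n, int(t)) for t in targets])
        grown.add_node(new_name)
        for t in targets:
            grown.add_edge(new_name, objs[t], weight=1.0, absweight=1.0, sign=1)
        objs.append(new_name)
        trace.lcc_size.append(max(g.connected_components().sizes()))
        trace.apl.append(_apl_ig(g))
    return grown, trace


def addition_stats(
    traces_by_k: dict[int, list[AdditionTrace]],
    baseline: nx.Graph,
) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of post-addition change in LCC and APL.

    For every k, per-replicate differences (final metric minus the
    un-grown network's metric) are tested against a zero median with an
    exact signed-rank test (normal approximation above n = 25); p-values
    are BH-adjusted across the whole (k, metric) family.  All-zero
    difference vectors get p = 1 by convention.
    """
    base_lcc = max(len(c) for c in nx.connected_components(baseline))
    base_apl = apl(baseline)

    rows = []
    for k in sorted(traces_by_k):
        traces = traces_by_k[k]
        if len(traces) < 5:
            raise ValueError("need at least 5 replicates per k")
        lcc_diff = np.array([t.lcc_size[-1] - base_lcc for t in traces], dtype=float)
        apl_diff = np.array([t.apl[-1] - base_apl for t in traces], dtype=float)
        for metric, diffs in [("lcc", lcc_diff), ("apl", apl_diff)]:
            rows.append({
                "k": k, "metric": metric,
                "diff_mean": float(np.mean(diffs)),
                "p_value": _wilcoxon_p(diffs),
            })
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def _wilcoxon_p(diffs: np.ndarray) -> float:
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    return float(stats.wilcoxon(nz, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def robustness_battery(
    nets: dict[str, nx.Graph],
    target: float = 0.80,
    n_boot: int = 100,
    k_values: tuple[int, ...] = (100, 300, 500, 700, 1000),
    n_reps: int = 5,
    attach_edges: int = 1,
    rule: str = "uniform",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Removal and addition robustness for a set of named networks.

    Returns (removal_table, addition_traces, addition_stats): the removal
    table has one row per network and strategy with the fraction of nodes
    removed to reach the loss target (random rows carry a bootstrap mean
    and 95% CI); addition traces are long-form per (network, k, replicate,
    iteration); addition stats hold the signed-rank results.
    """
    root = np.random.SeedSequence(seed)
    removal_rows, trace_rows, stat_frames = [], [], []
    for name in sorted(nets):
        net = nets[name]
        sub = root.spawn(1)[0]
        s_removal, s_add = (int(s) for s in sub.generate_state(2, dtype=np.uint32))
        for strategy in ("cascading", "betweenness", "degree"):
            curve = attack(net, strategy, target=target)
            removal_rows.append({
                "network": name, "strategy": strategy,
                "fraction_at_target": curve.fraction_at_target,
                "ci_low": np.nan, "ci_high": np.nan,
            })
        mean, (lo, hi) = random_attack_ci(net, target=target, n_boot=n_boot, seed=s_removal)
        removal_rows.append({
            "network": name, "strategy": "random",
            "fraction_at_target": mean, "ci_low": lo, "ci_high": hi,
        })

        traces_by_k: dict[int, list[AdditionTrace]] = {}
        add_seeds = np.random.SeedSequence(s_add).generate_state(
            len(k_values) * n_reps, dtype=np.uint32
        )
        idx = 0
        for k in k_values:
            traces_by_k[k] = []
            for rep in range(n_reps):
                _, tr = add_nodes(net, k, attach_edges=attach_edges, rule=rule,
                                  seed=int(add_seeds[idx]))
                idx += 1
                traces_by_k[k].append(tr)
                for it, (l, a) in enumerate(zip(tr.lcc_size, tr.apl), start=1):
                    trace_rows.append({
                        "network": name, "k": k, "replicate": rep,
                        "iteration": it, "lcc": l, "apl": a,
                    })
        st = addition_stats(traces_by_k, net)
        st.insert(0, "network", name)
        stat_frames.append(st)

    removal = pd.DataFrame(removal_rows)
    traces = pd.DataFrame(trace_rows)
    statdf = pd.concat(stat_frames, ignore_index=True) if stat_frames else pd.DataFrame()
    return removal, traces, statdf
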
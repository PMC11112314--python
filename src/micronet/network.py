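"""Thresholded signed co-occurrence networks, topology, and keystone taxa.

A co-occurrence network keeps every taxon pair whose SparCC correlation
magnitude exceeds a threshold (0.75 by default; 0.95 for the "core"
network).  Edges carry the signed correlation as ``weight`` plus its
absolute value and sign; isolated taxa are dropped.  Topology metrics
(modularity via Louvain, diameter, degree statistics, clustering) and the
three-criterion keystone classification (ubiquity, mean clr abundance,
eigenvector centrality) operate on these graphs.  Community detection and
centralities use absolute weights or unweighted structure — signed weights
enter only through edge attributes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ClrMatrix
from .sparcc import CorrelationMatrix
from .table import AbundanceTable

__all__ = [
    "TopologyReport",
    "build_network",
    "core_network",
    "topology_summary",
    "eigenvector_centrality",
    "ubiquity",
    "keystone_taxa",
    "write_graph",
]


def build_network(rho: CorrelationMatrix, threshold: float = 0.75) -> nx.Graph:
    """Signed graph of taxa with |rho| strictly above ``threshold``.

    Only taxa with at least one retained edge appear as nodes.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    G = nx.Graph(threshold=threshold)
    taxa = rho.taxon_ids
    R = rho.rho
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = R[i, j]
            if abs(r) > threshold:
                G.add_edge(
                    taxa[i], taxa[j],
                    weight=float(r), absweight=float(abs(r)),
                    sign=1 if r > 0 else -1,
                )
    return G


def core_network(rho: CorrelationMatrix) -> nx.Graph:
    """Core network at the stricter |rho| > 0.95 cutoff."""
    return build_network(rho, threshold=0.95)


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    modularity: float
    n_modules: int
    diameter: int
    avg_degree: float
    weighted_degree: float
    clustering_coefficient: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _module_assignment(G: nx.Graph, seed: int = 0, resolution: float = 1.0):
    comms = nx.community.louvain_communities(
        G, weight="absweight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    return comms


def topology_summary(net: nx.Graph, seed: int = 0) -> TopologyReport:
    """Node/edge counts, Louvain modularity, diameter of the largest
    component (unweighted hops), mean degree, mean absolute-weighted degree,
    and mean local clustering (unweighted, unsigned)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)

    comms = _module_assignment(net, seed=seed)
    modularity = nx.community.modularity(net, comms, weight="absweight")

    comps = list(nx.connected_components(net))
    lcc_size = max(len(c) for c in comps)
    # ties between equal-size largest components resolve to the widest one
    diameter = max(
        nx.diameter(net.subgraph(c)) if len(c) > 1 else 0
        for c in comps if len(c) == lcc_size
    )

    wdeg = [sum(d["absweight"] for _, _, d in net.edges(v, data=True)) for v in net]
    return TopologyReport(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_pos,
        n_negative=n_edges - n_pos,
        modularity=float(modularity),
        n_modules=len(comms),
        diameter=int(diameter),
        avg_degree=2.0 * n_edges / n_nodes,
        weighted_degree=float(np.mean(wdeg)),
        clustering_coefficient=float(nx.average_clustering(net)),
    )


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Leading eigenvector of the |weight| adjacency, max-normalized to 1.

    Power iteration runs on A + I (the shift leaves eigenvectors of A
    unchanged but guarantees convergence on bipartite graphs, where plain
    iteration oscillates).  On disconnected graphs the vector localizes on
    the dominant component and other components receive ~0, matching the
    Gephi convention of a whole-graph computation.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    index = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, d in net.edges(data=True):
        w = d.get("absweight", abs(d.get("weight", 1.0)))
        A[index[u], index[v]] = A[index[v], index[u]] = w
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        x_new = A @ x + x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            break
        x_new /= norm
        if np.abs(x_new - x).sum() < n * tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(f"eigenvector centrality did not converge in {max_iter} iterations")
    x = np.abs(x)
    x /= x.max()
    return {v: float(x[index[v]]) for v in nodes}


def ubiquity(table: AbundanceTable, group: str, timepoint: str | None = None) -> set[str]:
    """Taxa present (count > 0) in every sample of the condition."""
    sub = table.group_samples(group, timepoint)
    pres = (sub.counts > 0).all(axis=0)
    return set(pres.index[pres])


def keystone_taxa(
    net: nx.Graph,
    clr: ClrMatrix,
    table: AbundanceTable,
    group: str,
    timepoint: str | None = None,
    abund_cut: float = 0.35,
    eig_cut: float = 0.75,
) -> pd.DataFrame:
    """Three-criterion keystone classification of network taxa.

    A taxon is keystone iff it is ubiquitous in the condition, its mean clr
    abundance over the condition's samples is >= ``abund_cut``, and its
    eigenvector centrality in the network is >= ``eig_cut`` (both cutoffs
    inclusive).  Returns a per-taxon report.
    """
    missing = [v for v in net.nodes if v not in clr.taxon_ids]
    if missing:
        raise ValueError(f"network nodes missing from clr matrix: {missing[:5]}")
    sub = table.group_samples(group, timepoint)
    ubiq = ubiquity(table, group, timepoint)
    eig = eigenvector_centrality(net)
    mean_clr = clr.mean_by_samples(sub.sample_ids)

    rows = []
    tol = 1e-9  # cutoffs are inclusive; guard against rounding at the boundary
    for v in sorted(net.nodes):
        m = float(mean_clr[v])
        e = eig[v]
        u = v in ubiq
        rows.append(
            {
                "taxon_id": v,
                "mean_clr": m,
                "eigenvector": e,
                "ubiquitous": u,
                "is_keystone": bool(u and m >= abund_cut - tol and e >= eig_cut - tol),
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def write_graph(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Export as GraphML or GEXF with node/edge attributes intact."""
    G = net.copy()
    if G.graph.get("threshold") is None:
        G.graph.pop("threshold", None)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
        # strip the embedded modification date so identical runs produce
        # byte-identical artifacts
        text = Path(path).read_text()
        Path(path).write_text(re.sub(r' lastmodifieddate="[^"]*"', "", text))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
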
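"""Synthetic compositional count tables with planted correlation structure.

Every downstream stage of the pipeline (contaminant flagging, SparCC,
network topology, robustness simulation) is exercised against data from this
module, so its generative model matches the assumptions the inference makes:
per-sample *basis* log-abundances are drawn from a multivariate normal whose
correlation matrix carries a known, modular, signed edge structure; the
basis abundances are closed to fractions (softmax) and observed as
multinomial read counts at a sequencing depth drawn per sample — the
logistic-normal–multinomial model.

The planted structure is remembered in a :class:`GroundTruthNetwork` so that
tests can score sign/magnitude recovery of the inferred networks.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .table import AbundanceTable

__all__ = [
    "GroundTruthNetwork",
    "SimConfig",
    "make_basis_network",
    "simulate_counts",
    "spike_contaminants",
    "make_fixture_graph",
]


@dataclass
class GroundTruthNetwork:
    """Planted basis-correlation structure.

    ``basis_corr`` is a valid (positive semidefinite, unit-diagonal)
    correlation matrix; ``edge_sign`` records the sign of every planted
    edge, keyed by unordered taxon pair.
    """

    taxa: list[str]
    basis_corr: np.ndarray
    module_of: dict[str, int]
    edge_sign: dict[tuple[str, str], int]

    def planted_edges(self) -> list[tuple[str, str, int]]:
        return [(i, j, s) for (i, j), s in sorted(self.edge_sign.items())]

    def validate(self) -> None:
        C = self.basis_corr
        if not np.allclose(C, C.T):
            raise ValueError("basis_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("basis_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("basis_corr must be positive semidefinite")
        if set(self.module_of) != set(self.taxa):
            raise ValueError("module_of must cover all taxa")

    def to_json(self, path) -> None:
        doc = {
            "taxa": self.taxa,
            "basis_corr": np.round(self.basis_corr, 12).tolist(),
            "module_of": self.module_of,
            "edges": [[i, j, s] for (i, j), s in sorted(self.edge_sign.items())],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthNetwork":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            taxa=doc["taxa"],
            basis_corr=np.asarray(doc["basis_corr"]),
            module_of=doc["module_of"],
            edge_sign={(i, j): int(s) for i, j, s in doc["edges"]},
        )


@dataclass
class SimConfig:
    """Parameters of one synthetic study arm.

    Defaults emulate a genus-collapsed 16S V4 count table: ~30 genera in 3
    co-occurrence modules, sparse strong planted correlations (|rho| = 0.8,
    ~30% negative), mean depth 20k reads with moderate overdispersion, four
    water-template extraction controls carrying a handful of low-abundance
    contaminant genera.
    """

    n_taxa: int = 30
    n_samples_per_group: int = 8
    groups: list[str] = field(default_factory=lambda: ["control", "cancer"])
    depth: int = 20000
    depth_dispersion: float = 0.2
    logmean_range: tuple[float, float] = (0.0, 3.0)
    n_modules: int = 3
    p_within: float = 0.1
    p_between: float = 0.01
    corr_strength: float = 0.8
    neg_frac: float = 0.3
    n_contaminants: int = 3
    n_controls: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("SparCC unidentifiable below 4 taxa")
        if not (0 < self.corr_strength < 1):
            raise ValueError("corr_strength must be in (0, 1)")
        for name in ("p_within", "p_between", "neg_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 1 or self.depth_dispersion < 0:
            raise ValueError("depth >= 1 and depth_dispersion >= 0 required")


# ---------------------------------------------------------------------------
# basis network construction
# ---------------------------------------------------------------------------

def _psd_repair(X: np.ndarray, anchors: np.ndarray | None = None,
                mask: np.ndarray | None = None, max_iter: int = 2000) -> np.ndarray:
    """Project to the PSD correlation cone by eigenvalue clipping + rescale.

    When an anchor mask is given, the clip-and-rescale step is alternated
    with restoration of the anchored (planted) entries so that feasible
    planted targets are preserved instead of uniformly shrunk; the final
    pass is always a plain clip-and-rescale, so the result is PSD up to
    floating-point error.
    """
    X = X.copy()
    for _ in range(max_iter):
        w, V = np.linalg.eigh(X)
        if w.min() > -1e-12:
            break
        X = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(X), 1e-12, None))
        X = X / np.outer(d, d)
        if mask is not None:
            X[mask] = anchors[mask]
        np.fill_diagonal(X, 1.0)
    w, V = np.linalg.eigh(X)
    if w.min() < 0:
        X = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(X), 1e-12, None))
        X = X / np.outer(d, d)
        np.fill_diagonal(X, 1.0)
    return (X + X.T) / 2


def make_basis_network(
    n_taxa: int,
    n_modules: int,
    p_within: float,
    p_between: float,
    neg_frac: float = 0.0,
    corr_strength: float = 0.8,
    seed: int = 0,
    taxa: list[str] | None = None,
) -> GroundTruthNetwork:
    """Plant a modular signed correlation structure over ``n_taxa`` taxa.

    Taxa are split into ``n_modules`` near-equal modules; candidate edges
    are drawn independently with probability ``p_within`` inside a module
    and ``p_between`` across modules.  Edge signs derive from latent
    per-taxon polarities (sign of an edge = product of its endpoint
    polarities), with the polarity-flip rate calibrated so that the
    expected fraction of negative planted edges equals ``neg_frac``;
    balanced signs keep correlation targets of magnitude ``corr_strength``
    jointly satisfiable.  Unplanted entries are filled by distance decay
    (corr_strength ** path length within a planted component) and the
    matrix is repaired to the PSD correlation cone.

    Deterministic given ``seed``.
    """
    if n_taxa < 4:
        raise ValueError("SparCC unidentifiable below 4 taxa")
    if not (1 <= n_modules <= n_taxa):
        raise ValueError("n_modules must be in [1, n_taxa]")
    for name, v in [("p_within", p_within), ("p_between", p_between), ("neg_frac", neg_frac)]:
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if not (0 < corr_strength < 1):
        raise ValueError("corr_strength must be in (0, 1)")
    if neg_frac > 0.5:
        raise ValueError("neg_frac above 0.5 is not representable with balanced signs")

    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"g{i:03d}" for i in range(n_taxa)]
    module = np.array([i * n_modules // n_taxa for i in range(n_taxa)])

    # polarity flip rate q with 2 q (1-q) = neg_frac
    q = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * neg_frac)) if neg_frac > 0 else 0.0
    polarity = np.where(rng.random(n_taxa) < q, -1, 1)

    G = nx.Graph()
    G.add_nodes_from(range(n_taxa))
    edge_sign: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(n_taxa), 2):
        p = p_within if module[i] == module[j] else p_between
        if rng.random() < p:
            s = int(polarity[i] * polarity[j])
            G.add_edge(i, j)
            edge_sign[(taxa[i], taxa[j])] = s

    # distance-decay completion within planted components (PSD on trees,
    # near-PSD on balanced graphs), then anchored PSD repair
    C = np.eye(n_taxa)
    mask = np.zeros((n_taxa, n_taxa), dtype=bool)
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        dist = dict(nx.all_pairs_shortest_path_length(G.subgraph(comp)))
        for a, b in itertools.combinations(comp, 2):
            val = polarity[a] * polarity[b] * corr_strength ** dist[a][b]
            C[a, b] = C[b, a] = val
    for a, b in G.edges:
        mask[a, b] = mask[b, a] = True
    C = _psd_repair(C, anchors=C.copy(), mask=mask)

    gt = GroundTruthNetwork(
        taxa=list(taxa),
        basis_corr=C,
        module_of={t: int(m) for t, m in zip(taxa, module)},
        edge_sign=edge_sign,
    )
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    gt: GroundTruthNetwork,
    n_samples: int,
    depth: int = 20000,
    depth_dispersion: float = 0.0,
    logmean_range: tuple[float, float] = (0.0, 3.0),
    seed: int = 0,
    sample_prefix: str = "s",
    group: str = "all",
    timepoint: str = "all",
) -> AbundanceTable:
    """Draw logistic-normal–multinomial counts under a planted basis.

    Per sample: basis log-abundances ~ MVN(mu, gt.basis_corr) with unit
    per-taxon variances and per-taxon means uniform over ``logmean_range``;
    softmax to fractions; depth ~ negative binomial around ``depth``
    (exactly ``depth`` when ``depth_dispersion`` is 0); counts multinomial.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    C = gt.basis_corr
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-8:
        raise ValueError("gt.basis_corr is not positive semidefinite")

    rng = np.random.default_rng(seed)
    n_taxa = len(gt.taxa)
    mu = rng.uniform(logmean_range[0], logmean_range[1], size=n_taxa)
    # eigendecomposition square root tolerates exactly-singular matrices
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0, None))
    Z = rng.standard_normal((n_samples, n_taxa)) @ L.T + mu

    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)

    if depth_dispersion > 0:
        r = 1.0 / depth_dispersion
        depths = rng.negative_binomial(r, r / (r + depth), size=n_samples)
        depths = np.maximum(depths, 1)
    else:
        depths = np.full(n_samples, depth)

    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, P)])
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    df = pd.DataFrame(counts, index=sample_ids, columns=gt.taxa)
    meta = pd.DataFrame(
        {"group": group, "timepoint": timepoint, "is_control": False},
        index=sample_ids,
    )
    return AbundanceTable(df, meta)


def spike_contaminants(
    table: AbundanceTable,
    n_contaminants: int,
    n_controls: int,
    prevalence_in_controls: float = 1.0,
    prevalence_in_samples: float = 0.1,
    seed: int = 0,
) -> tuple[AbundanceTable, list[str]]:
    """Append negative-control samples dominated by contaminant taxa.

    New contaminant taxa are added to the table; they appear in a fraction
    ``prevalence_in_controls`` of the appended controls (at high counts —
    controls carry little but reagent DNA) and in ``prevalence_in_samples``
    of true samples at trace level (1–20 reads, mimicking carry-over).
    Returns the augmented table and the contaminant taxon ids for oracles.
    """
    for name, v in [("prevalence_in_controls", prevalence_in_controls),
                    ("prevalence_in_samples", prevalence_in_samples)]:
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("table must be nonempty")
    if n_contaminants > 0 and n_controls == 0:
        raise ValueError("contaminants require at least one negative control")
    if n_contaminants == 0 and n_controls == 0:
        return table, []

    rng = np.random.default_rng(seed)
    contam_ids = [f"contam{i:02d}" for i in range(n_contaminants)]

    counts = table.counts.copy()
    for cid in contam_ids:
        present = rng.random(table.n_samples) < prevalence_in_samples
        counts[cid] = np.where(present, rng.integers(1, 21, size=table.n_samples), 0)

    ctrl_ids = [f"ctrl{i:02d}" for i in range(n_controls)]
    ctrl = pd.DataFrame(0, index=ctrl_ids, columns=counts.columns)
    for cid in contam_ids:
        present = rng.random(n_controls) < prevalence_in_controls
        ctrl[cid] = np.where(present, rng.integers(200, 2001, size=n_controls), 0)

    all_counts = pd.concat([counts, ctrl])
    ctrl_meta = pd.DataFrame(
        {"group": "control_blank", "timepoint": "none", "is_control": True},
        index=ctrl_ids,
    )
    meta = pd.concat([table.metadata, ctrl_meta])
    return AbundanceTable(all_counts, meta), contam_ids


# ---------------------------------------------------------------------------
# fixture graphs
# ---------------------------------------------------------------------------

_FIXTURES = {"star", "path", "complete", "erdos_renyi", "barabasi_albert", "barbell"}


def make_fixture_graph(model: str, n: int, param=None, seed: int = 0) -> nx.Graph:
    """Named test graph with unit positive edge weights.

    ``param`` is the edge probability for ``erdos_renyi``, the number of
    attachment edges m for ``barabasi_albert``, and the path length for
    ``barbell``; it is ignored for the deterministic models.
    """
    if model not in _FIXTURES:
        raise ValueError(f"unknown fixture model {model!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if model == "star":
        G = nx.star_graph(n - 1)
    elif model == "path":
        G = nx.path_graph(n)
    elif model == "complete":
        G = nx.complete_graph(n)
    elif model == "erdos_renyi":
        G = nx.gnp_random_graph(n, 0.1 if param is None else param, seed=seed)
    elif model == "barabasi_albert":
        G = nx.barabasi_albert_graph(n, 2 if param is None else int(param), seed=seed)
    else:  # barbell
        G = nx.barbell_graph(n, 0 if param is None else int(param))
    H = nx.Graph()
    H.add_nodes_from(f"n{v}" for v in G.nodes)
    H.add_edges_from((f"n{u}", f"n{v}", {"weight": 1.0, "absweight": 1.0, "sign": 1})
                     for u, v in G.edges)
    H.graph["threshold"] = None
    return H


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

def default_group_sizes(
    config: SimConfig, timepoints: tuple[str, str] = ("16dpi", "22dpi")
) -> dict[tuple[str, str], int]:
    """Default study design.

    For the control/cancer design this is the emulated study's arm sizes —
    7 and 7 control samples at 16/22 dpi, 9 and 8 tumor-bearing samples —
    otherwise ``n_samples_per_group`` in every (group, timepoint) cell.
    """
    if sorted(config.groups) == ["cancer", "control"] and timepoints == ("16dpi", "22dpi"):
        return {
            ("control", "16dpi"): 7,
            ("cancer", "16dpi"): 9,
            ("control", "22dpi"): 7,
            ("cancer", "22dpi"): 8,
        }
    return {(g, t): config.n_samples_per_group for g in config.groups for t in timepoints}


def simulate_study(
    config: SimConfig,
    group_sizes: dict[tuple[str, str], int] | None = None,
    timepoints: tuple[str, str] = ("16dpi", "22dpi"),
) -> tuple[AbundanceTable, dict[tuple[str, str], GroundTruthNetwork], list[str]]:
    """Generate a full multi-group study table.

    Each (group, timepoint) cell gets its own planted basis network over a
    shared taxon set (different seeds -> group-specific structure, as the
    per-condition co-occurrence networks differ in the system this
    emulates), then contaminants and negative controls are spiked in.

    Returns the combined table, per-cell ground truths, and contaminant ids.
    """
    if group_sizes is None:
        group_sizes = default_group_sizes(config, timepoints)

    root = np.random.SeedSequence(config.seed)
    cells = sorted(group_sizes)
    seeds = root.generate_state(2 * len(cells) + 1, dtype=np.uint32)

    tables, truths = [], {}
    for k, (g, t) in enumerate(cells):
        gt = make_basis_network(
            config.n_taxa, config.n_modules, config.p_within, config.p_between,
            config.neg_frac, config.corr_strength, seed=int(seeds[2 * k]),
        )
        tab = simulate_counts(
            gt, group_sizes[(g, t)], config.depth, config.depth_dispersion,
            config.logmean_range, seed=int(seeds[2 * k + 1]),
            sample_prefix=f"{g}_{t}_", group=g, timepoint=t,
        )
        truths[(g, t)] = gt
        tables.append(tab)

    combined = AbundanceTable(
        pd.concat([t.counts for t in tables]),
        pd.concat([t.metadata for t in tables]),
    )
    combined, contam_ids = spike_contaminants(
        combined, config.n_contaminants, config.n_controls,
        prevalence_in_controls=1.0, prevalence_in_samples=0.1,
        seed=int(seeds[-1]),
    )
    return combined, truths, contam_ids
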
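"""End-to-end orchestration: counts in, networks and reports out.

``run_pipeline`` strings the stages together the way the analysis is meant
to be run: contaminant flagging against negative controls, removal of
flagged taxa, low-abundance filtering, then per (group x timepoint) cell:
clr transform, diversity (rarefaction, observed features, Jaccard +
PERMANOVA across cells), SparCC, thresholded and core networks, topology,
keystone taxa, and the robustness battery; plus pairwise differential
abundance between cells.  All randomness derives from one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .table import AbundanceTable
from .synthgen import SimConfig, simulate_study
from .preprocess import clr_transform, diff_abundance, filter_low_abundance, flag_contaminants
from .diversity import jaccard_matrix, observed_features, permanova, rarefy
from .sparcc import sparcc
from .network import build_network, core_network, keystone_taxa, topology_summary, write_graph
from .robustness import robustness_battery

logger = logging.getLogger("micronet")

__all__ = ["PipelineConfig", "run_pipeline", "compare_networks"]


@dataclass
class PipelineConfig:
    """All thresholds and settings of one pipeline run."""

    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    biom_json: str | None = None
    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    contaminant_score: float = 0.1
    min_total_reads: int = 10
    min_prevalence: float = 0.30
    edge_threshold: float = 0.75
    core_threshold: float = 0.95
    keystone_abund_cut: float = 0.35
    keystone_eig_cut: float = 0.75
    loss_target: float = 0.80

    sparcc_resamples: int = 20
    sparcc_exclusion_threshold: float = 0.1
    sparcc_max_rounds: int = 10

    n_boot: int = 100
    k_values: tuple[int, ...] = (100, 300, 500, 700, 1000)
    n_reps: int = 5
    attach_edges: int = 1
    attach_rule: str = "uniform"
    n_perm: int = 999
    n_mc_instances: int = 128

    seed: int = 0
    outdir: str = "micronet_out"

    def validate(self) -> None:
        for name, lo, hi in [
            ("contaminant_score", 0, 1), ("min_prevalence", 0, 1),
            ("edge_threshold", 0, 1), ("core_threshold", 0, 1),
            ("loss_target", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config field {name}={v} outside [{lo}, {hi}]")
        if not (0 < self.edge_threshold < 1):
            raise ValueError(f"config field edge_threshold={self.edge_threshold} outside (0, 1)")
        if self.attach_rule not in ("uniform", "preferential"):
            raise ValueError(f"config field attach_rule={self.attach_rule!r} unknown")
        if not self.synthetic and self.counts_tsv is None and self.biom_json is None:
            raise ValueError("config needs counts_tsv or biom_json when synthetic is false")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["sim"] = asdict(self.sim)
        doc["k_values"] = list(self.k_values)
        doc["sim"]["logmean_range"] = list(self.sim.logmean_range)
        doc["sim"]["groups"] = list(self.sim.groups)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sim = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim is not None:
            sim["logmean_range"] = tuple(sim["logmean_range"])
            cfg.sim = SimConfig(**sim)
        cfg.k_values = tuple(cfg.k_values)
        return cfg

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        doc = asdict(self)
        doc["sim"] = asdict(self.sim)
        doc.pop("outdir")
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_table(config: PipelineConfig) -> AbundanceTable:
    if config.synthetic:
        table, _, _ = simulate_study(config.sim)
        return table
    if config.biom_json:
        return AbundanceTable.from_biom_json(config.biom_json)
    return AbundanceTable.from_tsv(config.counts_tsv, config.metadata_tsv)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ["rarefy", "sparcc", "diversity", "diffabund", "robustness", "louvain"],
            root.generate_state(6, dtype=np.uint32),
        )
    }

    table = _load_table(config)
    table.to_tsv(outdir / "counts_raw.tsv", outdir / "metadata.tsv")
    logger.info("input table: %d samples x %d taxa", table.n_samples, table.n_taxa)

    # contaminant removal (only when controls are present)
    if table.metadata["is_control"].any():
        flagged = flag_contaminants(table, config.contaminant_score)
        logger.info("flagged %d contaminant taxa: %s", len(flagged), sorted(flagged))
        table = table.true_samples().subset_taxa(
            [t for t in table.taxon_ids if t not in flagged]
        )
        pd.Series(sorted(flagged), name="taxon_id").to_csv(
            outdir / "contaminants.tsv", sep="\t", index=False
        )
    else:
        table = table.true_samples()

    table = filter_low_abundance(table, config.min_total_reads, config.min_prevalence)
    logger.info("after filtering: %d samples x %d taxa", table.n_samples, table.n_taxa)
    table.to_tsv(outdir / "counts_filtered.tsv")

    cells = sorted(
        set(zip(table.metadata["group"], table.metadata["timepoint"]))
    )

    # diversity across all true samples
    rare = rarefy(table, seed=stage_seeds["rarefy"])
    alpha = observed_features(rare)
    alpha_df = pd.DataFrame({"sample_id": alpha.index, "metric": "observed_features",
                             "value": alpha.to_numpy()})
    alpha_df.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)
    dm = jaccard_matrix(rare)
    dm.to_tsv(outdir / "jaccard_distance.tsv")
    labels = [f"{g}_{t}" for g, t in zip(table.metadata["group"], table.metadata["timepoint"])]
    f_stat, p_val = permanova(dm, labels, n_perm=config.n_perm, seed=stage_seeds["diversity"])
    pd.DataFrame([{"test": "permanova_jaccard", "pseudo_F": f_stat, "p_value": p_val}]).to_csv(
        outdir / "permanova.tsv", sep="\t", index=False, float_format="%.10g"
    )

    clr = clr_transform(table)
    clr.to_tsv(outdir / "clr.tsv")

    # per-cell networks
    nets: dict[str, nx.Graph] = {}
    topo_rows = []
    sparcc_seeds = np.random.SeedSequence(stage_seeds["sparcc"]).generate_state(
        len(cells), dtype=np.uint32
    )
    for (group, timepoint), s in zip(cells, sparcc_seeds):
        name = f"{group}_{timepoint}"
        sub = table.group_samples(group, timepoint)
        rho = sparcc(
            sub.counts, n_resamples=config.sparcc_resamples, seed=int(s),
            exclusion_threshold=config.sparcc_exclusion_threshold,
            max_exclusion_rounds=config.sparcc_max_rounds,
        )
        rho.to_tsv(outdir / f"sparcc_{name}.tsv")
        net = build_network(rho, threshold=config.edge_threshold)
        core = build_network(rho, threshold=config.core_threshold) \
            if config.core_threshold < 1 else core_network(rho)
        if net.number_of_nodes() == 0:
            logger.warning("network %s is empty at threshold %.2f", name, config.edge_threshold)
            continue
        nets[name] = net
        topo = topology_summary(net, seed=0)
        topo_rows.append(pd.concat([pd.Series({"network": name}), topo.to_series()]))
        ks = keystone_taxa(
            net, clr, table, group, timepoint,
            abund_cut=config.keystone_abund_cut, eig_cut=config.keystone_eig_cut,
        )
        ks.to_csv(outdir / f"keystones_{name}.tsv", sep="\t", float_format="%.10g")
        write_graph(net, outdir / f"network_{name}.graphml")
        write_graph(net, outdir / f"network_{name}.gexf", fmt="gexf")
        if core.number_of_nodes():
            write_graph(core, outdir / f"core_network_{name}.graphml")
    if topo_rows:
        pd.DataFrame(topo_rows).to_csv(
            outdir / "topology.tsv", sep="\t", index=False, float_format="%.10g"
        )

    # pairwise differential abundance (control vs cancer per timepoint,
    # and within group across timepoints)
    comparisons = []
    groups = sorted({g for g, _ in cells})
    times = sorted({t for _, t in cells})
    for t in times:
        if len(groups) == 2:
            comparisons.append(((groups[0], t), (groups[1], t)))
    for g in groups:
        if len(times) == 2:
            comparisons.append(((g, times[0]), (g, times[1])))
    da_seeds = np.random.SeedSequence(stage_seeds["diffabund"]).generate_state(
        max(len(comparisons), 1), dtype=np.uint32
    )
    for ((ga, ta), (gb, tb)), s in zip(comparisons, da_seeds):
        if (ga, ta) not in cells or (gb, tb) not in cells:
            continue
        res = diff_abundance(
            table, ga, gb, n_mc_instances=config.n_mc_instances, seed=int(s),
            timepoint_a=ta, timepoint_b=tb,
        )
        res.to_tsv(outdir / f"diffabund_{ga}_{ta}_vs_{gb}_{tb}.tsv")

    # robustness battery
    if nets:
        removal, traces, addstats = robustness_battery(
            nets, target=config.loss_target, n_boot=config.n_boot,
            k_values=config.k_values, n_reps=config.n_reps,
            attach_edges=config.attach_edges, rule=config.attach_rule,
            seed=stage_seeds["robustness"],
        )
        removal.to_csv(outdir / "attack_fractions.tsv", sep="\t", index=False,
                       float_format="%.10g")
        traces.to_csv(outdir / "addition_traces.tsv", sep="\t", index=False,
                      float_format="%.10g")
        addstats.to_csv(outdir / "addition_stats.tsv", sep="\t", index=False,
                        float_format="%.10g")
        shared = compare_networks(nets)
        shared.to_csv(outdir / "network_membership.tsv", sep="\t")

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "micronet_version": __version__,
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "networks": sorted(nets),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config.yaml")
    return outdir


def compare_networks(nets: dict[str, nx.Graph]) -> pd.DataFrame:
    """Per-taxon membership across networks plus intersection-pattern counts.

    The returned frame has one boolean column per network and a ``pattern``
    column (e.g. ``control_16dpi+cancer_16dpi``); UpSet-style counts can be
    read off with ``df.groupby("pattern").size()``.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to compare")
    names = sorted(nets)
    taxa = sorted(set().union(*(set(nets[n].nodes) for n in names)))
    df = pd.DataFrame(
        {n: [t in nets[n] for t in taxa] for n in names},
        index=pd.Index(taxa, name="taxon_id"),
    )
    df["pattern"] = df[names].apply(
        lambda r: "+".join(n for n in names if r[n]) or "none", axis=1
    )
    return df
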
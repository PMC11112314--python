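"""Count-table preprocessing and clr-based differential abundance.

Implements the standard amplicon-study front end: prevalence-based
contaminant flagging against negative controls, low-abundance taxon
filtering, the centered log-ratio (clr) transform, and a Dirichlet
Monte-Carlo Kruskal-Wallis differential-abundance test in the style of
ALDEx2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .table import AbundanceTable

__all__ = [
    "ClrMatrix",
    "DiffAbundanceResult",
    "flag_contaminants",
    "filter_low_abundance",
    "clr_transform",
    "diff_abundance",
    "bh_adjust",
]


@dataclass
class ClrMatrix:
    """clr-transformed abundances; every row sums to zero."""

    values: pd.DataFrame  # samples x taxa

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def taxon_ids(self):
        return list(self.values.columns)

    def mean_by_samples(self, sample_ids) -> pd.Series:
        """Per-taxon mean clr over the given samples."""
        return self.values.loc[list(sample_ids)].mean(axis=0)

    def to_tsv(self, path) -> None:
        out = self.values.T
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class DiffAbundanceResult:
    """Per-taxon Kruskal-Wallis statistics with BH-adjusted q-values."""

    table: pd.DataFrame  # index taxon; columns H, p_value, q_value, clr_effect

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q_value"] < alpha])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def flag_contaminants(table: AbundanceTable, score_threshold: float = 0.1) -> set[str]:
    """Prevalence-based contaminant identification against negative controls.

    For each taxon a 2x2 presence/absence table (control vs true sample) is
    scored by the chi-squared statistic without continuity correction; the
    score is the chi-squared tail probability when the taxon is more
    prevalent in controls than in true samples, and 1 otherwise.  Taxa with
    score < ``score_threshold`` are flagged for removal.
    """
    controls = table.controls()
    trues = table.true_samples()
    if controls.n_samples == 0:
        raise ValueError("prevalence method requires negative controls")
    if trues.n_samples == 0:
        raise ValueError("prevalence method requires true samples")

    pres_ctrl = (controls.counts.to_numpy() > 0).sum(axis=0)
    pres_true = (trues.counts.to_numpy() > 0).sum(axis=0)
    n_ctrl, n_true = controls.n_samples, trues.n_samples

    flagged = set()
    for t, a, c in zip(table.taxon_ids, pres_ctrl, pres_true):
        prev_ctrl, prev_true = a / n_ctrl, c / n_true
        if prev_ctrl <= prev_true:
            continue  # score forced to 1: not contaminant-like
        obs = np.array([[a, n_ctrl - a], [c, n_true - c]], dtype=float)
        row = obs.sum(axis=1)
        col = obs.sum(axis=0)
        if (row == 0).any() or (col == 0).any():
            continue
        exp = np.outer(row, col) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        score = stats.chi2.sf(chi2, df=1)
        if score < score_threshold:
            flagged.add(t)
    return flagged


def filter_low_abundance(
    table: AbundanceTable,
    min_total_reads: int = 10,
    min_prevalence: float = 0.30,
) -> AbundanceTable:
    """Remove rare taxa: keep those with total reads >= ``min_total_reads``
    AND nonzero in >= ``min_prevalence`` of samples (strict less-than
    removal on both criteria).  The sample set is unchanged."""
    if min_total_reads < 0 or min_prevalence < 0:
        raise ValueError("thresholds must be >= 0")
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("empty table")
    arr = table.counts.to_numpy()
    total = arr.sum(axis=0)
    prevalence = (arr > 0).mean(axis=0)
    keep = (total >= min_total_reads) & (prevalence >= min_prevalence)
    return table.subset_taxa([t for t, k in zip(table.taxon_ids, keep) if k])


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> ClrMatrix:
    """Centered log-ratio transform: log(count + pseudocount) centered by
    its per-sample mean, so each row sums to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logc = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    vals = logc - logc.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(vals, index=table.sample_ids, columns=table.taxon_ids))


def _kruskal_vectorized(values: np.ndarray, group_idx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Kruskal-Wallis H and chi-squared p per column, tie-corrected.

    ``values`` is samples x taxa; ``group_idx`` the row indices per group.
    Matches scipy.stats.kruskal (cross-checked in the test suite).
    """
    n, m = values.shape
    ranks = stats.rankdata(values, axis=0)
    H = np.zeros(m)
    for idx in group_idx:
        r = ranks[idx].sum(axis=0)
        H += r * r / len(idx)
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    # tie correction per column
    tie = np.ones(m)
    for j in range(m):
        _, counts = np.unique(values[:, j], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie[j] = 1.0 - (t**3 - t).sum() / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(tie > 0, H / tie, 0.0)
    df = len(group_idx) - 1
    p = np.where(tie > 0, stats.chi2.sf(H, df), 1.0)
    return H, p


def diff_abundance(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    n_mc_instances: int = 128,
    seed: int = 0,
    timepoint_a: str | None = None,
    timepoint_b: str | None = None,
) -> DiffAbundanceResult:
    """ALDEx2-style two-group differential abundance.

    For each Monte-Carlo instance, per-sample taxon proportions are drawn
    from Dirichlet(counts + 0.5), clr-transformed, and compared between the
    groups with a Kruskal-Wallis test per taxon.  Reported p-values are the
    expectation over instances, BH-adjusted across taxa; ``clr_effect`` is
    the expected difference of group mean clr (group_b minus group_a).
    """
    sub_a = table.group_samples(group_a, timepoint_a)
    sub_b = table.group_samples(group_b, timepoint_b)
    if sub_a.n_samples < 3 or sub_b.n_samples < 3:
        raise ValueError("each group needs at least 3 samples")

    counts = np.vstack([sub_a.counts.to_numpy(), sub_b.counts.to_numpy()]).astype(float)
    n_a = sub_a.n_samples
    n = counts.shape[0]
    group_idx = [np.arange(n_a), np.arange(n_a, n)]
    alpha = counts + 0.5

    rng = np.random.default_rng(seed)
    p_sum = np.zeros(counts.shape[1])
    H_sum = np.zeros(counts.shape[1])
    eff_sum = np.zeros(counts.shape[1])
    for _ in range(n_mc_instances):
        # per-sample Dirichlet draw via normalized gammas
        g = rng.standard_gamma(alpha)
        frac = g / g.sum(axis=1, keepdims=True)
        logf = np.log(frac)
        clr = logf - logf.mean(axis=1, keepdims=True)
        H, p = _kruskal_vectorized(clr, group_idx)
        p_sum += p
        H_sum += H
        eff_sum += clr[n_a:].mean(axis=0) - clr[:n_a].mean(axis=0)

    p_mean = p_sum / n_mc_instances
    out = pd.DataFrame(
        {
            "H": H_sum / n_mc_instances,
            "p_value": p_mean,
            "q_value": bh_adjust(p_mean),
            "clr_effect": eff_sum / n_mc_instances,
        },
        index=table.taxon_ids,
    )
    return DiffAbundanceResult(out)
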
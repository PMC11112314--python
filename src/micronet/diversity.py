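"""Alpha diversity, Jaccard beta diversity, and PERMANOVA.

Richness (observed features) is computed on rarefied tables; community
dissimilarity uses the presence/absence Jaccard index compared across
groups with a permutation PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "rarefy",
    "observed_features",
    "jaccard_matrix",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    d: pd.DataFrame  # square, index == columns == sample ids

    def __post_init__(self) -> None:
        arr = self.d.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def sample_ids(self):
        return list(self.d.index)

    def to_tsv(self, path) -> None:
        out = self.d.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    ``depth`` defaults to the minimum sample total.  Raises if any sample
    has fewer than ``depth`` reads, naming the offending sample.
    """
    totals = table.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"sample {short.index[0]!r} has {int(short.iloc[0])} reads, fewer than depth {depth}"
        )
    rng = np.random.default_rng(seed)
    arr = table.counts.to_numpy()
    out = np.vstack([rng.multivariate_hypergeometric(row, depth) for row in arr])
    return AbundanceTable(
        pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids),
        table.metadata.copy(),
    )


def observed_features(table: AbundanceTable) -> pd.Series:
    """Per-sample richness: number of taxa with count > 0."""
    return (table.counts > 0).sum(axis=1)


def jaccard_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Jaccard distance 1 - |A∩B| / |A∪B| on presence/absence.

    Two all-zero samples (identical empty sets) are at distance 0.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    pres = (table.counts.to_numpy() > 0).astype(float)
    inter = pres @ pres.T
    sizes = pres.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids))


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances into among- and
    within-group components; the pseudo-F statistic is compared against
    ``n_perm`` label permutations, with p = (1 + #{F_perm >= F}) /
    (1 + n_perm).  Deterministic given ``seed``.
    """
    labels = pd.Series(list(labels), index=dm.sample_ids)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")

    d2 = dm.d.to_numpy() ** 2
    n = d2.shape[0]
    k = len(groups)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    if sst == 0:
        # all samples identical under this metric: no partition can explain
        # any variance, the test is vacuous
        return float("nan"), 1.0
    codes = labels.map({g: i for i, g in enumerate(groups)}).to_numpy()

    def pseudo_f(c: np.ndarray) -> float:
        ssw = 0.0
        for g in range(k):
            idx = np.flatnonzero(c == g)
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ssa = sst - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssa / (k - 1)) / (ssw / (n - k))  # inf when groups are perfectly tight

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)
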
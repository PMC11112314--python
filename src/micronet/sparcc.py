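"""SparCC: basis correlations from compositional counts.

Sequencing counts carry only relative information, so naive correlations on
fractions are spurious.  SparCC estimates correlations of the unobserved
*basis* abundances from the variance matrix of pairwise log-ratios,

    t_ij = Var[ log(x_i / x_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

exploiting a sparsity assumption (most rho_ij ~ 0) to solve the row-sum
linear system for the basis variances w_i, then reading off rho_ij.  Pairs
with strong apparent correlation are iteratively excluded from the system
and the whole procedure is repeated over Dirichlet resamples of the counts,
aggregating by the elementwise median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariationMatrix",
    "CorrelationMatrix",
    "variation_matrix",
    "basis_variances",
    "correlations_from_basis",
    "sparcc_single",
    "sparcc",
]


@dataclass
class VariationMatrix:
    """Variance of log-ratios for every taxon pair (symmetric, zero diag)."""

    taxon_ids: list[str]
    t: np.ndarray


@dataclass
class CorrelationMatrix:
    """Estimated basis correlations rho and basis variances w."""

    taxon_ids: list[str]
    rho: np.ndarray
    basis_var: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxon_ids, columns=self.taxon_ids)

    def to_tsv(self, path) -> None:
        out = self.to_dataframe()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def to_long_tsv(self, path) -> None:
        rows = []
        for i, ti in enumerate(self.taxon_ids):
            for j in range(i + 1, len(self.taxon_ids)):
                rows.append((ti, self.taxon_ids[j], self.rho[i, j]))
        pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def _as_fractions(fractions) -> tuple[np.ndarray, list[str]]:
    if isinstance(fractions, pd.DataFrame):
        return fractions.to_numpy(dtype=float), list(fractions.columns)
    arr = np.asarray(fractions, dtype=float)
    return arr, [f"t{i}" for i in range(arr.shape[1])]


def variation_matrix(fractions) -> VariationMatrix:
    """t_ij = sample variance (n-1 denominator) of log(x_i/x_j).

    ``fractions`` is samples x taxa and must be strictly positive (draw
    from a Dirichlet posterior first if the counts contain zeros).
    """
    arr, taxa = _as_fractions(fractions)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if arr.shape[1] < 4:
        raise ValueError("SparCC unidentifiable below 4 taxa")
    if (arr <= 0).any():
        raise ValueError("fractions must be strictly positive")
    logf = np.log(arr)
    n, D = logf.shape
    # Var(log xi - log xj) = Var(li) + Var(lj) - 2 Cov(li, lj)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2 * cov
    t = np.clip((t + t.T) / 2, 0, None)
    np.fill_diagonal(t, 0.0)
    return VariationMatrix(taxa, t)


def basis_variances(
    T: VariationMatrix,
    excluded_pairs: list[tuple[int, int]] | None = None,
    floor: float = 1e-6,
) -> np.ndarray:
    """Solve the SparCC row-sum system for basis variances.

    Under the sparsity approximation the row sums of t satisfy
    ``sum_j t_ij ~= (D-1) w_i + sum_{j != i} w_j``; excluded pairs are
    dropped from both the row sums and the system coefficients.  Negative
    solutions are clipped to ``floor``.
    """
    t = T.t
    D = t.shape[0]
    if D < 4:
        raise ValueError("SparCC unidentifiable below 4 taxa")
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    t_row = t.sum(axis=1)
    for i, j in excluded_pairs or []:
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] -= 1
        M[j, i] -= 1
        t_row[i] -= t[i, j]
        t_row[j] -= t[i, j]
    try:
        w = np.linalg.solve(M, t_row)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"singular SparCC system: {exc}") from exc
    return np.clip(w, floor, None)


def correlations_from_basis(T: VariationMatrix, w: np.ndarray) -> CorrelationMatrix:
    """rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1]."""
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("basis variances must be positive")
    om = w[:, None] + w[None, :]
    rho = (om - T.t) / (2.0 * np.sqrt(np.outer(w, w)))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(T.taxon_ids, rho, w)


def sparcc_single(
    fractions,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
) -> CorrelationMatrix:
    """One SparCC pass on a strictly-positive fraction matrix.

    Per round the strongest not-yet-excluded off-diagonal pair is excluded
    from the basis-variance system while its |rho| exceeds
    ``exclusion_threshold``, for at most ``max_exclusion_rounds`` rounds
    (the Friedman-Alm defaults).  If every pair of some taxon ends up
    excluded, that taxon is dropped from the system and reported via the
    returned object's ``basis_var`` floor.
    """
    T = variation_matrix(fractions)
    D = T.t.shape[0]
    excluded: list[tuple[int, int]] = []
    excluded_count = np.zeros(D, dtype=int)
    result = None
    for round_ in range(max_exclusion_rounds + 1):
        w = basis_variances(T, excluded)
        result = correlations_from_basis(T, w)
        if round_ == max_exclusion_rounds:
            break
        A = np.abs(result.rho).copy()
        np.fill_diagonal(A, 0.0)
        for i, j in excluded:
            A[i, j] = A[j, i] = 0.0
        i, j = np.unravel_index(int(A.argmax()), A.shape)
        if A[i, j] <= exclusion_threshold:
            break
        if excluded_count[i] >= D - 2 or excluded_count[j] >= D - 2:
            break  # would disconnect a taxon from the system entirely
        excluded.append((min(i, j), max(i, j)))
        excluded_count[i] += 1
        excluded_count[j] += 1
    return result


def sparcc(
    counts,
    n_resamples: int = 20,
    seed: int = 0,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
) -> CorrelationMatrix:
    """Full SparCC estimate with Dirichlet resampling.

    For each resample, per-sample fractions are drawn from
    Dirichlet(counts + ``pseudocount``) and a single SparCC pass is run;
    the final rho is the elementwise median over resamples (basis
    variances are medians too).  Deterministic given ``seed``.
    """
    if isinstance(counts, pd.DataFrame):
        arr, taxa = counts.to_numpy(dtype=float), list(counts.columns)
    else:
        arr = np.asarray(counts, dtype=float)
        taxa = [f"t{i}" for i in range(arr.shape[1])]
    if arr.shape[1] < 4:
        raise ValueError("SparCC unidentifiable below 4 taxa")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")

    rng = np.random.default_rng(seed)
    rhos, ws = [], []
    alpha = arr + pseudocount
    for _ in range(n_resamples):
        g = rng.standard_gamma(alpha)
        frac = g / g.sum(axis=1, keepdims=True)
        est = sparcc_single(
            pd.DataFrame(frac, columns=taxa),
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
        )
        rhos.append(est.rho)
        ws.append(est.basis_var)
    rho = np.median(rhos, axis=0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(taxa, rho, np.median(ws, axis=0))
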
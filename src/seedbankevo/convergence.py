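"""Convergent vs divergent evolution between cohorts at the gene level.

Three complementary comparisons of two strain-transfer-regime cohorts:

* **Set overlap** -- the intersection size of the two cohorts' significant
  gene sets against the exact hypergeometric null of two uniformly random
  subsets of the gene universe (larger than expected = convergence, smaller
  = divergence).
* **<dM> with a fixed-margin permutation null** -- the mean absolute
  difference of relative multiplicities over a shared gene universe,
  standardized (Z) against randomized gene-by-cohort contingency tables with
  both margins fixed (Patefield/ASA159 sampling).  Positive Z marks
  divergence, negative convergence.
* **Skellam scan** -- per-gene difference of the two cohorts' counts against
  the difference of independent Poisson counts at the cohorts'
  length-proportional null rates, flagging genes preferentially enriched in
  one cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parallelism import EnrichmentResult, GeneCatalog

__all__ = [
    "OverlapTest",
    "DivergenceResult",
    "overlap_null",
    "relative_multiplicities",
    "mean_abs_diff",
    "fixed_margin_null",
    "divergence_analysis",
    "skellam_preferential",
    "skellam_gene_scan",
]


@dataclass
class OverlapTest:
    """Exact hypergeometric null for the overlap of two gene sets.

    ``support`` and ``pmf`` describe the null distribution of the
    intersection size ``k``; ``p_convergence`` is the upper tail
    ``P(K >= k)`` and ``p_divergence`` the lower tail ``P(K <= k)``.
    """

    size1: int
    size2: int
    n_genes: int
    k: int
    support: np.ndarray
    pmf: np.ndarray
    p_convergence: float
    p_divergence: float

    @property
    def expected_k(self) -> float:
        return self.size1 * self.size2 / self.n_genes

    def classify(self, alpha: float = 0.05) -> str:
        if self.p_convergence <= alpha:
            return "convergent"
        if self.p_divergence <= alpha:
            return "divergent"
        return "neither"


def overlap_null(size1: int, size2: int, n_genes: int, k: int) -> OverlapTest:
    """Hypergeometric test for the intersection of two enriched-gene sets.

    Two subsets of sizes ``size1`` and ``size2`` drawn uniformly from
    ``n_genes`` genes intersect in ``K ~ Hypergeometric(n_genes, size1,
    size2)`` genes.
    """
    if size1 > n_genes or size2 > n_genes:
        raise ValueError("set sizes cannot exceed the gene universe")
    lo = max(0, size1 + size2 - n_genes)
    hi = min(size1, size2)
    if not lo <= k <= hi:
        raise ValueError(f"observed overlap {k} outside support [{lo}, {hi}]")
    rv = stats.hypergeom(n_genes, size1, size2)
    support = np.arange(lo, hi + 1)
    return OverlapTest(
        size1=size1,
        size2=size2,
        n_genes=n_genes,
        k=k,
        support=support,
        pmf=rv.pmf(support),
        p_convergence=float(rv.sf(k - 1)),
        p_divergence=float(rv.cdf(k)),
    )


def relative_multiplicities(m: Sequence[float]) -> np.ndarray:
    """Normalize multiplicities to the simplex, ``M_i = m_i / sum(m)``."""
    m = np.asarray(m, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("relative multiplicities require a positive total")
    return m / total


def mean_abs_diff(M1: Sequence[float], M2: Sequence[float]) -> float:
    """Mean absolute difference of two relative-multiplicity vectors."""
    M1 = np.asarray(M1, dtype=float)
    M2 = np.asarray(M2, dtype=float)
    if M1.shape != M2.shape:
        raise ValueError("vectors must share the same gene universe")
    for M in (M1, M2):
        if abs(M.sum() - 1) > 1e-6:
            raise ValueError("inputs must be normalized relative multiplicities")
    return float(np.mean(np.abs(M1 - M2)))


@dataclass
class DivergenceResult:
    """<dM> between two cohorts with its fixed-margin permutation null.

    ``z`` is (observed - null mean)/null sd; positive = divergence, negative
    = convergence.  ``p_normal`` assumes an approximately normal null;
    ``p_empirical`` is the two-sided empirical-quantile p-value.
    """

    gene_universe: list
    M1: np.ndarray
    M2: np.ndarray
    observed: float
    null: np.ndarray
    iterations: int
    seed: int
    z: float
    p_normal: float
    p_empirical: float


def fixed_margin_null(
    count_matrix: np.ndarray,
    iterations: int = 10000,
    seed: int = 0,
    length_weights: Sequence[float] | None = None,
    gene_universe: Sequence | None = None,
) -> DivergenceResult:
    """Standardized <dM> against randomized tables with both margins fixed.

    ``count_matrix`` is a genes x 2 integer matrix of mutation counts.
    Randomization holds the per-gene totals (row margins) and per-cohort
    totals (column margins) fixed, sampling via Patefield's algorithm
    (the ASA159 permutation null).  ``length_weights`` optionally carries
    ``Lbar/L_i`` so that the statistic operates on relative multiplicities
    rather than raw relative counts.
    """
    counts = np.asarray(count_matrix, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("count_matrix must be genes x 2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    col = counts.sum(axis=0)
    if (col == 0).any():
        raise ValueError("degenerate margins: a cohort has zero mutations")
    row = counts.sum(axis=1)
    w = np.ones(len(counts)) if length_weights is None else np.asarray(length_weights, float)
    if w.shape != (len(counts),) or (w <= 0).any():
        raise ValueError("length_weights must be positive, one per gene")

    def dm(tab: np.ndarray) -> float:
        m1 = tab[:, 0] * w
        m2 = tab[:, 1] * w
        return float(np.mean(np.abs(m1 / m1.sum() - m2 / m2.sum())))

    observed = dm(counts)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row, col)
    tables = sampler.rvs(iterations, method="patefield", random_state=rng)
    null = np.empty(iterations)
    for i in range(iterations):
        tab = tables[i]
        c = tab.sum(axis=0)
        if (c == 0).any():  # pragma: no cover - excluded by margin check
            null[i] = np.nan
            continue
        null[i] = dm(tab)
    mu = float(np.nanmean(null))
    sd = float(np.nanstd(null))
    if sd == 0:
        z = math.nan
        p_normal = math.nan
    else:
        z = (observed - mu) / sd
        p_normal = 2 * stats.norm.sf(abs(z))
    upper = (1 + np.sum(null >= observed)) / (1 + iterations)
    lower = (1 + np.sum(null <= observed)) / (1 + iterations)
    p_emp = min(1.0, 2 * min(upper, lower))
    M1 = relative_multiplicities(counts[:, 0] * w)
    M2 = relative_multiplicities(counts[:, 1] * w)
    universe = list(gene_universe) if gene_universe is not None else list(range(len(counts)))
    return DivergenceResult(
        gene_universe=universe,
        M1=M1,
        M2=M2,
        observed=observed,
        null=null,
        iterations=iterations,
        seed=seed,
        z=float(z),
        p_normal=float(p_normal),
        p_empirical=float(p_emp),
    )


def divergence_analysis(
    result1: EnrichmentResult,
    result2: EnrichmentResult,
    universe: str = "union",
    iterations: int = 10000,
    seed: int = 0,
    use_length_weights: bool = True,
) -> DivergenceResult:
    """<dM> divergence between two cohorts' enrichment results.

    The gene universe defaults to the union of the two significant sets
    (genes significant in only one cohort enter with their observed counts,
    possibly 0 in the other cohort); ``universe="intersection"`` restricts to
    genes significant in both.
    """
    if universe == "union":
        genes = sorted(result1.significant | result2.significant)
    elif universe == "intersection":
        genes = sorted(result1.significant & result2.significant)
    else:
        raise ValueError(f"unknown universe rule {universe!r}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes in the comparison universe")
    counts = np.column_stack(
        [
            result1.counts.reindex(genes, fill_value=0).to_numpy(),
            result2.counts.reindex(genes, fill_value=0).to_numpy(),
        ]
    )
    weights = None
    if use_length_weights:
        # lambdas are proportional to L_i within a cohort; recover Lbar/L_i
        rel = result1.lambdas.reindex(genes).to_numpy()
        with np.errstate(divide="ignore"):
            weights = np.where(rel > 0, rel.mean() / rel, 1.0)
    return fixed_margin_null(
        counts,
        iterations=iterations,
        seed=seed,
        length_weights=weights,
        gene_universe=genes,
    )


def skellam_preferential(n1: int, n2: int, mu1: float, mu2: float) -> float:
    """Two-sided Skellam tail p-value for a between-cohort count difference.

    Under independent Poisson counts with rates ``mu1`` and ``mu2``, the
    difference ``K = N1 - N2`` is Skellam-distributed; the p-value is
    ``P(|K| >= |n1 - n2|)``.
    """
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("Skellam rates must be positive")
    d = abs(int(n1) - int(n2))
    if d == 0:
        return 1.0
    return float(
        stats.skellam.sf(d - 1, mu1, mu2) + stats.skellam.cdf(-d, mu1, mu2)
    )


def skellam_gene_scan(
    counts1: pd.Series,
    counts2: pd.Series,
    catalog: GeneCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene preferential-enrichment scan between two cohorts.

    Null rates default to each gene's expected count under its cohort's
    total and the length-proportional model, ``mu_ij = ntot_j * L_i /
    (Lbar * N_genes)``.  The critical p-value ``P*`` follows the same
    survival-curve FDR rule as the parallelism module, using the Skellam
    null's own tail probabilities to count expected false discoveries.
    """
    L = catalog.lengths
    n1 = counts1.reindex(L.index, fill_value=0).to_numpy(dtype=np.int64)
    n2 = counts2.reindex(L.index, fill_value=0).to_numpy(dtype=np.int64)
    ntot1, ntot2 = int(n1.sum()), int(n2.sum())
    base = L.to_numpy() / (catalog.mean_length * catalog.n_genes)
    mu1 = ntot1 * base
    mu2 = ntot2 * base
    d = np.abs(n1 - n2)
    k_max = max(int(d.max()) + 50, 100)
    ks = np.arange(1, k_max + 1)
    # tails[g, k-1] = P(|K_g| >= k) under the gene's Skellam null
    tails = (
        stats.skellam.sf(ks[None, :] - 1, mu1[:, None], mu2[:, None])
        + stats.skellam.cdf(-ks[None, :], mu1[:, None], mu2[:, None])
    )
    pvals = np.where(d == 0, 1.0, tails[np.arange(len(d)), np.maximum(d, 1) - 1])
    # survival-curve critical threshold on the Skellam null: for each
    # candidate, the expected false discoveries are the per-gene tails at the
    # smallest |difference| whose p-value clears the threshold
    candidates = np.unique(pvals[pvals < 1])
    p_star = 0.0
    for thr in candidates:
        observed = int(np.sum(pvals <= thr))
        reach = tails <= thr
        has = reach.any(axis=1)
        first = np.argmax(reach, axis=1)
        expected = float(tails[np.arange(len(d)), first][has].sum())
        if observed > 0 and expected / observed <= alpha:
            p_star = max(p_star, float(thr))
    return pd.DataFrame(
        {
            "gene_id": L.index,
            "n1": n1,
            "n2": n2,
            "mu1": mu1,
            "mu2": mu2,
            "pvalue": pvals,
            "significant": (pvals <= p_star) & (p_star > 0),
        }
    ).set_index("gene_id")
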
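"""Gene-level parallelism statistics for evolve-and-resequence cohorts.

A cohort (one strain-transfer-regime combination) contributes a per-gene
count ``n_i`` of nonsynonymous mutations pooled across replicate
populations.  Parallelism is quantified by

* **multiplicity** ``m_i = n_i * Lbar / L_i`` -- the gene's mutation count
  rescaled by the ratio of the mean to the gene-specific effective
  nonsynonymous length, so ``m_i > 1`` marks excess hits;
* the genome-wide log-likelihood excess ``delta_ell = sum n_i log(m_i/mbar)``
  of the gene-specific multiplicity model over the uniform null (a scaled
  Kullback-Leibler divergence, hence nonnegative), with permutation and
  mutation-subsampling controls;
* per-gene Poisson tail P-values under the length-proportional null, an FDR
  threshold ``P*`` built from the null Poisson survival curves, and the
  resulting significant-gene set (genes with at least 3 mutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio.Data import CodonTable

__all__ = [
    "GeneCatalog",
    "GeneMutationTable",
    "EnrichmentResult",
    "multiplicity",
    "delta_ell",
    "permutation_delta_ell",
    "subsample_delta_ell",
    "poisson_gene_pvalue",
    "critical_pvalue",
    "gene_enrichment",
    "significant_genes",
    "region_binomial_test",
    "fraction_difference_test",
    "effective_gene_lengths",
]


@dataclass
class GeneCatalog:
    """Per-gene effective nonsynonymous lengths plus optional gene sets.

    ``lengths`` is indexed by gene id; ``gene_sets`` maps a set name (e.g.
    ``"spo0A_regulon"``) to a collection of member gene ids.
    """

    lengths: pd.Series
    gene_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=float)
        if (self.lengths <= 0).any():
            bad = self.lengths[self.lengths <= 0].index[0]
            raise ValueError(f"gene {bad!r} has nonpositive effective length")
        if self.lengths.index.has_duplicates:
            dup = self.lengths.index[self.lengths.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        for name, members in self.gene_sets.items():
            extra = set(members) - set(self.lengths.index)
            if extra:
                raise ValueError(f"gene set {name!r} has unknown genes: {sorted(extra)[:5]}")
            self.gene_sets[name] = set(members)

    @property
    def n_genes(self) -> int:
        return len(self.lengths)

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean())

    def subset(self, genes: Iterable) -> "GeneCatalog":
        wanted = set(genes)
        keep = [g for g in self.lengths.index if g in wanted]
        return GeneCatalog(self.lengths.loc[keep])

    def excluding(self, set_name: str) -> "GeneCatalog":
        """Catalog restricted to genes outside a named gene set."""
        members = self.gene_sets[set_name]
        return self.subset(g for g in self.lengths.index if g not in members)


@dataclass
class GeneMutationTable:
    """Per-gene nonsynonymous mutation counts for one cohort.

    Counts are pooled across the cohort's replicate populations; genes absent
    from ``counts`` carry 0.
    """

    counts: pd.Series

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("mutation counts must be nonnegative")

    @property
    def n_tot(self) -> int:
        return int(self.counts.sum())

    def aligned_to(self, catalog: GeneCatalog) -> pd.Series:
        """Counts reindexed over the catalog's gene universe (missing -> 0)."""
        extra = set(self.counts.index) - set(catalog.lengths.index)
        if extra:
            raise ValueError(f"counts reference genes absent from the catalog: {sorted(extra)[:5]}")
        return self.counts.reindex(catalog.lengths.index, fill_value=0)


def multiplicity(n_i, L_i, L_mean) -> np.ndarray | float:
    """Multiplicity ``m_i = n_i * Lbar / L_i`` (vectorized)."""
    return np.asarray(n_i) * np.asarray(L_mean) / np.asarray(L_i)


def delta_ell(table: GeneMutationTable, catalog: GeneCatalog) -> float:
    """Genome-wide parallelism score ``sum_i n_i log(m_i / mbar)``.

    Natural log; genes with ``n_i = 0`` contribute 0 (the ``n log n -> 0``
    limit).  Always nonnegative, since it equals ``n_tot`` times a KL
    divergence between the observed and length-proportional mutation
    distributions.
    """
    n = table.aligned_to(catalog).to_numpy(dtype=float)
    n_tot = n.sum()
    if n_tot == 0:
        raise ValueError("delta_ell requires at least one mutation")
    L = catalog.lengths.to_numpy(dtype=float)
    m = n * catalog.mean_length / L
    m_bar = n_tot / catalog.n_genes
    pos = n > 0
    return float(np.sum(n[pos] * np.log(m[pos] / m_bar)))


def permutation_delta_ell(
    table: GeneMutationTable,
    catalog: GeneCatalog,
    iterations: int = 10000,
    seed: int = 0,
) -> tuple:
    """Permutation p-value for delta_ell.

    Mutations are reassigned to genes with probability proportional to
    ``L_i`` each iteration; the p-value is the fraction of null values at
    least as large as observed (with the +1 pseudo-count convention).
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    rng = np.random.default_rng(seed)
    n = table.aligned_to(catalog).to_numpy(dtype=float)
    n_tot = int(n.sum())
    L = catalog.lengths.to_numpy(dtype=float)
    p = L / L.sum()
    m_bar = n_tot / catalog.n_genes
    scale = catalog.mean_length / L
    observed = delta_ell(table, catalog)
    null = np.empty(iterations)
    draws = rng.multinomial(n_tot, p, size=iterations)
    for i in range(iterations):
        ni = draws[i]
        pos = ni > 0
        null[i] = np.sum(ni[pos] * np.log(ni[pos] * scale[pos] / m_bar))
    pval = (1 + np.sum(null >= observed)) / (1 + iterations)
    return observed, float(pval), null


def subsample_delta_ell(
    table: GeneMutationTable,
    catalog: GeneCatalog,
    target_total: int,
    iterations: int = 1000,
    seed: int = 0,
    exclude_set: str | None = None,
) -> np.ndarray:
    """Distribution of delta_ell after subsampling the observed mutations.

    Each iteration draws ``target_total`` mutations without replacement from
    the observed multiset (every observed mutation equally likely), which
    removes the dependence of delta_ell on cohort size when comparing
    cohorts.  ``exclude_set`` names a catalog gene set to drop first (e.g.
    the *spo0A* regulon control), in which case the catalog statistics are
    recomputed over the remaining genes.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    if exclude_set is not None:
        catalog_used = catalog.excluding(exclude_set)
        counts = table.counts[table.counts.index.isin(catalog_used.lengths.index)]
        table = GeneMutationTable(counts)
    else:
        catalog_used = catalog
    if target_total > table.n_tot:
        raise ValueError("target_total exceeds the number of observed mutations")
    rng = np.random.default_rng(seed)
    n = table.aligned_to(catalog_used).to_numpy(dtype=np.int64)
    scale = catalog_used.mean_length / catalog_used.lengths.to_numpy(dtype=float)
    m_bar = target_total / catalog_used.n_genes
    out = np.empty(iterations)
    for i in range(iterations):
        ni = rng.multivariate_hypergeometric(n, target_total)
        pos = ni > 0
        out[i] = np.sum(ni[pos] * np.log(ni[pos] * scale[pos] / m_bar))
    return out


def poisson_gene_pvalue(n_i, n_tot: int, L_i, L_mean: float, N_genes: int):
    """Upper Poisson tail P(N >= n_i) with lambda = n_tot*L_i/(Lbar*N_genes).

    Evaluated through the regularized upper incomplete gamma function
    (scipy's Poisson survival function) for numerical stability.
    """
    lam = n_tot * np.asarray(L_i, dtype=float) / (L_mean * N_genes)
    return stats.poisson.sf(np.asarray(n_i) - 1, lam)


def _null_sf_table(lambdas: np.ndarray, n_max: int) -> np.ndarray:
    """``sf[i, n] = P(Poisson(lambda_i) >= n)`` for n = 0..n_max."""
    n = np.arange(n_max + 1)
    return stats.poisson.sf(n[None, :] - 1, lambdas[:, None])


def critical_pvalue(
    pvalues: Sequence[float],
    lambdas: Sequence[float],
    alpha: float = 0.05,
    count_filter: int = 3,
    observed_counts: Sequence[int] | None = None,
) -> float:
    """FDR-controlling critical P-value from null Poisson survival curves.

    ``P*`` is the largest observed threshold ``P`` such that the expected
    number of null genes reaching significance (a Poisson draw with the
    gene's null rate that both passes the ``n_i >= count_filter`` filter and
    attains a tail P-value <= P) divided by the observed number of genes with
    ``P_i <= P`` is at most ``alpha``.  Only genes passing the count filter
    contribute observed discoveries.  Returns 0.0 when no threshold
    qualifies.
    """
    p = np.asarray(pvalues, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value input")
    if len(p) != len(lam):
        raise ValueError("pvalues and lambdas must align")
    if observed_counts is None:
        passing = np.ones(len(p), dtype=bool)
    else:
        passing = np.asarray(observed_counts) >= count_filter
    candidates = np.unique(p[passing])
    if len(candidates) == 0:
        return 0.0
    if alpha >= 1:
        return float(candidates.max())

    n_max = 200
    sf = _null_sf_table(lam, n_max)
    best = 0.0
    for thr in candidates:
        observed = int(np.sum(passing & (p <= thr)))
        # smallest count whose tail p-value clears thr, per gene
        n_star = np.sum(sf > thr, axis=1)
        n_eff = np.maximum(n_star, count_filter)
        n_eff = np.minimum(n_eff, n_max)
        expected = float(sf[np.arange(len(lam)), n_eff].sum())
        if observed > 0 and expected / observed <= alpha:
            best = max(best, float(thr))
    return best


@dataclass
class EnrichmentResult:
    """Full per-cohort gene-enrichment summary.

    Indexing of all Series follows the catalog's gene universe.  ``p_star``
    is the survival-curve FDR threshold; ``significant`` the gene set
    ``{i : P_i <= P*, n_i >= count_filter}``.
    """

    counts: pd.Series
    multiplicities: pd.Series
    m_bar: float
    delta_ell: float
    pvalues: pd.Series
    lambdas: pd.Series
    p_star: float
    alpha: float
    count_filter: int
    significant: set


def gene_enrichment(
    table: GeneMutationTable,
    catalog: GeneCatalog,
    alpha: float = 0.05,
    count_filter: int = 3,
    method: str = "survival",
) -> EnrichmentResult:
    """Multiplicities, delta_ell, Poisson P-values and the significant set.

    ``method="survival"`` uses the Poisson-survival-curve critical P-value;
    ``method="bh"`` substitutes plain Benjamini-Hochberg over the filtered
    genes.
    """
    n = table.aligned_to(catalog)
    n_tot = int(n.sum())
    L = catalog.lengths
    m = pd.Series(multiplicity(n, L, catalog.mean_length), index=L.index)
    m_bar = n_tot / catalog.n_genes
    lam = pd.Series(
        n_tot * L.to_numpy() / (catalog.mean_length * catalog.n_genes), index=L.index
    )
    pvals = pd.Series(
        poisson_gene_pvalue(n.to_numpy(), n_tot, L.to_numpy(), catalog.mean_length, catalog.n_genes),
        index=L.index,
    )
    passing = n >= count_filter
    if method == "survival":
        p_star = critical_pvalue(
            pvals.to_numpy(), lam.to_numpy(), alpha, count_filter, n.to_numpy()
        )
    elif method == "bh":
        p_star = 0.0
        if passing.any():
            sub = pvals[passing].to_numpy()
            reject, _, _, _ = multipletests(sub, alpha=alpha, method="fdr_bh")
            if reject.any():
                p_star = float(sub[reject].max())
    else:
        raise ValueError(f"unknown method {method!r}")
    sig = set(L.index[(pvals <= p_star) & passing]) if p_star > 0 else set()
    return EnrichmentResult(
        counts=n,
        multiplicities=m,
        m_bar=m_bar,
        delta_ell=delta_ell(table, catalog) if n_tot > 0 else 0.0,
        pvalues=pvals,
        lambdas=lam,
        p_star=p_star,
        alpha=alpha,
        count_filter=count_filter,
        significant=sig,
    )


def significant_genes(result: EnrichmentResult) -> set:
    """Significant-gene set ``{i : P_i <= P*, n_i >= count_filter}``."""
    if result.p_star <= 0:
        return set()
    mask = (result.pvalues <= result.p_star) & (result.counts >= result.count_filter)
    return set(result.pvalues.index[mask])


def region_binomial_test(n_region: int, n_total: int, l: float) -> float:
    """Upper-tail binomial P-value for a genomic region's mutation count.

    Under the null, each of ``n_total`` mutations falls in the region with
    probability ``l`` (its genome fraction); the P-value is
    ``P(N >= n_region)``.
    """
    if not 0 < l < 1:
        raise ValueError("region fraction l must lie in (0, 1)")
    if n_region > n_total:
        raise ValueError("n_region cannot exceed n_total")
    return float(stats.binom.sf(n_region - 1, n_total, l))


def fraction_difference_test(
    n_region_1: int,
    n_total_1: int,
    n_region_2: int,
    n_total_2: int,
    l: float,
    iterations: int = 10000,
    seed: int = 0,
) -> tuple:
    """Signed between-cohort difference in a region's mutation fraction.

    The observed difference ``n1/N1 - n2/N2`` is compared against a null
    simulated by drawing both region counts binomially with probability
    ``l``; the returned p-value is two-sided on the absolute difference.
    """
    if not 0 < l < 1:
        raise ValueError("region fraction l must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    observed = n_region_1 / n_total_1 - n_region_2 / n_total_2
    d1 = rng.binomial(n_total_1, l, size=iterations) / n_total_1
    d2 = rng.binomial(n_total_2, l, size=iterations) / n_total_2
    null = d1 - d2
    pval = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + iterations)
    return float(observed), float(pval), null


# ---------------------------------------------------------------------------
# Effective nonsynonymous gene lengths (site counting)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _codon_nonsyn_sites(codon: str, forward_table: dict, stop_codons: set) -> float:
    """Count of effective nonsynonymous sites in one codon.

    For each position, the fraction of the 3 possible point substitutions
    that change the encoded amino acid (substitutions creating a stop count
    as nonsynonymous).
    """
    total = 0.0
    aa = forward_table[codon]
    for pos in range(3):
        nonsyn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in stop_codons or forward_table[alt] != aa:
                nonsyn += 1
        total += nonsyn / 3.0
    return total


def effective_gene_lengths(
    coding_sequences: Mapping[str, str],
    codon_table_id: int = 11,
    gene_sets: dict | None = None,
) -> GeneCatalog:
    """Effective nonsynonymous length of each gene by codon site counting.

    Uses the bacterial genetic code (NCBI table 11) by default.  A trailing
    stop codon is allowed and excluded from the count; internal stops or
    lengths not divisible by 3 raise an error naming the gene.
    """
    table = CodonTable.unambiguous_dna_by_id[codon_table_id]
    forward = dict(table.forward_table)
    stops = set(table.stop_codons)
    site_counts = {c: _codon_nonsyn_sites(c, forward, stops) for c in forward}
    lengths = {}
    for gene, seq in coding_sequences.items():
        s = str(seq).upper().replace("U", "T")
        if len(s) % 3 != 0:
            raise ValueError(f"gene {gene!r}: CDS length {len(s)} not divisible by 3")
        codons = [s[i:i + 3] for i in range(0, len(s), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        total = 0.0
        for k, codon in enumerate(codons):
            if codon in stops:
                raise ValueError(f"gene {gene!r}: internal stop codon at codon {k + 1}")
            if codon not in forward:
                raise ValueError(f"gene {gene!r}: ambiguous codon {codon!r}")
            total += site_counts[codon]
        if total <= 0:
            raise ValueError(f"gene {gene!r}: no nonsynonymous sites")
        lengths[gene] = total
    return GeneCatalog(pd.Series(lengths, dtype=float), gene_sets or {})
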
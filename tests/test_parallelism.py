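"""Tests for multiplicity, delta_ell, Poisson enrichment, and site counting."""

import math

import numpy as np
import pandas as pd
import pytest

import seedbankevo as se


def _catalog(lengths):
    return se.GeneCatalog(pd.Series(lengths, dtype=float))


class TestMultiplicity:
    def test_arithmetic(self):
        assert se.multiplicity(4, 100.0, 100.0) == pytest.approx(4.0)
        assert se.multiplicity(3, 200.0, 100.0) == pytest.approx(1.5)
        assert se.multiplicity(0, 50.0, 100.0) == 0.0

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        L = rng.lognormal(6, 0.4, 50)
        n = rng.poisson(2.0, 50)
        m = se.multiplicity(n, L, L.mean())
        assert np.sum(m * L / L.mean()) == pytest.approx(n.sum())


class TestDeltaEll:
    def test_two_gene_worked_example(self):
        cat = _catalog({"a": 100.0, "b": 100.0})
        table = se.GeneMutationTable(pd.Series({"a": 4, "b": 0}))
        assert se.delta_ell(table, cat) == pytest.approx(4 * math.log(2))

    def test_zero_when_counts_proportional_to_lengths(self):
        cat = _catalog({"a": 100.0, "b": 300.0})
        table = se.GeneMutationTable(pd.Series({"a": 10, "b": 30}))
        assert se.delta_ell(table, cat) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            n_genes = rng.integers(3, 30)
            L = rng.lognormal(6, 0.5, n_genes)
            cat = _catalog({f"g{i}": L[i] for i in range(n_genes)})
            counts = rng.poisson(rng.uniform(0.2, 3.0), n_genes)
            if counts.sum() == 0:
                continue
            table = se.GeneMutationTable(pd.Series(counts, index=cat.lengths.index))
            assert se.delta_ell(table, cat) >= -1e-9

    def test_permutation_pvalue_separates_signal_from_null(self):
        rng = np.random.default_rng(2)
        L = rng.lognormal(6, 0.4, 100)
        cat = _catalog({f"g{i}": L[i] for i in range(100)})
        null_counts = rng.poisson(2 * L / L.mean())
        enriched = null_counts.copy()
        enriched[:3] += 40
        tab_null = se.GeneMutationTable(pd.Series(null_counts, index=cat.lengths.index))
        tab_sig = se.GeneMutationTable(pd.Series(enriched, index=cat.lengths.index))
        _, p_null, _ = se.permutation_delta_ell(tab_null, cat, iterations=300, seed=0)
        _, p_sig, _ = se.permutation_delta_ell(tab_sig, cat, iterations=300, seed=0)
        assert p_sig < 0.01 < p_null


class TestSubsampling:
    def test_full_sample_returns_observed_value(self):
        cat = _catalog({"a": 100.0, "b": 100.0, "c": 100.0})
        table = se.GeneMutationTable(pd.Series({"a": 5, "b": 1, "c": 0}))
        obs = se.delta_ell(table, cat)
        vals = se.subsample_delta_ell(table, cat, target_total=6, iterations=5, seed=1)
        assert np.allclose(vals, obs)

    def test_reproducible_and_validated(self):
        cat = _catalog({"a": 100.0, "b": 100.0})
        table = se.GeneMutationTable(pd.Series({"a": 6, "b": 2}))
        v1 = se.subsample_delta_ell(table, cat, 4, iterations=1, seed=7)
        v2 = se.subsample_delta_ell(table, cat, 4, iterations=1, seed=7)
        assert v1 == v2
        with pytest.raises(ValueError):
            se.subsample_delta_ell(table, cat, 0)
        with pytest.raises(ValueError):
            se.subsample_delta_ell(table, cat, 100)

    def test_subsampled_mean_below_observed_for_enriched_table(self):
        rng = np.random.default_rng(3)
        L = rng.lognormal(6, 0.4, 200)
        cat = _catalog({f"g{i}": L[i] for i in range(200)})
        counts = rng.poisson(0.5 * L / L.mean())
        counts[:5] += 30
        table = se.GeneMutationTable(pd.Series(counts, index=cat.lengths.index))
        obs = se.delta_ell(table, cat)
        sub = se.subsample_delta_ell(table, cat, table.n_tot // 2, iterations=200, seed=4)
        assert sub.mean() < obs

    def test_gene_set_exclusion(self):
        lengths = pd.Series({"a": 100.0, "b": 100.0, "c": 100.0})
        cat = se.GeneCatalog(lengths, {"regulon": {"a"}})
        table = se.GeneMutationTable(pd.Series({"a": 50, "b": 4, "c": 2}))
        vals = se.subsample_delta_ell(
            table, cat, target_total=6, iterations=10, seed=0, exclude_set="regulon"
        )
        # with gene a excluded only 6 mutations remain; every draw is the full set
        rest = se.GeneMutationTable(pd.Series({"b": 4, "c": 2}))
        assert np.allclose(vals, se.delta_ell(rest, cat.excluding("regulon")))


class TestPoissonPvalues:
    def test_boundary_and_worked_example(self):
        assert se.poisson_gene_pvalue(0, 10, 100.0, 100.0, 10) == pytest.approx(1.0)
        # lambda = 2, n = 4: 1 - e^-2 (1 + 2 + 2 + 4/3)
        p = se.poisson_gene_pvalue(4, 20, 100.0, 100.0, 10)
        assert p == pytest.approx(1 - math.exp(-2) * (1 + 2 + 2 + 4 / 3), abs=1e-12)

    def test_matches_term_summation_oracle(self):
        for lam in (0.3, 2.0, 7.5, 20.0):
            for n in (0, 1, 3, 10, 50):
                # catalog chosen so lambda comes out exactly as requested
                p = se.poisson_gene_pvalue(n, 100, lam, 1.0, 100)
                # stable term-by-term oracle: accumulate pmf recursively
                term = math.exp(-lam)
                cdf = 0.0
                for k in range(n):
                    cdf += term
                    term *= lam / (k + 1)
                assert p == pytest.approx(1 - cdf, abs=1e-12)

    def test_tail_monotone_in_count(self):
        ps = [se.poisson_gene_pvalue(n, 100, 2.0, 1.0, 100) for n in range(10)]
        assert np.all(np.diff(ps) < 0)


class TestCriticalPvalue:
    def test_alpha_one_admits_every_filtered_gene(self):
        p = [0.5, 0.2, 0.9]
        lam = [1.0, 1.0, 1.0]
        out = se.critical_pvalue(p, lam, alpha=1.0, observed_counts=[3, 5, 4])
        assert out == 0.9

    def test_no_signal_yields_empty_set(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.5, 500)
        lam = np.full(500, counts.sum() / 500)
        pvals = se.poisson_gene_pvalue(counts, counts.sum(), 1.0, 1.0, 500)
        # With length-proportional null counts, few if any genes clear P*
        pstar = se.critical_pvalue(pvals, lam, alpha=0.05, observed_counts=counts)
        n_sig = int(np.sum((pvals <= pstar) & (counts >= 3))) if pstar > 0 else 0
        assert n_sig <= 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            se.critical_pvalue([], [])

    def test_significant_genes_match_brute_force_refilter(self, small_catalog):
        spec = se.SyntheticSpec(strains=("WT",), regimes=("1day",),
                                target_mutations=800, n_planted=5)
        tables, _ = se.generate_gene_counts(spec, small_catalog, seed=9)
        res = se.gene_enrichment(tables["WT_1day"], small_catalog)
        brute = {
            g
            for g in small_catalog.lengths.index
            if res.pvalues[g] <= res.p_star and res.counts[g] >= 3
        } if res.p_star > 0 else set()
        assert se.significant_genes(res) == brute == res.significant


class TestRegionBinomial:
    def test_boundaries_and_worked_example(self):
        assert se.region_binomial_test(0, 10, 0.03) == pytest.approx(1.0)
        assert se.region_binomial_test(2, 2, 0.5) == pytest.approx(0.25)

    def test_matches_enumeration_for_small_totals(self):
        for n_total in (1, 5, 12):
            for l in (0.03, 0.3, 0.7):
                for n_region in range(n_total + 1):
                    p = se.region_binomial_test(n_region, n_total, l)
                    brute = sum(
                        math.comb(n_total, k) * l**k * (1 - l) ** (n_total - k)
                        for k in range(n_region, n_total + 1)
                    )
                    assert p == pytest.approx(brute, abs=1e-12)

    def test_fraction_difference_two_sided(self):
        obs, p, null = se.fraction_difference_test(30, 100, 2, 100, 0.05,
                                                   iterations=2000, seed=0)
        assert obs == pytest.approx(0.28)
        assert p < 0.01
        _, p_null, _ = se.fraction_difference_test(5, 100, 6, 100, 0.05,
                                                   iterations=2000, seed=0)
        assert p_null > 0.1


class TestEffectiveLengths:
    def test_single_codon_atg_fully_nonsynonymous(self):
        # Met has a unique codon: all 9 point substitutions are nonsynonymous
        cat = se.effective_gene_lengths({"g": "ATG"})
        assert cat.lengths["g"] == pytest.approx(3.0)

    def test_fourfold_degenerate_third_position(self):
        # GGN = Gly: third-position substitutions are all synonymous
        cat = se.effective_gene_lengths({"g": "GGT"})
        codon = "GGT"
        brute = 0.0
        from Bio.Data import CodonTable

        tab = CodonTable.unambiguous_dna_by_id[11]
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                aa = tab.forward_table.get(alt)
                if aa is None or aa != "G":
                    brute += 1 / 3
        assert cat.lengths["g"] == pytest.approx(brute)
        assert cat.lengths["g"] < 3.0  # third position contributes nothing

    def test_doubling_doubles_length_and_stop_is_trimmed(self):
        one = se.effective_gene_lengths({"g": "ATGGGT"}).lengths["g"]
        two = se.effective_gene_lengths({"g": "ATGGGTATGGGT"}).lengths["g"]
        with_stop = se.effective_gene_lengths({"g": "ATGGGTTAA"}).lengths["g"]
        assert two == pytest.approx(2 * one)
        assert with_stop == pytest.approx(one)

    def test_errors_name_the_gene(self):
        with pytest.raises(ValueError, match="badlen"):
            se.effective_gene_lengths({"badlen": "ATGG"})
        with pytest.raises(ValueError, match="stopgene"):
            se.effective_gene_lengths({"stopgene": "ATGTAAGGT"})


def test_null_fdr_of_pstar_procedure_controlled(small_catalog):
    """Under length-proportional Poisson counts the realized FDR stays <= alpha."""
    rng = np.random.default_rng(12)
    L = small_catalog.lengths.to_numpy()
    false_rates = []
    for rep in range(60):
        lam = 400 * L / L.sum()
        counts = np.random.default_rng(1000 + rep).poisson(lam)
        table = se.GeneMutationTable(pd.Series(counts, index=small_catalog.lengths.index))
        res = se.gene_enrichment(table, small_catalog, alpha=0.05)
        n_sig = len(res.significant)
        false_rates.append(1.0 if n_sig else 0.0)  # every discovery is false here
    # expected false-discovery proportion bounded by alpha within MC error
    fr = np.mean(false_rates)
    assert fr <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(false_rates))
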
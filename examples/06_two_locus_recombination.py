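"""Two linked loci in a population with a seed bank.

Compares trajectory correlations under complete linkage vs free
recombination -- the statistical-dependence proxy used to reason about
recombination rates from pooled time series.
"""

import numpy as np

import seedbankevo as se

for r_rec, label in [(0.0, "complete linkage"), (1.0, "free recombination")]:
    r2s = []
    for rep in range(40):
        params = se.TwoLocusParams(
            A=500, D=200, c=5.0, generations=150, seed=rep,
            init_freqs=(0.2, 0.2),
            init_haplotype_freqs=(0.8, 0.0, 0.0, 0.2),
            r_rec=r_rec,
        )
        res = se.run_two_locus(params)
        r2 = res.squared_correlation()
        if not np.isnan(r2):
            r2s.append(r2)
    print(f"{label:18s} (r_rec={r_rec}): mean r^2 between allele "
          f"trajectories = {np.mean(r2s):.3f} over {len(r2s)} runs")

print(
    "\nUnder complete linkage the two alleles ride the same genomic "
    "background and\ntheir frequency trajectories are nearly perfectly "
    "correlated; free\nrecombination decouples them toward the independent-"
    "loci baseline."
)
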
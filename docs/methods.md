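# Methods

## The seed-bank Wright–Fisher model

A population holds a constant number *A* of active individuals and *D* of
dormant ones. Each generation applies, in order: metabolic exchange,
mutation, selection/reproduction. The model assumes discrete
non-overlapping generations, a constant environment within a run, beneficial
mutations only (the rapid frequency rises that pooled sequencing resolves
are selection-driven; neutral and deleterious inputs are out of scope), an
infinite-sites genome with no back-mutation, and no recombination in the
single-locus simulator.

**Exchange.** Per-individual transition probabilities are *c/A* (active →
dormant) and *c/D* (dormant → active), giving geometric dwell times with
mean ⟨T_d⟩ = D/c and variance (1 − c/D)/(c/D)². Independent binomial draws
for the two directions rarely agree, so compartment sizes would drift. We
balance both directions to the randomized-rounded average of the two
binomial totals, returning surplus movers / recruiting deficits uniformly
over individuals. This keeps the expected throughput exactly *c* per
direction, so the realized dwell-time distribution stays geometric with mean
D/c (verified empirically: mean 99.8 ± 0.2 and variance 9,858 vs the
theoretical 9,900 at D = 1000, c = 10, n ≈ 2×10⁵ completed dwells). The
simpler alternative — truncating the larger flow to the smaller — delivers
E[min(X, Y)] < c exchanges per generation and inflates mean dwell times by
~20% at these parameters, which is why it was rejected.

**Mutation.** A Poisson(A·U_b·L_genome) number of beneficial mutations per
generation, each assigned to a distinct uniformly chosen active individual
(multivariate hypergeometric over lineage classes); double mutants within a
single generation are neglected, a Poisson-thinning approximation that is
immaterial at per-individual rates ≪ 1. Effects are exponential with scale
10⁻² by default and add on the log-fitness scale. Dormant individuals do
not replicate their genomes and acquire nothing.

**Reproduction.** Active individuals are resampled multinomially with
weights e^{X_i − X̄}; dormant individuals are carried unchanged. Bookkeeping
is by lineage class (genotype), which is distributionally identical to
per-individual records and keeps A = 10⁶ tractable.

**Recorded frequencies** default to the combined (A + D) scope because
pooled sequencing of a flask samples vegetative cells and spores together;
active-only recording is available. Trajectories are recorded every 10
generations by default, mirroring sparse experimental sampling.

**Two-locus variant.** Four haplotype counts replace lineage classes.
With probability *r* an offspring draws its two loci from independent
parents (free recombination at *r* = 1); otherwise it inherits a parental
haplotype. The recombination mechanism follows the main single-locus model's
compartment structure; it is an approximation to the full coalescent-style
treatment and is labelled as such.

## Trajectory statistics

Frequencies use the naive estimator f̂ = F/G; cells with zero depth are
missing, and missing cells contribute 0 to M(t) (the statistic sums
*detected* derived alleles) with a logged warning.

The hyperbolic model log₁₀M(t*) = log₁₀M(0) + [log₁₀M]_max·t*/(t*₁/₂+t*)
is fit by least squares with BFGS from a fixed 54-point grid: intercepts at
{min, mean, max} of log₁₀M, amplitudes at {0.5, 1, 2}× the observed range
(floored at 0.1 for flat series), and six log-spaced half-times spanning the
sampled window. The half-time is optimized as log t*₁/₂ — a monotone
reparameterization that enforces positivity without changing the model.
Convergence uses a gradient norm of 10⁻⁸. Standard errors are Gauss–Newton
asymptotics; residual-bootstrap intervals are available, with refits started
from the point estimate (the objective is locally smooth, so the full start
grid is unnecessary there). τ₁/₂ = t*₁/₂ × per-day generations, a required
user input because the per-day rate differs by transfer regime.

Per-mutation f_max is truncated to the first 6 observations by default so
cohorts with different sampling depths stay comparable. Direction ratios
f(τ+Δτ)/f(τ) are undefined at f(τ) = 0 (excluded); a crash to f(τ+Δτ) = 0
yields ratio 0 and is retained in the read-count path. For *simulated*
trajectories (`simulation_measures`) the ratio is instead computed only over
intervals with the allele present at both endpoints: the direction of change
of a lost allele is degenerate, and the survival-distribution contraction
that the simulator is meant to exhibit (toward 1 from above) is otherwise
masked by the point mass at 0.

Fate calling is a transparent threshold rule (detect 0.05, fix 0.95,
extinct 0.01) replacing HMM-based inference, and the interface accepts
externally produced fate labels. The relative log fitness X(t) uses the
natural log (standard for selection-like quantities; the base is an
argument). Generations per transfer average per-replicate log₂(N_f/N_i)
values — consistent with replicate-level reporting of means and standard
errors.

## Gene-level statistics

Multiplicity, Δℓ, and the Poisson P-values follow the definitions in the
README. Genes with n_i = 0 contribute 0 to Δℓ (the n log n → 0 limit);
natural log throughout. Δℓ ≥ 0 always, since Δℓ = n_tot × KL(observed ‖
length-proportional) — this identity is exercised as a property test.

The critical threshold P* is the largest observed P such that the expected
number of *null* genes reaching significance — a Poisson draw at the gene's
null rate λ_i = n_tot·L_i/(L̄·N_genes) that both passes the n_i ≥ 3 count
filter and attains a tail P-value ≤ P — divided by the observed number of
discoveries is at most α. The count filter gates significance testing only;
n_tot includes all mutations. A plain Benjamini–Hochberg alternative is
selectable. Effective nonsynonymous lengths count, per codon position, the
fraction of the three point substitutions that change the amino acid
(substitutions to stop count as nonsynonymous) under NCBI table 11; a
trailing stop codon is trimmed, internal stops are errors.

## Convergence/divergence

Significant-set overlaps use the exact two-set hypergeometric null
(validated by exhaustive subset enumeration); upper tail = convergence,
lower tail = divergence. ⟨ΔM⟩ compares relative multiplicities over the
*union* of the two significant sets by default (genes absent from one
cohort enter with count 0); intersection is selectable. The null randomizes
the gene-by-cohort count matrix with both margins fixed using Patefield's
algorithm, i.e. the multiple-hypergeometric permutation null — the same
null the chi-square enumeration test validates. Z⟨ΔM⟩ > 0 means divergence.
Because the null of ⟨ΔM⟩ is right-skewed, the normal-approximation p-value
is complemented by an empirical-quantile p-value. Skellam rates default to
each cohort's expected gene counts under its total and the shared length
model; the per-gene scan reuses the survival-curve FDR rule with the
Skellam null's own tails.

## Synthetic data

The generator emulates the study design the statistics assume: strain ×
transfer-regime cohorts, 5 replicate populations, 7 samples at 100-day
intervals, depth ~ 1 + NB(mean 100, shape 10), binomial read sampling, and
a detection floor of 10⁻² applied to the maximum observed frequency. True
trajectories come from the simulator or a logistic-sweep surrogate
(establishment times uniform, effects exponential with scale 10⁻², a 40%
fraction of clonal-interference losers that peak and decay). Gene counts
are Poisson with rates ∝ L_i, planted genes at 10× with cohort totals
calibrated to 2,000 mutations — the scale of five pooled replicate
populations over a multi-year daily-transfer experiment, and the regime in
which a 10× planted signal is recoverable at ≥ 90% sensitivity with FDR
≤ 5%. What the generator does *not* emulate: sequencing error beyond
binomial counting noise, depth heterogeneity along the genome, linkage
between mutations in the trajectory surrogate, and demographic fluctuations
between transfers. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated observation model, not robustness to
artifacts absent from it.

## Problem sizes used in tests and the acceptance script

Simulation checks run at reduced scale chosen as the package's own desk-scale
configuration: A = 10⁴, c = 10, D ∈ {10², 10³, 10⁴, 10⁵} (⟨T_d⟩ from 10 to
10⁴), 500 generations, 10 replicates per D, with the study's per-bp rate
U_b = 3.28×10⁻¹¹ and L_genome = 4.29×10⁶ so the Poisson supply scales with
A automatically (≈1.4/generation at A = 10⁴ vs ≈140.7 at A = 10⁶ — the
latter verified directly over a short large-A run). Neutral oracles use
A = 100 with 10⁴ replicates. Monte-Carlo assertions use 3-standard-error
bands throughout.

## Known limitations

- The exchange-balancing rule preserves per-individual marginals and mean
  throughput but makes the two directional flows equal within a generation;
  within-generation flow variance is halved relative to fully independent
  binomials (dwell-time and equilibrium properties are unaffected).
- The P* construction depends on the Poisson null being correctly scaled;
  heavily overdispersed mutation counts would need a negative-binomial null
  that is not implemented.
- The two-locus model treats recombination as gamete reshuffling among
  active individuals only; dormant recombination (e.g. transformation of
  spore DNA) is not modelled.
- Z⟨ΔM⟩'s normal p-value can be anticonservative for small gene universes;
  prefer the empirical p-value below ~30 genes.
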
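"""Synthetic pooled-sequencing datasets with known ground truth.

Emulates the observable structure of a serially transferred
evolve-and-resequence experiment: a handful of strain x transfer-regime
cohorts, 5 replicate populations each, sampled at ~7 timepoints, with
allele frequencies observed through binomial read sampling at realistic
depth and a detection floor of order 1e-2.  True frequency trajectories come
either from the seed-bank Wright-Fisher simulator or from a fast parametric
logistic-sweep surrogate; gene-level mutation counts follow a
length-proportional Poisson null with planted enriched genes; synthetic
genomes provide in-frame coding sequences so site counting runs end to end.

Everything is regenerable bit-identically from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parallelism import GeneCatalog, GeneMutationTable, effective_gene_lengths
from .simulate import SeedBankParams, run_simulation
from .trajectories import TrajectoryMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticGenome",
    "generate_trajectory_dataset",
    "generate_gene_counts",
    "generate_genome",
]

_LOG2_10 = math.log2(10.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic dataset.

    Defaults mirror the study design this package analyzes: 2 strains x a
    transfer regime, 5 replicate populations, 7 samples at 100-day intervals,
    ~100x mean coverage, and a detection floor of 0.01 (pooled sequencing
    resolves frequencies down to about 1e-2).
    """

    strains: tuple = ("WT", "dspo0A")
    regimes: tuple = ("1day",)
    n_populations: int = 5
    sample_days: tuple = (100, 200, 300, 400, 500, 600, 700)
    per_day_generations: float = _LOG2_10  # 1:10 dilution, log2(10) per daily transfer
    depth_mean: float = 100.0
    depth_shape: float = 10.0
    detection_floor: float = 0.01
    truth_model: str = "logistic"  # or "simulator"
    mean_mutations_per_population: float = 30.0
    sweep_s_scale: float = 1e-2
    loss_fraction: float = 0.4
    init_frequency: float = 1e-3
    # seed-bank simulator backing (used when truth_model == "simulator")
    sim_params: SeedBankParams = field(
        default_factory=lambda: SeedBankParams(
            A=10**4, D=10**3, c=10.0, generations=2300, seed=0
        )
    )
    # gene-count generation
    n_genes: int = 1000
    target_mutations: int = 2000
    n_planted: int = 10
    planted_multiplier: float = 10.0
    # genome generation
    genome_n_genes: int = 200
    gene_length_mean: float = 900.0
    gene_length_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean < 1:
            raise ValueError("mean depth must be >= 1")
        if self.planted_multiplier < 1:
            raise ValueError("planted multipliers must be >= 1")
        if not 0 < self.detection_floor < 1:
            raise ValueError("detection floor must lie in (0, 1)")


@dataclass
class GroundTruth:
    """True (pre-observation) state backing a synthetic dataset."""

    trajectories: pd.DataFrame  # population_id, mutation_id, day, generations, true_frequency
    fates: pd.DataFrame  # population_id, mutation_id, true_fate, detected
    enriched_genes: dict = field(default_factory=dict)  # cohort -> set of planted genes
    spec: SyntheticSpec | None = None


def _sample_depths(rng: np.random.Generator, spec: SyntheticSpec, size: int) -> np.ndarray:
    """Shifted negative binomial depths (gamma-Poisson mixture, min 1)."""
    shape = spec.depth_shape
    lam = rng.gamma(shape, (spec.depth_mean - 1) / shape, size=size)
    return 1 + rng.poisson(lam)


def _logistic_truth(
    rng: np.random.Generator, spec: SyntheticSpec, tau_grid: np.ndarray
) -> tuple:
    """Parametric surrogate trajectories on the generation grid.

    Each mutation establishes at a uniform time with a beneficial effect
    drawn from an exponential distribution and rises logistically; a fraction
    are clonal-interference losers that peak and then decay.
    """
    n_mut = rng.poisson(spec.mean_mutations_per_population)
    tau_max = tau_grid[-1] if len(tau_grid) else 0.0
    rows = []
    fates = []
    for m in range(n_mut):
        s = rng.exponential(spec.sweep_s_scale)
        t0 = rng.uniform(0, tau_max)
        f0 = spec.init_frequency
        dt = tau_grid - t0
        with np.errstate(over="ignore"):
            grow = f0 * np.exp(s * np.clip(dt, 0, None))
        f = grow / (1 + grow - f0)
        f[dt < 0] = 0.0
        if rng.random() < spec.loss_fraction:
            # loser: peaks midway then decays at a comparable rate
            t_peak = rng.uniform(t0, tau_max + 1)
            decay = np.clip(tau_grid - t_peak, 0, None)
            f = f * np.exp(-2 * s * decay)
        f = np.clip(f, 0.0, 1.0)
        rows.append(f)
        if f[-1] >= 0.95:
            fates.append("fixed")
        elif f.max() >= 0.05 and f[-1] <= 0.01:
            fates.append("extinct")
        else:
            fates.append("segregating")
    mat = np.vstack(rows) if rows else np.zeros((0, len(tau_grid)))
    return mat, fates


def _simulator_truth(
    spec: SyntheticSpec, seed: int, tau_grid: np.ndarray
) -> tuple:
    """True trajectories from a seed-bank Wright-Fisher run, interpolated
    onto the requested generation grid."""
    gens = int(math.ceil(tau_grid[-1])) if len(tau_grid) else 0
    params = replace(spec.sim_params, generations=max(gens, 1))
    res = run_simulation(params, seed=seed, record_dwell_times=False)
    ids, mat = res.frequency_array()
    if not ids:
        return np.zeros((0, len(tau_grid))), []
    sampled = np.vstack(
        [np.interp(tau_grid, res.sample_generations, mat[i]) for i in range(len(ids))]
    )
    fates = []
    for f in sampled:
        if f[-1] >= 0.95:
            fates.append("fixed")
        elif f.max() >= 0.05 and f[-1] <= 0.01:
            fates.append("extinct")
        else:
            fates.append("segregating")
    return sampled, fates


def generate_trajectory_dataset(
    spec: SyntheticSpec,
    catalog: GeneCatalog | None = None,
    seed: int | None = None,
) -> tuple:
    """Synthetic pooled-sequencing trajectory table plus its ground truth.

    Observation model: per timepoint the depth ``G`` is drawn from the
    coverage model and the alternate-read count ``F ~ Binomial(G, f_true)``.
    Mutations whose estimated frequency never reaches the detection floor are
    omitted from the observable table but retained in the ground truth.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    days = np.asarray(spec.sample_days, dtype=float)
    tau_grid = days * spec.per_day_generations

    gene_ids = list(catalog.lengths.index) if catalog is not None else None
    gene_p = None
    if catalog is not None:
        L = catalog.lengths.to_numpy(dtype=float)
        gene_p = L / L.sum()

    obs_rows = []
    truth_rows = []
    fate_rows = []
    mut_counter = 0
    for strain in spec.strains:
        for regime in spec.regimes:
            for rep in range(spec.n_populations):
                pop = f"{strain}_{regime}_r{rep}"
                if spec.truth_model == "logistic":
                    mat, fates = _logistic_truth(rng, spec, tau_grid)
                elif spec.truth_model == "simulator":
                    mat, fates = _simulator_truth(
                        spec, int(rng.integers(2**31)), tau_grid
                    )
                else:
                    raise ValueError(f"unknown truth model {spec.truth_model!r}")
                for i in range(mat.shape[0]):
                    mid = f"m{mut_counter}"
                    mut_counter += 1
                    if gene_ids is not None:
                        gene = gene_ids[rng.choice(len(gene_ids), p=gene_p)]
                    else:
                        gene = "NA"
                    anno = "nonsynonymous" if rng.random() < 0.7 else "synonymous"
                    depths = _sample_depths(rng, spec, len(days))
                    alts = rng.binomial(depths, mat[i])
                    fhat = alts / depths
                    detected = bool(fhat.max() >= spec.detection_floor)
                    for j, day in enumerate(days):
                        truth_rows.append(
                            (pop, mid, day, tau_grid[j], mat[i, j])
                        )
                        if detected:
                            obs_rows.append(
                                (
                                    mid, pop, strain, regime, gene, anno,
                                    day, tau_grid[j], int(alts[j]), int(depths[j]),
                                )
                            )
                    fate_rows.append((pop, mid, fates[i], detected))

    obs = pd.DataFrame(
        obs_rows,
        columns=[
            "mutation_id", "population_id", "strain", "regime", "gene_id",
            "annotation_class", "day", "generations", "alt_count", "depth",
        ],
    )
    truth = GroundTruth(
        trajectories=pd.DataFrame(
            truth_rows,
            columns=["population_id", "mutation_id", "day", "generations", "true_frequency"],
        ),
        fates=pd.DataFrame(
            fate_rows, columns=["population_id", "mutation_id", "true_fate", "detected"]
        ),
        spec=spec,
    )
    return TrajectoryMatrix(obs), truth


def generate_gene_counts(
    spec: SyntheticSpec,
    catalog: GeneCatalog,
    seed: int | None = None,
    planted: Mapping[str, Sequence] | None = None,
) -> tuple:
    """Per-cohort gene mutation counts with planted enriched genes.

    Counts are Poisson with rates proportional to effective gene length,
    multiplied by ``planted_multiplier`` for planted genes, and calibrated so
    the expected cohort total equals ``target_mutations``.  ``planted``
    optionally fixes the planted gene sets per cohort; by default each cohort
    receives ``n_planted`` genes sampled independently.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    L = catalog.lengths.to_numpy(dtype=float)
    genes = list(catalog.lengths.index)
    tables = {}
    enriched = {}
    for strain in spec.strains:
        for regime in spec.regimes:
            cohort = f"{strain}_{regime}"
            if planted is not None and cohort in planted:
                chosen = list(planted[cohort])
            else:
                chosen = [genes[i] for i in rng.choice(len(genes), spec.n_planted, replace=False)]
            mult = np.ones(len(genes))
            idx = [genes.index(g) for g in chosen]
            mult[idx] = spec.planted_multiplier
            rate = L * mult
            lam = spec.target_mutations * rate / rate.sum()
            counts = rng.poisson(lam)
            tables[cohort] = GeneMutationTable(pd.Series(counts, index=genes))
            enriched[cohort] = set(chosen)
    truth = GroundTruth(
        trajectories=pd.DataFrame(),
        fates=pd.DataFrame(),
        enriched_genes=enriched,
        spec=spec,
    )
    return tables, truth


@dataclass
class SyntheticGenome:
    """A synthetic bacterial genome fixture: catalog + sequences + features."""

    catalog: GeneCatalog
    coding_sequences: dict
    genome_sequence: str
    features: pd.DataFrame  # GFF3-style: seqid, start, end, strand, gene_id


_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_genome(spec: SyntheticSpec, seed: int | None = None) -> SyntheticGenome:
    """Random in-frame coding sequences on a single synthetic contig.

    Gene lengths (in bp, excluding the stop codon) are log-normal with the
    configured mean; every CDS starts with ATG, contains no internal stops,
    ends with a stop codon, and genes alternate strands along the contig with
    short intergenic spacers.  Deterministic per seed.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mu = math.log(spec.gene_length_mean) - spec.gene_length_sigma**2 / 2
    raw = rng.lognormal(mu, spec.gene_length_sigma, size=spec.genome_n_genes)
    n_codons = np.maximum((raw / 3).round().astype(int), 10)

    sequences = {}
    pieces = []
    feat_rows = []
    pos = 0
    for i, nc in enumerate(n_codons):
        gene = f"gene{i:04d}"
        body = rng.choice(len(_SENSE_CODONS), size=nc - 1)
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in body)
        stop = _STOPS[int(rng.integers(3))]
        full = cds + stop
        sequences[gene] = full
        strand = "+" if i % 2 == 0 else "-"
        placed = full if strand == "+" else full[::-1].translate(_COMPLEMENT)
        spacer = "".join(rng.choice(list("ACGT"), size=50))
        pieces.append(placed)
        pieces.append(spacer)
        start = pos + 1  # 1-based inclusive, GFF3 convention
        end = pos + len(full)
        feat_rows.append(("contig1", start, end, strand, gene))
        pos = end + 50
    genome = "".join(pieces)
    catalog = effective_gene_lengths(sequences)
    features = pd.DataFrame(
        feat_rows, columns=["seqid", "start", "end", "strand", "gene_id"]
    )
    return SyntheticGenome(
        catalog=catalog,
        coding_sequences=sequences,
        genome_sequence=genome,
        features=features,
    )
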
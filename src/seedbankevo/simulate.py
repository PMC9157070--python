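"""Forward-time Wright-Fisher simulation with a seed bank.

The population holds ``A`` active individuals and ``D`` dormant individuals.
Each generation consists of three steps:

1. **Metabolic exchange** -- every active individual enters dormancy with
   probability ``c/A`` and every dormant individual resuscitates with
   probability ``c/D``, so on average ``c`` individuals move each way and the
   compartment sizes stay constant.  Dwell times in the seed bank are
   geometric with success probability ``c/D`` and mean ``<Td> = D/c``.
2. **Mutation** -- a Poisson(``A*Ub*Lgenome``) number of beneficial mutations
   arises among active individuals; dormant individuals do not replicate
   their genomes and acquire none.  Fitness effects are drawn from an
   exponential distribution of beneficial effects.
3. **Selection and reproduction** -- the next generation of ``A`` active
   individuals is drawn multinomially with weights ``exp(s_i)`` where
   ``s_i = X_i - Xbar`` is the selection coefficient of lineage ``i`` relative
   to the current active mean log fitness.  Dormant individuals do not
   reproduce.

Bookkeeping is by lineage class (a genotype shared by many individuals)
rather than per individual, which makes ``A = 10**6`` tractable while being
distributionally identical.  Mutations follow the infinite-sites convention:
each new mutation receives a fresh integer identifier and there is no
back-mutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SeedBankParams",
    "LineageState",
    "SimulationResult",
    "TwoLocusParams",
    "TwoLocusResult",
    "step_metabolic_exchange",
    "step_mutation",
    "step_selection_reproduction",
    "run_simulation",
    "run_replicates",
    "run_two_locus",
    "mean_dormancy_time",
    "active_dormant_ratio",
]


class ConfigurationError(ValueError):
    """Raised when simulation parameters are inconsistent."""


@dataclass(frozen=True)
class SeedBankParams:
    """Configuration of a seed-bank Wright-Fisher run.

    Parameters
    ----------
    A : int
        Number of active individuals (constant through time).
    D : int
        Number of dormant individuals (constant; 0 disables the seed bank).
    c : float
        Number of individuals exchanging metabolic state per generation.
        ``c/A`` is the per-individual probability of entering dormancy and
        ``c/D`` the per-individual probability of resuscitation.
    Ub : float
        Beneficial mutation rate per individual per base pair per generation.
    Lgenome : float
        Genome length in base pairs.
    dfe_scale : float
        Scale of the exponential distribution of beneficial fitness effects.
    generations : int
        Number of generations to simulate.
    replicates : int
        Number of independent replicate runs (replicate ``r`` uses
        ``seed + r``).
    seed : int
        Base RNG seed.
    """

    A: int
    D: int = 0
    c: float = 0.0
    Ub: float = 3.28e-11
    Lgenome: float = 4.29e6
    dfe_scale: float = 1e-2
    generations: int = 1000
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A < 1:
            raise ConfigurationError(f"A must be >= 1, got {self.A}")
        if self.D < 0:
            raise ConfigurationError(f"D must be >= 0, got {self.D}")
        if self.Ub < 0:
            raise ConfigurationError("Ub must be >= 0")
        if self.dfe_scale <= 0:
            raise ConfigurationError("dfe_scale must be > 0")
        if self.D == 0:
            if self.c != 0:
                raise ConfigurationError(
                    "c > 0 requires a dormant compartment (D > 0)"
                )
        else:
            if not 0 <= self.c <= min(self.A, self.D):
                raise ConfigurationError(
                    f"c must satisfy 0 <= c <= min(A, D); got c={self.c}"
                )
            if self.c == 0:
                warnings.warn(
                    "D > 0 with c = 0: the seed bank is permanently inert",
                    stacklevel=3,
                )

    @classmethod
    def with_exchange_fraction(cls, *, c_fraction_of_A: float, **kwargs) -> "SeedBankParams":
        """Build params giving ``c`` as a fraction of ``A`` instead of a count.

        The paper-style parameterization ``c = 1e-5 * A`` maps a per-active
        entry probability directly onto the exchange count.
        """
        A = kwargs["A"]
        return cls(c=c_fraction_of_A * A, **kwargs)


def mean_dormancy_time(params: SeedBankParams) -> float:
    """Mean number of generations spent dormant, ``<Td> = D/c``.

    Returns ``inf`` (with a warning) when ``c = 0`` and the seed bank never
    turns over.
    """
    if params.D == 0:
        return 0.0
    if params.c == 0:
        warnings.warn("c = 0: dormancy dwell time is infinite", stacklevel=2)
        return math.inf
    return params.D / params.c


def active_dormant_ratio(params: SeedBankParams) -> float:
    """Ratio of active to dormant individuals, ``K = A/D``."""
    if params.D == 0:
        return math.inf
    return params.A / params.D


@dataclass
class LineageState:
    """Mutable per-lineage state of the population at one generation.

    A lineage is a class of individuals sharing the same genotype (set of
    mutation identifiers) and log fitness.  ``active`` and ``dormant`` hold
    per-lineage counts; their sums are exactly ``A`` and ``D`` at all times.
    ``dormant_cohorts`` tallies dormant individuals by the generation they
    entered the seed bank (for dwell-time statistics only).
    """

    active: list
    dormant: list
    fitness: list
    mutations: list
    generation: int = 0
    dormant_cohorts: dict = field(default_factory=dict)
    dwell_samples: list = field(default_factory=list)
    record_dwell_times: bool = True

    @classmethod
    def monomorphic(cls, params: SeedBankParams) -> "LineageState":
        state = cls(
            active=[params.A],
            dormant=[params.D],
            fitness=[0.0],
            mutations=[()],
        )
        if params.D > 0:
            state.dormant_cohorts = {0: params.D}
        return state

    @classmethod
    def from_lineages(
        cls,
        lineages: Iterable[tuple],
        params: SeedBankParams,
    ) -> "LineageState":
        """Build a state from ``(active, dormant, fitness, mutations)`` tuples."""
        active, dormant, fitness, muts = [], [], [], []
        for a, d, x, m in lineages:
            active.append(int(a))
            dormant.append(int(d))
            fitness.append(float(x))
            muts.append(tuple(m))
        state = cls(active=active, dormant=dormant, fitness=fitness, mutations=muts)
        state.check_invariants(params)
        if params.D > 0:
            state.dormant_cohorts = {0: params.D}
        return state

    def check_invariants(self, params: SeedBankParams) -> None:
        if sum(self.active) != params.A:
            raise ValueError(
                f"active compartment holds {sum(self.active)}, expected {params.A}"
            )
        if sum(self.dormant) != params.D:
            raise ValueError(
                f"dormant compartment holds {sum(self.dormant)}, expected {params.D}"
            )
        if any(a < 0 for a in self.active) or any(d < 0 for d in self.dormant):
            raise ValueError("negative lineage count")

    def prune(self) -> None:
        """Drop lineage classes with no remaining individuals."""
        keep = [i for i, (a, d) in enumerate(zip(self.active, self.dormant)) if a or d]
        if len(keep) != len(self.active):
            self.active = [self.active[i] for i in keep]
            self.dormant = [self.dormant[i] for i in keep]
            self.fitness = [self.fitness[i] for i in keep]
            self.mutations = [self.mutations[i] for i in keep]

    def mutation_counts(self, scope: str = "combined") -> dict:
        """Per-mutation individual counts over the requested compartment scope."""
        counts: dict = {}
        if scope == "combined":
            weights = [a + d for a, d in zip(self.active, self.dormant)]
        elif scope == "active":
            weights = self.active
        else:
            raise ValueError(f"unknown frequency scope: {scope!r}")
        for w, muts in zip(weights, self.mutations):
            if not w:
                continue
            for m in muts:
                counts[m] = counts.get(m, 0) + w
        return counts


def _balance_movers(
    rng: np.random.Generator,
    moved: np.ndarray,
    stayers: np.ndarray,
    target: int,
) -> np.ndarray:
    """Adjust per-lineage mover counts so they sum to ``target``.

    A surplus is returned by sampling uniformly from the movers; a deficit is
    filled by recruiting uniformly from the individuals that had stayed
    (multivariate hypergeometric across lineages either way), keeping the
    exchange uniform over individuals.
    """
    total = int(moved.sum())
    if total > target:
        returned = rng.multivariate_hypergeometric(moved, total - target)
        return moved - returned
    if total < target:
        extra = rng.multivariate_hypergeometric(stayers, target - total)
        return moved + extra
    return moved


def step_metabolic_exchange(
    state: LineageState, params: SeedBankParams, rng: np.random.Generator
) -> LineageState:
    """Exchange individuals between the active and dormant compartments.

    Entry and exit counts are drawn binomially per lineage (probabilities
    ``c/A`` and ``c/D``); because the two independent draws rarely agree,
    both directions are then balanced to the rounded average of the two
    totals (surplus movers returned, deficits recruited, uniformly over
    individuals).  This keeps compartment sizes exactly constant while the
    expected throughput stays exactly ``c`` per direction, so dwell times
    remain geometric with mean ``D/c``.
    """
    if params.c == 0 or params.D == 0:
        if params.c > 0 and params.D == 0:
            raise ConfigurationError("c > 0 requires D > 0")
        return state

    active = np.asarray(state.active, dtype=np.int64)
    dormant = np.asarray(state.dormant, dtype=np.int64)
    p_in = params.c / params.A
    p_out = params.c / params.D
    n_in = rng.binomial(active, p_in)
    n_out = rng.binomial(dormant, p_out)
    total_in = int(n_in.sum())
    total_out = int(n_out.sum())
    both = total_in + total_out
    target = both // 2 + (1 if (both % 2) and rng.random() < 0.5 else 0)
    target = min(target, params.D, params.A)
    n_in = _balance_movers(rng, n_in, active - n_in, target)
    n_out = _balance_movers(rng, n_out, dormant - n_out, target)
    total_in = total_out = target

    if state.record_dwell_times and total_out > 0:
        # exits are uniform among dormant individuals, so conditionally on the
        # total they are multivariate-hypergeometric across entry cohorts
        gens = list(state.dormant_cohorts)
        counts = np.array([state.dormant_cohorts[g] for g in gens], dtype=np.int64)
        taken = rng.multivariate_hypergeometric(counts, total_out)
        for g, k in zip(gens, taken):
            if k:
                state.dwell_samples.extend([state.generation - g] * int(k))
                state.dormant_cohorts[g] -= int(k)
                if state.dormant_cohorts[g] == 0:
                    del state.dormant_cohorts[g]
    if state.record_dwell_times and total_in > 0:
        state.dormant_cohorts[state.generation] = (
            state.dormant_cohorts.get(state.generation, 0) + total_in
        )

    state.active = list(active - n_in + n_out)
    state.dormant = list(dormant + n_in - n_out)
    return state


def step_mutation(
    state: LineageState,
    params: SeedBankParams,
    rng: np.random.Generator,
    mutation_effects: dict | None = None,
) -> int:
    """Introduce new beneficial mutations among active individuals.

    Returns the number of mutations introduced this generation.  Each new
    mutation hits a distinct uniformly chosen active individual, founding a
    new single-individual lineage whose fitness is the parent's plus an
    exponential draw.
    """
    if params.Ub == 0:
        return 0
    supply = params.A * params.Ub * params.Lgenome
    n_new = int(rng.poisson(supply))
    if n_new == 0:
        return 0
    n_new = min(n_new, params.A)
    active = np.asarray(state.active, dtype=np.int64)
    carriers = rng.multivariate_hypergeometric(active, n_new)
    effects = rng.exponential(params.dfe_scale, size=n_new)
    next_id = 0 if mutation_effects is None else len(mutation_effects)
    if mutation_effects is None:
        mutation_effects = {}
    e = 0
    for i in np.nonzero(carriers)[0]:
        k = int(carriers[i])
        state.active[i] -= k
        for _ in range(k):
            s = float(effects[e])
            mid = next_id
            next_id += 1
            e += 1
            mutation_effects[mid] = s
            state.active.append(1)
            state.dormant.append(0)
            state.fitness.append(state.fitness[i] + s)
            state.mutations.append(state.mutations[i] + (mid,))
    return n_new


def step_selection_reproduction(
    state: LineageState, params: SeedBankParams, rng: np.random.Generator
) -> LineageState:
    """Resample the active compartment multinomially with weights e^{s_i}."""
    active = np.asarray(state.active, dtype=np.int64)
    fitness = np.asarray(state.fitness, dtype=np.float64)
    live = active > 0
    xbar = float(np.dot(active[live], fitness[live])) / params.A
    s = fitness - xbar
    # lineage weight = (count) * e^{s_i}; subtracting max(s) guards overflow
    w = active * np.exp(s - s[live].max(initial=0.0))
    total = w.sum()
    state.active = list(rng.multinomial(params.A, w / total))
    return state


@dataclass
class SimulationResult:
    """Output of one seed-bank Wright-Fisher run.

    ``trajectories`` maps mutation id to its frequency at each recorded
    sampling point (``sample_generations``), measured over ``frequency_scope``
    (combined active+dormant by default, matching pooled sequencing of
    vegetative cells and spores together).
    """

    params: SeedBankParams
    seed: int
    frequency_scope: str
    sample_generations: np.ndarray
    trajectories: dict
    mutation_effects: dict
    mean_fitness: np.ndarray
    dwell_times: np.ndarray
    mutation_supply: np.ndarray

    def frequency_array(self) -> tuple:
        """Return (mutation ids, mutations x timepoints frequency matrix)."""
        ids = sorted(self.trajectories)
        if not ids:
            return [], np.zeros((0, len(self.sample_generations)))
        mat = np.vstack([self.trajectories[m] for m in ids])
        return ids, mat

    def final_frequencies(self) -> dict:
        return {m: f[-1] for m, f in self.trajectories.items()}

    @property
    def fixed_mutations(self) -> set:
        return {m for m, f in self.trajectories.items() if f[-1] == 1.0}


def run_simulation(
    params: SeedBankParams,
    *,
    seed: int | None = None,
    sampling_interval: int = 10,
    frequency_scope: str = "combined",
    initial_lineages: Sequence[tuple] | None = None,
    record_dwell_times: bool = True,
    stop_when_monomorphic: bool = False,
) -> SimulationResult:
    """Run one replicate of the three-step seed-bank Wright-Fisher model.

    Parameters
    ----------
    sampling_interval : int
        Record mutation frequencies every this many generations (sparse
        recording mirrors the sparse sampling of serial-transfer experiments).
    frequency_scope : {"combined", "active"}
        Compartment(s) over which recorded frequencies are computed.
    initial_lineages : sequence of (active, dormant, fitness, mutations)
        Optional standing variation to start from, e.g. a marked neutral
        lineage for fixation-probability experiments.
    stop_when_monomorphic : bool
        Stop early once a single genotype remains (useful with ``Ub = 0``).
    """
    if frequency_scope not in ("combined", "active"):
        raise ValueError(f"unknown frequency scope: {frequency_scope!r}")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if initial_lineages is None:
        state = LineageState.monomorphic(params)
    else:
        state = LineageState.from_lineages(initial_lineages, params)
    state.record_dwell_times = record_dwell_times and params.D > 0

    denom = params.A + params.D if frequency_scope == "combined" else params.A
    mutation_effects: dict = {}
    traj: dict = {}
    sample_gens: list = []
    mean_fit: list = []
    supply: list = []

    def record() -> None:
        counts = state.mutation_counts(frequency_scope)
        n_prev = len(sample_gens)
        for m in set(traj) | set(counts):
            series = traj.setdefault(m, [0.0] * n_prev)
            series.append(counts.get(m, 0) / denom)
        sample_gens.append(state.generation)
        active = np.asarray(state.active)
        fitness = np.asarray(state.fitness)
        mean_fit.append(float(np.dot(active, fitness)) / params.A)

    record()
    for _ in range(params.generations):
        state.generation += 1
        step_metabolic_exchange(state, params, rng)
        n_new = step_mutation(state, params, rng, mutation_effects)
        supply.append(n_new)
        step_selection_reproduction(state, params, rng)
        state.prune()
        if state.generation % sampling_interval == 0:
            record()
        if stop_when_monomorphic and len(state.active) == 1:
            if state.generation % sampling_interval != 0:
                record()
            break

    return SimulationResult(
        params=params,
        seed=seed,
        frequency_scope=frequency_scope,
        sample_generations=np.asarray(sample_gens),
        trajectories={m: np.asarray(f) for m, f in traj.items()},
        mutation_effects=mutation_effects,
        mean_fitness=np.asarray(mean_fit),
        dwell_times=np.asarray(state.dwell_samples, dtype=np.int64),
        mutation_supply=np.asarray(supply, dtype=np.int64),
    )


def run_replicates(params: SeedBankParams, **kwargs) -> list:
    """Run ``params.replicates`` independent replicates (replicate r seeds with seed+r)."""
    return [
        run_simulation(params, seed=params.seed + r, **kwargs)
        for r in range(params.replicates)
    ]


# ---------------------------------------------------------------------------
# Two-locus model with recombination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoLocusParams:
    """Two biallelic loci segregating in an active/dormant population.

    ``r_rec`` is the per-individual per-generation probability that an
    offspring is a recombinant, drawing its two loci from independent
    parents.  ``init_haplotype_freqs`` orders haplotypes as
    (ab, Ab, aB, AB); when omitted, the two focal alleles are placed in
    maximal coupling consistent with ``init_freqs``.
    """

    A: int
    D: int = 0
    c: float = 0.0
    generations: int = 500
    seed: int = 0
    init_freqs: tuple = (0.1, 0.1)
    init_haplotype_freqs: tuple | None = None
    r_rec: float = 0.0
    s1: float = 0.0
    s2: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.r_rec <= 1):
            raise ConfigurationError("r_rec must lie in [0, 1]")
        if not all(0 <= p <= 1 for p in self.init_freqs):
            raise ConfigurationError("initial frequencies must lie in [0, 1]")
        # compartment structure checks reuse the single-locus validation
        SeedBankParams(A=self.A, D=self.D, c=self.c, Ub=0.0)

    def haplotype_freqs(self) -> np.ndarray:
        if self.init_haplotype_freqs is not None:
            h = np.asarray(self.init_haplotype_freqs, dtype=float)
            if h.shape != (4,) or abs(h.sum() - 1) > 1e-9 or (h < 0).any():
                raise ConfigurationError("init_haplotype_freqs must be a 4-simplex point")
            return h
        p1, p2 = self.init_freqs
        pab = min(p1, p2)  # maximal coupling: both alleles on one founder
        return np.asarray([1 - p1 - p2 + pab, p1 - pab, p2 - pab, pab])


@dataclass
class TwoLocusResult:
    params: TwoLocusParams
    seed: int
    sample_generations: np.ndarray
    freq1: np.ndarray
    freq2: np.ndarray

    def correlation(self) -> float:
        """Pearson correlation of the two allele-frequency trajectories."""
        f1, f2 = self.freq1, self.freq2
        if np.std(f1) == 0 or np.std(f2) == 0:
            return math.nan
        return float(np.corrcoef(f1, f2)[0, 1])

    def squared_correlation(self) -> float:
        r = self.correlation()
        return r * r


_HAP_ALLELE1 = np.array([0, 1, 0, 1])
_HAP_ALLELE2 = np.array([0, 0, 1, 1])


def run_two_locus(
    params: TwoLocusParams,
    *,
    seed: int | None = None,
    sampling_interval: int = 1,
    frequency_scope: str = "combined",
) -> TwoLocusResult:
    """Simulate two linked loci in the active/dormant compartment structure.

    Haplotype counts replace lineage classes; exchange and selection steps
    mirror the single-locus model, and with probability ``r_rec`` an offspring
    draws its two loci from independent parents (free recombination at
    ``r_rec = 1``).
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    h0 = params.haplotype_freqs()
    active = rng.multinomial(params.A, h0)
    dormant = rng.multinomial(params.D, h0) if params.D > 0 else np.zeros(4, dtype=np.int64)
    fitness = params.s1 * _HAP_ALLELE1 + params.s2 * _HAP_ALLELE2

    denom = params.A + params.D if frequency_scope == "combined" else params.A

    def freqs() -> tuple:
        tot = active + dormant if frequency_scope == "combined" else active
        return (
            float(tot @ _HAP_ALLELE1) / denom,
            float(tot @ _HAP_ALLELE2) / denom,
        )

    sample_gens = [0]
    f1, f2 = freqs()
    freq1, freq2 = [f1], [f2]

    for gen in range(1, params.generations + 1):
        if params.c > 0 and params.D > 0:
            n_in = rng.binomial(active, params.c / params.A)
            n_out = rng.binomial(dormant, params.c / params.D)
            both = int(n_in.sum()) + int(n_out.sum())
            target = both // 2 + (1 if (both % 2) and rng.random() < 0.5 else 0)
            target = min(target, params.D, params.A)
            n_in = _balance_movers(rng, n_in, active - n_in, target)
            n_out = _balance_movers(rng, n_out, dormant - n_out, target)
            active = active - n_in + n_out
            dormant = dormant + n_in - n_out
        if active.sum() != params.A:  # pragma: no cover - invariant guard
            raise RuntimeError("active compartment size drifted")
        p = active / params.A
        w = p * np.exp(fitness - float(p @ fitness))
        p_sel = w / w.sum()
        q1 = p_sel[1] + p_sel[3]
        q2 = p_sel[2] + p_sel[3]
        p_free = np.array(
            [(1 - q1) * (1 - q2), q1 * (1 - q2), (1 - q1) * q2, q1 * q2]
        )
        p_off = (1 - params.r_rec) * p_sel + params.r_rec * p_free
        active = rng.multinomial(params.A, p_off)
        if gen % sampling_interval == 0 or gen == params.generations:
            f1, f2 = freqs()
            sample_gens.append(gen)
            freq1.append(f1)
            freq2.append(f2)

    return TwoLocusResult(
        params=params,
        seed=seed,
        sample_generations=np.asarray(sample_gens),
        freq1=np.asarray(freq1),
        freq2=np.asarray(freq2),
    )
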
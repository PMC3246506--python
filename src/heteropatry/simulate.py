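"""The generation loop, the three-phase schedule, and run bookkeeping.

A run starts from ``initial_pop_size`` individuals whose 26 preference
alleles are drawn uniformly on (-1, 1) — non-discriminating phenotypes with
high preference for every niche — and whose mating genotype is rr (random
mating).  Each discrete, non-overlapping generation then:

1. computes every individual's response array Psi,
2. allocates reproductive output e and niche loads E,
3. computes density-dependent fitness f,
4. assigns mating pools and forms pairs,
5. gives each pair round(mean(f1, f2)) recruits, built from parental
   gametes with crossover and (phase-dependent) mutation,
6. replaces the parents with the recruits.

The phase schedule enforces random mating early on: mating-gene mutation is
disabled before ``mating_mutation_start`` (so the initial all-r population
cannot acquire the assortative allele), enabled until ``mutation_stop``,
after which *all* mutations are switched off (crossover is retained by
default — recombination is not mutation — and can be disabled too).

Reproducibility: a run is fully determined by (config, seed).  One
`numpy.random.Generator` drives everything, with a fixed draw order per
generation: pool sampling (one uniform per individual) -> pairing
(permutation + partner draws) -> preference-gamete blocks (templates,
crossover switches, mutation masks, perturbations) -> mating-gamete blocks
(template choices, flip mask).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import (
    DEFAULT_OMEGA,
    DEFAULT_RESOURCE_VALUES,
    DEFAULT_SIGNALS,
    A_ALLELE,
    R_ALLELE,
    Environment,
    Genome,
    SignalSet,
    assortative_mask,
    class_index,
    classify_phenotype,
    n_loci,
    response_matrix,
)
from .ecology import EcologyParams, niche_totals, population_fitness, reproductive_output
from .mating import MutationRates, assign_pools, form_pairs

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Population",
    "PhaseFlags",
    "GenerationRecord",
    "RunResult",
    "init_population",
    "phase_flags",
    "step_generation",
    "make_record",
    "run",
]


class ConfigError(ValueError):
    """A simulation parameter is missing, malformed or out of range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Every constant of a run; (config, seed) fully determines the output."""

    # population / genome
    initial_pop_size: int = 500
    n_hidden: int = 3
    init_weight_range: float = 1.0   # initial alleles uniform on (-range, range)
    omega: float = DEFAULT_OMEGA
    a_dominant: bool = True
    # environment
    resource_values: Tuple[float, ...] = DEFAULT_RESOURCE_VALUES
    signals: Tuple[Tuple[float, float], ...] = DEFAULT_SIGNALS
    suitability_threshold: float = 1.0
    # ecology
    phi: float = 3.0
    epsilon: float = 1.5
    abruptness: float = 2.5
    # mutation / recombination
    crossover_per_locus: float = 1e-4
    point_mut_per_allele: float = 0.01
    perturbation_range: float = 10.0
    allele_clamp: float = 20.0
    mating_mut_rate: float = 5e-4
    # schedule
    generations: int = 100_000
    mating_mutation_start: int = 20_000
    mutation_stop: int = 80_000
    crossover_after_stop: bool = True
    # mating details
    p0_partner_scope: str = "population"
    # recruit accounting per pair:
    #   "sum":        the pair contributes round(f1 + f2) recruits (default;
    #                 the variant that both lets the stated initial
    #                 population persist and avoids rounding-overshoot
    #                 collapses of homogeneous specialist lineages);
    #   "per_parent": each parent is replaced by round(mean(f1, f2)) recruits,
    #                 so the pair contributes 2 * round(mean);
    #   "mean":       the pair contributes round(mean(f1, f2)) — with phi = 3
    #                 this caps pair output at replacement and a population
    #                 of non-discriminating founders cannot persist.
    pair_fecundity: str = "sum"
    # logging
    snapshot_interval: int = 1000
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.initial_pop_size < 1:
            raise ConfigError(f"initial_pop_size must be >= 1, got {self.initial_pop_size}")
        if self.n_hidden < 1:
            raise ConfigError(f"n_hidden must be >= 1, got {self.n_hidden}")
        if self.init_weight_range <= 0:
            raise ConfigError("init_weight_range must be > 0")
        if self.omega <= 0:
            raise ConfigError("omega must be > 0")
        for name in ("phi", "epsilon", "abruptness", "perturbation_range", "allele_clamp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("crossover_per_locus", "point_mut_per_allele", "mating_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if not (0 <= self.mating_mutation_start <= self.mutation_stop):
            raise ConfigError(
                "phase boundaries must satisfy 0 <= mating_mutation_start <= mutation_stop"
            )
        if self.generations < 0:
            raise ConfigError(f"generations must be >= 0, got {self.generations}")
        if self.snapshot_interval < 1:
            raise ConfigError("snapshot_interval must be >= 1")
        if self.p0_partner_scope not in ("population", "pool"):
            raise ConfigError(f"unknown p0_partner_scope {self.p0_partner_scope!r}")
        if self.pair_fecundity not in ("per_parent", "mean", "sum"):
            raise ConfigError(f"unknown pair_fecundity {self.pair_fecundity!r}")
        # construct derived objects so their own validation fires
        self.environment()
        self.ecology_params()
        self.mutation_rates()
        return self

    # derived parameter objects -------------------------------------------------
    def environment(self) -> Environment:
        return Environment(
            resource_values=np.asarray(self.resource_values, dtype=float),
            signal_set=SignalSet(np.asarray(self.signals, dtype=float)),
            suitability_threshold=self.suitability_threshold,
        )

    def ecology_params(self) -> EcologyParams:
        return EcologyParams(self.phi, self.epsilon, self.abruptness)

    def mutation_rates(self) -> MutationRates:
        return MutationRates(
            crossover_per_locus=self.crossover_per_locus,
            point_mut_per_allele=self.point_mut_per_allele,
            perturbation_range=self.perturbation_range,
            allele_clamp=self.allele_clamp,
            mating_mut_rate=self.mating_mut_rate,
        )

    @property
    def n_loci(self) -> int:
        return n_loci(self.n_hidden)

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["resource_values"] = list(self.resource_values)
        d["signals"] = [list(s) for s in self.signals]
        return d


class Population:
    """One generation of exploiters, stored as flat arrays.

    ``pref``   : (n, 2, L) float — the two preference haplotypes of each
                 individual, in storage order;
    ``mating`` : (n, 2) int8 — mating alleles, 0 = r and 1 = a.
    """

    __slots__ = ("pref", "mating")

    def __init__(self, pref: np.ndarray, mating: np.ndarray):
        pref = np.asarray(pref, dtype=float)
        mating = np.asarray(mating, dtype=np.int8)
        if pref.ndim != 3 or pref.shape[1] != 2:
            raise ValueError(f"pref must be (n, 2, L), got {pref.shape}")
        if mating.shape != (pref.shape[0], 2):
            raise ValueError(f"mating must be (n, 2), got {mating.shape}")
        self.pref = pref
        self.mating = mating

    def __len__(self) -> int:
        return self.pref.shape[0]

    @property
    def n_loci(self) -> int:
        return self.pref.shape[2]

    def expressed(self) -> np.ndarray:
        """Codominant expressed weights, (n, L)."""
        return self.pref.mean(axis=1)

    def genome(self, i: int) -> Genome:
        alleles = (R_ALLELE, A_ALLELE)
        return Genome(
            self.pref[i].copy(),
            (alleles[int(self.mating[i, 0])], alleles[int(self.mating[i, 1])]),
        )

    def to_genomes(self) -> List[Genome]:
        return [self.genome(i) for i in range(len(self))]

    @classmethod
    def from_genomes(cls, genomes: Sequence[Genome]) -> "Population":
        if not genomes:
            raise ValueError("cannot build a population from zero genomes")
        pref = np.stack([g.pref for g in genomes])
        mating = np.array(
            [[1 if m == A_ALLELE else 0 for m in g.mating] for g in genomes],
            dtype=np.int8,
        )
        return cls(pref, mating)

    def copy(self) -> "Population":
        return Population(self.pref.copy(), self.mating.copy())


@dataclass(frozen=True)
class PhaseFlags:
    """Which stochastic genome-altering processes are active this generation."""

    mating_mutation_enabled: bool
    point_mutation_enabled: bool
    crossover_enabled: bool


def phase_flags(generation: int, config: SimulationConfig) -> PhaseFlags:
    """Three-phase schedule: mating-gene mutation off before
    ``mating_mutation_start``; all mutations off from ``mutation_stop``."""
    if generation < 0:
        raise ConfigError(f"generation must be >= 0, got {generation}")
    if generation < config.mating_mutation_start:
        return PhaseFlags(False, True, True)
    if generation < config.mutation_stop:
        return PhaseFlags(True, True, True)
    return PhaseFlags(False, False, config.crossover_after_stop)


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation summary used for trajectory plots and phase analysis."""

    generation: int
    size: int
    class_counts: Tuple[int, ...]        # 16 phenotype classes, psi_1 = MSB
    freq_r: float
    freq_a: float
    n_het_mating: int                    # ra genotypes
    n_het_pref: int                      # individuals with non-identical haplotypes
    mean_hap_divergence: float           # mean |h1 - h2| over loci and individuals
    n_unfit: int                         # phenotypes preferring an unsuitable niche

    FIELDS = (
        "generation",
        "size",
        *[f"class_{i:04b}" for i in range(16)],
        "freq_r",
        "freq_a",
        "n_het_mating",
        "n_het_pref",
        "mean_hap_divergence",
        "n_unfit",
    )

    def as_row(self) -> List[object]:
        return [
            self.generation,
            self.size,
            *self.class_counts,
            self.freq_r,
            self.freq_a,
            self.n_het_mating,
            self.n_het_pref,
            self.mean_hap_divergence,
            self.n_unfit,
        ]


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: SimulationConfig
    records: List[GenerationRecord]
    snapshots: Dict[int, Population]
    final_population: Optional[Population]
    termination: str  # "completed" | "extinct"


def init_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Initial population: all preference alleles uniform on the init range,
    all mating genotypes rr (non-discriminating random maters)."""
    config.validate()
    n = config.initial_pop_size
    L = config.n_loci
    pref = rng.uniform(-config.init_weight_range, config.init_weight_range, size=(n, 2, L))
    mating = np.zeros((n, 2), dtype=np.int8)
    return Population(pref, mating)


def make_record(
    population: Population, config: SimulationConfig, generation: int
) -> GenerationRecord:
    env = config.environment()
    psi = response_matrix(population.expressed(), env.signal_set.signals, config.omega)
    classes = classify_phenotype(psi)
    idx = class_index(classes)
    counts = np.bincount(idx, minlength=2 ** classes.shape[1])
    n = len(population)
    freq_a = float(population.mating.mean())
    het_mating = int(np.count_nonzero(population.mating[:, 0] != population.mating[:, 1]))
    hap_diff = np.abs(population.pref[:, 0, :] - population.pref[:, 1, :])
    het_pref = int(np.count_nonzero(hap_diff.max(axis=1) > 0))
    unfit = int(np.count_nonzero((classes[:, ~env.suitability] == 1).any(axis=1)))
    return GenerationRecord(
        generation=generation,
        size=n,
        class_counts=tuple(int(c) for c in counts),
        freq_r=1.0 - freq_a,
        freq_a=freq_a,
        n_het_mating=het_mating,
        n_het_pref=het_pref,
        mean_hap_divergence=float(hap_diff.mean()),
        n_unfit=unfit,
    )


def _make_gametes(
    population: Population,
    parent_idx: np.ndarray,
    config: SimulationConfig,
    flags: PhaseFlags,
    rng: np.random.Generator,
) -> Population:
    """Vectorised recruit formation for all offspring of one generation.

    ``parent_idx`` has shape (n_off, 2).  Draw order (block-wise over all
    offspring): preference templates, crossover switches, point-mutation
    masks, perturbations, mating templates, mating flip mask.
    """
    n_off = parent_idx.shape[0]
    L = population.n_loci
    rates = config.mutation_rates()

    templates = rng.integers(0, 2, size=(n_off, 2))
    if flags.crossover_enabled and rates.crossover_per_locus > 0:
        switches = rng.random((n_off, 2, L)) < rates.crossover_per_locus
        which = (templates[:, :, None] + np.cumsum(switches, axis=2)) % 2
    else:
        which = np.broadcast_to(templates[:, :, None], (n_off, 2, L))
    loci = np.arange(L)[None, None, :]
    pref = population.pref[parent_idx[:, :, None], which, loci].astype(float, copy=True)

    if flags.point_mutation_enabled and rates.point_mut_per_allele > 0:
        hit = rng.random((n_off, 2, L)) < rates.point_mut_per_allele
        delta = rng.uniform(-rates.perturbation_range, rates.perturbation_range, size=(n_off, 2, L))
        pref[hit] += delta[hit]
        np.clip(pref, -rates.allele_clamp, rates.allele_clamp, out=pref)

    m_templates = rng.integers(0, 2, size=(n_off, 2))
    mating = population.mating[parent_idx, m_templates]
    if flags.mating_mutation_enabled and rates.mating_mut_rate > 0:
        flips = rng.random((n_off, 2)) < rates.mating_mut_rate
        mating = mating ^ flips.astype(np.int8)
    return Population(pref, mating)


def step_generation(
    population: Population,
    config: SimulationConfig,
    generation: int,
    rng: np.random.Generator,
) -> Tuple[Optional[Population], GenerationRecord]:
    """Advance one generation.

    Returns the recruit population (or ``None`` on extinction, i.e. zero
    recruits) and the record describing the *current* population.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    env = config.environment()
    params = config.ecology_params()
    flags = phase_flags(generation, config)

    record = make_record(population, config, generation)

    psi = response_matrix(population.expressed(), env.signal_set.signals, config.omega)
    e = reproductive_output(psi, params.phi)
    totals = niche_totals(e)
    f = population_fitness(e, env, params, totals)

    classes = classify_phenotype(psi)
    assort = assortative_mask(population.mating, config.a_dominant)
    pools = assign_pools(classes, assort, rng)
    pairs = form_pairs(pools, rng, config.p0_partner_scope)
    if not pairs:
        return None, record

    pair_arr = np.asarray(pairs, dtype=np.int64)
    pair_sum = f[pair_arr[:, 0]] + f[pair_arr[:, 1]]
    if config.pair_fecundity == "mean":
        counts = np.floor(pair_sum / 2.0 + 0.5).astype(np.int64)
    elif config.pair_fecundity == "sum":
        counts = np.floor(pair_sum + 0.5).astype(np.int64)
    else:  # per_parent
        counts = 2 * np.floor(pair_sum / 2.0 + 0.5).astype(np.int64)
    keep = counts > 0
    if not np.any(keep):
        return None, record
    parent_idx = np.repeat(pair_arr[keep], counts[keep], axis=0)
    recruits = _make_gametes(population, parent_idx, config, flags, rng)
    return recruits, record


def run(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    progress: bool = False,
) -> RunResult:
    """Iterate the generation loop over the configured number of
    generations (or until extinction), collecting records and periodic
    full-genome snapshots."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = init_population(config, rng)
    records: List[GenerationRecord] = []
    snapshots: Dict[int, Population] = {}
    termination = "completed"
    iterator: Iterable[int] = range(config.generations)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, unit="gen")
    gen = 0
    for gen in iterator:
        if gen % config.snapshot_interval == 0:
            snapshots[gen] = population.copy()
        nxt, record = step_generation(population, config, gen, rng)
        records.append(record)
        if nxt is None:
            termination = "extinct"
            population = None  # type: ignore[assignment]
            break
        population = nxt
    if termination == "completed":
        records.append(make_record(population, config, config.generations))
        snapshots[config.generations] = population.copy()
    return RunResult(
        config=config,
        records=records,
        snapshots=snapshots,
        final_population=population,
        termination=termination,
    )
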
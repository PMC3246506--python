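"""Mating pools, pair formation, offspring counts, gametes and inheritance.

Mating is organised around five pools: p0 (random maters, genotype rr under
a-dominance) and p1..p4, one per niche.  Assortative maters join one of
p1..p4, sampled in proportion to their rounded (binary) response array —
a [1,0,0,0] specialist joins p1 with probability 1, a [1,0,1,0]
selective generalist joins p1 or p3 with probability 0.5 each.

Pairing draws the first member of each pair uniformly from the whole
unmated population; its partner comes uniformly from its own pool
(p1..p4), or from the whole unmated population if it is a p0 individual.
Assortative individuals therefore never *choose* a random mater, but can
be chosen by one.  Mated individuals are removed until nobody (or a single
unmatchable individual) is left.

Gametes: each parent contributes one preference haplotype — copied from a
uniformly chosen parental haplotype with a small per-locus probability of
switching template (crossover; linkage otherwise preserved) and a per-allele
point-mutation probability adding a uniform(-10, 10) perturbation, clamped
to [-20, 20] — plus one mating allele, copied from a uniformly chosen
parental allele and (when enabled) flipped r<->a with a small probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genome import (
    A_ALLELE,
    R_ALLELE,
    Genome,
)

__all__ = [
    "MutationRates",
    "assign_pools",
    "form_pairs",
    "offspring_count",
    "make_preference_gamete",
    "make_mating_gamete",
    "make_offspring",
    "punnett_expectation",
]

UNASSIGNED = -1  # assortative individuals whose rounded Psi is all-zero


@dataclass(frozen=True)
class MutationRates:
    """Recombination and mutation constants.

    crossover_per_locus : probability of switching template haplotype at
        each locus while copying a preference gamete (default 1e-4)
    point_mut_per_allele : per-allele probability of a point mutation on a
        preference gamete (default 0.01)
    perturbation_range : half-width of the uniform mutational perturbation,
        drawn on (-range, +range) (default 10)
    allele_clamp : weight values are clamped to [-clamp, +clamp] after
        mutation (default 20)
    mating_mut_rate : probability that a copied mating allele flips
        r <-> a (default 5e-4)
    """

    crossover_per_locus: float = 1e-4
    point_mut_per_allele: float = 0.01
    perturbation_range: float = 10.0
    allele_clamp: float = 20.0
    mating_mut_rate: float = 5e-4

    def __post_init__(self) -> None:
        for name in ("crossover_per_locus", "point_mut_per_allele", "mating_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.perturbation_range <= 0 or self.allele_clamp <= 0:
            raise ValueError("perturbation_range and allele_clamp must be > 0")


# ---------------------------------------------------------------------------
# Pools and pairing
# ---------------------------------------------------------------------------

def assign_pools(
    classes: np.ndarray,
    assortative: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign every individual to a mating pool.

    Parameters
    ----------
    classes : (n, k) binary phenotype classes (rounded response arrays)
    assortative : (n,) boolean mask of expressed mating behaviour
    rng : the simulation's random generator; one uniform deviate is drawn
        per individual, in index order, whether or not it is used

    Returns
    -------
    (n,) integer labels: 0 = p0 (random maters), 1..k = niche pools,
    -1 = unassigned (assortative with an all-zero class; such individuals
    skip mating this generation).
    """
    classes = np.asarray(classes, dtype=float)
    n, k = classes.shape
    assortative = np.asarray(assortative, dtype=bool)
    labels = np.zeros(n, dtype=np.int64)
    u = rng.random(n)  # fixed draw count for reproducibility

    row_sum = classes.sum(axis=1)
    eligible = assortative & (row_sum > 0)
    labels[assortative & ~eligible] = UNASSIGNED
    if np.any(eligible):
        probs = classes[eligible] / row_sum[eligible, None]
        cum = np.cumsum(probs, axis=1)
        # niche index = first cumulative bin exceeding the uniform draw
        pick = (u[eligible, None] > cum).sum(axis=1)
        labels[eligible] = pick + 1
    return labels


def form_pairs(
    pool_labels: np.ndarray,
    rng: np.random.Generator,
    p0_partner_scope: str = "population",
) -> List[Tuple[int, int]]:
    """Form mating pairs from a pool assignment.

    The first member of each pair is drawn uniformly from the unmated
    assigned individuals (realised as a single random permutation, which is
    distributionally equivalent); the partner is drawn uniformly from the
    first member's pool for p1..p4, or — for p0 — from the whole unmated
    population (``p0_partner_scope="population"``, the default) or from p0
    only (``"pool"``).  A first member with no eligible partner stays
    unmated but remains available as a partner for later draws.
    """
    if p0_partner_scope not in ("population", "pool"):
        raise ValueError(f"unknown p0_partner_scope {p0_partner_scope!r}")
    labels = np.asarray(pool_labels)
    n = labels.shape[0]
    if n == 0:
        return []
    assigned = np.flatnonzero(labels >= 0)
    if assigned.size < 2:
        return []
    order = rng.permutation(assigned)

    # membership lists with O(1) swap-remove
    pools: Dict[int, List[int]] = {}
    pos_pool = np.full(n, -1, dtype=np.int64)
    for i in assigned:
        lab = int(labels[i])
        members = pools.setdefault(lab, [])
        pos_pool[i] = len(members)
        members.append(int(i))
    everyone: List[int] = [int(i) for i in assigned]
    pos_all = np.full(n, -1, dtype=np.int64)
    pos_all[assigned] = np.arange(assigned.size)

    def _remove(lst: List[int], pos: np.ndarray, i: int) -> None:
        p = pos[i]
        last = lst[-1]
        lst[p] = last
        pos[last] = p
        lst.pop()
        pos[i] = -1

    mated = np.zeros(n, dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for i in order:
        i = int(i)
        if mated[i]:
            continue
        lab = int(labels[i])
        if lab == 0 and p0_partner_scope == "population":
            candidates = everyone
        else:
            candidates = pools[lab]
        if len(candidates) < 2:
            continue  # only itself remains eligible
        while True:
            j = candidates[int(rng.integers(len(candidates)))]
            if j != i:
                break
        for ind in (i, j):
            mated[ind] = True
            _remove(pools[int(labels[ind])], pos_pool, ind)
            _remove(everyone, pos_all, ind)
        pairs.append((i, j))
    return pairs


def offspring_count(f1: float, f2: float) -> int:
    """Number of offspring of a pair: the pair's mean fitness rounded to
    the nearest integer (half-values round up)."""
    if f1 < 0 or f2 < 0:
        raise ValueError("fitness values must be non-negative")
    return int(np.floor((f1 + f2) / 2.0 + 0.5))


# ---------------------------------------------------------------------------
# Gametes
# ---------------------------------------------------------------------------

def make_preference_gamete(
    genome: Genome,
    rates: MutationRates,
    rng: np.random.Generator,
    mutations_enabled: bool = True,
    crossover_enabled: bool = True,
) -> np.ndarray:
    """Produce one haploid preference chromosome from a parent.

    Copying starts from a uniformly chosen parental haplotype and walks the
    loci in chromosome order; at every locus the template haplotype
    switches with probability ``crossover_per_locus`` (before the locus is
    copied).  Point mutations then hit each allele independently with
    probability ``point_mut_per_allele``, adding a uniform perturbation and
    clamping to the allowed weight range.
    """
    loci = genome.n_loci
    template = int(rng.integers(2))
    if crossover_enabled and rates.crossover_per_locus > 0:
        switches = rng.random(loci) < rates.crossover_per_locus
    else:
        switches = np.zeros(loci, dtype=bool)
    which = (template + np.cumsum(switches)) % 2
    gamete = genome.pref[which, np.arange(loci)].copy()
    if mutations_enabled and rates.point_mut_per_allele > 0:
        hit = rng.random(loci) < rates.point_mut_per_allele
        if np.any(hit):
            delta = rng.uniform(
                -rates.perturbation_range, rates.perturbation_range, size=loci
            )
            gamete[hit] += delta[hit]
            np.clip(gamete, -rates.allele_clamp, rates.allele_clamp, out=gamete)
    return gamete


def make_mating_gamete(
    genome: Genome,
    rate: float,
    rng: np.random.Generator,
    mating_mut_enabled: bool = True,
) -> str:
    """Copy one mating allele from a uniformly chosen parental chromosome,
    flipping r <-> a with probability ``rate`` when mutation is enabled."""
    allele = genome.mating[int(rng.integers(2))]
    if mating_mut_enabled and rng.random() < rate:
        allele = A_ALLELE if allele == R_ALLELE else R_ALLELE
    return allele


def make_offspring(
    parent1: Genome,
    parent2: Genome,
    rates: MutationRates,
    rng: np.random.Generator,
    mutations_enabled: bool = True,
    crossover_enabled: bool = True,
    mating_mut_enabled: bool = True,
) -> Genome:
    """One diploid recruit: a preference gamete and a mating gamete from
    each parent (parent 1's gametes stored first)."""
    h1 = make_preference_gamete(parent1, rates, rng, mutations_enabled, crossover_enabled)
    h2 = make_preference_gamete(parent2, rates, rng, mutations_enabled, crossover_enabled)
    m1 = make_mating_gamete(parent1, rates.mating_mut_rate, rng, mating_mut_enabled)
    m2 = make_mating_gamete(parent2, rates.mating_mut_rate, rng, mating_mut_enabled)
    return Genome(np.stack([h1, h2]), (m1, m2))


# ---------------------------------------------------------------------------
# Mendelian oracle
# ---------------------------------------------------------------------------

def _classify_haplotype(hap: np.ndarray, refs: Sequence[np.ndarray]) -> str:
    for label, ref in zip("AB", refs):
        if np.array_equal(hap, ref):
            return label
    raise ValueError("parent haplotype does not match any reference haplotype")


def punnett_expectation(
    g1: Genome,
    g2: Genome,
    references: Tuple[np.ndarray, np.ndarray] | None = None,
) -> Dict[str, float]:
    """Exact Mendelian offspring-genotype distribution of a cross, ignoring
    mutation and crossover.

    Parents must be composed of two reference haplotypes A and B (passed
    explicitly, or inferred from the distinct haplotypes the parents carry).
    Returns probabilities over the unordered genotype classes
    {'AA', 'AB', 'BB'}; a heterozygote x heterozygote cross yields the
    familiar 1:2:1 ratio.
    """
    if references is None:
        distinct: List[np.ndarray] = []
        for g in (g1, g2):
            for hap in g.pref:
                if not any(np.array_equal(hap, d) for d in distinct):
                    distinct.append(hap)
        if len(distinct) > 2:
            raise ValueError(
                "parents carry more than two distinct haplotypes; pass "
                "reference haplotypes explicitly"
            )
        while len(distinct) < 2:
            distinct.append(None)  # type: ignore[arg-type]
        references = (distinct[0], distinct[1])

    def labels(g: Genome) -> List[str]:
        return [
            _classify_haplotype(h, [r for r in references if r is not None])
            for h in g.pref
        ]

    dist: Dict[str, float] = {}
    for a in labels(g1):
        for b in labels(g2):
            key = "".join(sorted(a + b))
            dist[key] = dist.get(key, 0.0) + 0.25
    return dist
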
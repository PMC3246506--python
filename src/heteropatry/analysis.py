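"""Statistics on simulated populations.

This module hosts the analysis battery used on simulator output:

* unfit-phenotype fractions (a phenotype is *unfit* when its binary class
  prefers at least one unsuitable niche);
* the maximum-likelihood chi-square (likelihood-ratio G) test on 2x2
  count tables, ``G = 2 * sum O * ln(O / E)``;
* the mutation-robustness resampling assay: ``K = P * (P - 1)`` single
  mutants drawn with replacement from a genotype pool of size ``P``,
  scoring how many become unfit;
* PCA + centroid clustering of haplotype (13-dim) or genotype (26-dim,
  storage-order concatenation) matrices — genotype rows keep haplotype
  storage order, which is why a heterozygote appears as two mirror-image
  clusters (AB and BA);
* running-average smoothing of phenotype-count trajectories;
* polymorphism classification of a snapshot (two-haplotype polymorphism,
  and whether the heterozygote is phenotypically identical to one
  homozygote — the "type" configuration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .genome import (
    DEFAULT_OMEGA,
    Environment,
    class_index,
    classify_phenotype,
    response_matrix,
)
from .mating import MutationRates
from .simulate import Population

__all__ = [
    "unfit_mask",
    "unfit_fraction",
    "ml_chi2",
    "RobustnessResult",
    "robustness_test",
    "pca_cluster",
    "smooth_counts",
    "assign_genotypes",
    "PolymorphismSummary",
    "polymorphism_summary",
]


# ---------------------------------------------------------------------------
# Unfit phenotypes
# ---------------------------------------------------------------------------

def unfit_mask(classes: np.ndarray, suitability: np.ndarray) -> np.ndarray:
    """Boolean mask of phenotype classes preferring >= 1 unsuitable niche."""
    classes = np.atleast_2d(np.asarray(classes))
    suitability = np.asarray(suitability, dtype=bool)
    return (classes[:, ~suitability] == 1).any(axis=1)


def unfit_fraction(classes: np.ndarray, suitability: np.ndarray) -> float:
    """Fraction of phenotype classes that are unfit."""
    classes = np.atleast_2d(np.asarray(classes))
    if classes.shape[0] == 0:
        raise ValueError("cannot compute the unfit fraction of zero phenotypes")
    return float(unfit_mask(classes, suitability).mean())


# ---------------------------------------------------------------------------
# Maximum-likelihood chi-square (likelihood-ratio G)
# ---------------------------------------------------------------------------

def ml_chi2(table: np.ndarray) -> Tuple[float, float]:
    """Likelihood-ratio (maximum-likelihood chi-square) test of independence
    on a 2x2 contingency table.

    Returns ``(G, p)`` with ``G = 2 * sum O * ln(O / E)``, the expectations
    E taken from the table margins, and the p-value from the chi-square
    distribution with 1 degree of freedom.  Zero cells contribute zero
    (0 * ln 0 = 0); a zero row or column margin is degenerate and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    expected = np.outer(rows, cols) / total
    g = 2.0 * float(np.sum(xlogy(obs, obs) - xlogy(obs, expected)))
    g = max(g, 0.0)  # guard tiny negative round-off at independence
    p = float(stats.chi2.sf(g, df=1))
    return g, p


# ---------------------------------------------------------------------------
# Mutation-robustness resampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of the single-mutant robustness assay on one genotype pool.

    ``expected_unfit_count`` is the mutant unfit percentage projected back
    onto the pool: round(mutant_unfit_fraction * P).  ``increase_pct`` is
    the change relative to the pool's original unfit count,
    (expected - baseline) / baseline * 100, and equals 0 when nothing
    changed (including the all-robust 0 -> 0 case); it is NaN when the
    baseline count is zero but mutants became unfit.
    """

    pool_size: int                 # P
    n_mutants: int                 # K = P * (P - 1)
    baseline_unfit_count: int
    baseline_unfit_pct: float
    mutant_unfit_pct: float
    expected_unfit_count: int
    increase_pct: float


def robustness_test(
    pool: Population | Sequence,
    env: Environment,
    rates: MutationRates,
    rng: np.random.Generator,
    omega: float = DEFAULT_OMEGA,
) -> RobustnessResult:
    """Mutation-robustness assay on a pool of genomes of one genotype class.

    ``K = P * (P - 1)`` mutants are generated by sampling individuals with
    replacement, applying one point mutation (the simulation's uniform
    weight perturbation, clamped) at a random locus of a random haplotype,
    and scoring the mutant's phenotype against the environment's
    suitability.
    """
    if not isinstance(pool, Population):
        pool = Population.from_genomes(list(pool))
    P = len(pool)
    if P < 2:
        raise ValueError(f"robustness assay needs a pool of >= 2 genomes, got {P}")
    K = P * (P - 1)
    L = pool.n_loci
    signals = env.signal_set.signals

    base_classes = classify_phenotype(
        response_matrix(pool.expressed(), signals, omega)
    )
    baseline = int(unfit_mask(base_classes, env.suitability).sum())

    picks = rng.integers(0, P, size=K)
    hap = rng.integers(0, 2, size=K)
    locus = rng.integers(0, L, size=K)
    delta = rng.uniform(-rates.perturbation_range, rates.perturbation_range, size=K)

    mutated = pool.pref[picks].copy()
    mutated[np.arange(K), hap, locus] = np.clip(
        mutated[np.arange(K), hap, locus] + delta,
        -rates.allele_clamp,
        rates.allele_clamp,
    )
    mut_classes = classify_phenotype(
        response_matrix(mutated.mean(axis=1), signals, omega)
    )
    mut_frac = float(unfit_mask(mut_classes, env.suitability).mean())
    expected = int(np.floor(mut_frac * P + 0.5))
    if expected == baseline:
        increase = 0.0
    elif baseline == 0:
        increase = float("nan")
    else:
        increase = (expected - baseline) / baseline * 100.0
    return RobustnessResult(
        pool_size=P,
        n_mutants=K,
        baseline_unfit_count=baseline,
        baseline_unfit_pct=100.0 * baseline / P,
        mutant_unfit_pct=100.0 * mut_frac,
        expected_unfit_count=expected,
        increase_pct=increase,
    )


# ---------------------------------------------------------------------------
# PCA + clustering
# ---------------------------------------------------------------------------

def pca_cluster(
    matrix: np.ndarray,
    n_clusters: Optional[int] = None,
    n_components: int = 2,
    random_state: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Principal-component scores plus a centroid-based partition.

    ``matrix`` holds haplotype rows (L-dim) or genotype rows (2L-dim,
    haplotypes concatenated in storage order).  When ``n_clusters`` is
    None, k is chosen from 2..6 by silhouette score (degenerate inputs —
    all rows identical — collapse to a single cluster).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if n_clusters is not None and n_clusters > X.shape[0]:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {X.shape[0]} rows"
        )
    n_comp = min(n_components, X.shape[0], X.shape[1])
    scores = PCA(n_components=n_comp, random_state=random_state).fit_transform(X)

    distinct = np.unique(X, axis=0).shape[0]
    if distinct == 1:
        return scores, np.zeros(X.shape[0], dtype=np.int64)

    def _fit(k: int) -> np.ndarray:
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        return km.fit_predict(scores)

    if n_clusters is not None:
        return scores, _fit(min(n_clusters, distinct))

    best_labels, best_score = None, -np.inf
    for k in range(2, min(6, distinct) + 1):
        labels = _fit(k)
        if np.unique(labels).size < 2:
            continue
        s = silhouette_score(scores, labels)
        if s > best_score:
            best_labels, best_score = labels, s
    if best_labels is None:
        best_labels = np.zeros(X.shape[0], dtype=np.int64)
    return scores, best_labels


# ---------------------------------------------------------------------------
# Trajectory smoothing
# ---------------------------------------------------------------------------

def smooth_counts(
    series: pd.DataFrame | pd.Series | np.ndarray,
    window: int = 80,
    stride: int = 20,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Running averages of per-generation counts for trajectory plots.

    A centred mean over ``window`` generations is emitted every ``stride``
    generations; series whose raw counts never exceed ``threshold`` are
    dropped.  The result keeps the (generation) index of the emitted rows.
    """
    if isinstance(series, pd.Series):
        df = series.to_frame()
    elif isinstance(series, pd.DataFrame):
        df = series
    else:
        arr = np.asarray(series, dtype=float)
        df = pd.DataFrame(arr if arr.ndim == 2 else arr[:, None])
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if window > len(df):
        raise ValueError(
            f"window ({window}) exceeds series length ({len(df)})"
        )
    keep = [c for c in df.columns if df[c].max() > threshold]
    rolled = df[keep].rolling(window, center=True, min_periods=window).mean()
    rolled = rolled.dropna(how="all")
    return rolled.iloc[::stride]


# ---------------------------------------------------------------------------
# Genotype assignment and polymorphism classification
# ---------------------------------------------------------------------------

def assign_genotypes(
    population: Population,
    random_state: int = 0,
) -> Tuple[np.ndarray, float]:
    """Assign AA/AB/BB labels by 2-means clustering of all haplotypes.

    Haplotypes of the whole population are pooled (2n rows), clustered into
    two groups on their principal-component scores, and each individual is
    labelled by the cluster membership of its two haplotypes.  Cluster A is
    the more common haplotype.  Returns (labels, silhouette) where the
    silhouette score measures how cleanly two haplotype clouds separate.
    """
    n = len(population)
    haps = population.pref.reshape(2 * n, population.n_loci)
    if np.unique(haps, axis=0).shape[0] == 1:
        return np.array(["AA"] * n), 0.0
    scores, hap_labels = pca_cluster(haps, n_clusters=2, random_state=random_state)
    sil = float(silhouette_score(scores, hap_labels)) if np.unique(hap_labels).size == 2 else 0.0
    # canonicalise: cluster 0 (-> allele "A") is the majority haplotype
    if np.count_nonzero(hap_labels == 0) < np.count_nonzero(hap_labels == 1):
        hap_labels = 1 - hap_labels
    per_ind = hap_labels.reshape(n, 2)
    names = np.array(["AA", "AB", "BB"])
    return names[per_ind.sum(axis=1)], sil


@dataclass(frozen=True)
class PolymorphismSummary:
    """Classification of a snapshot's genetic organisation.

    ``outcome`` is one of:

    * ``"monomorphic"`` — no clean two-haplotype structure;
    * ``"type_polymorphism"`` — two haplotypes whose heterozygote expresses
      the same phenotype as exactly one homozygote (the configuration in
      which silenced alleles arise);
    * ``"non_type_polymorphism"`` — two haplotypes with any other
      genotype-to-phenotype arrangement.
    """

    outcome: str
    silhouette: float
    genotype_counts: Dict[str, int]
    modal_classes: Dict[str, Tuple[int, ...]]


def polymorphism_summary(
    population: Population,
    env: Environment,
    omega: float = DEFAULT_OMEGA,
    min_homozygote_fraction: float = 0.02,
    min_silhouette: float = 0.6,
    random_state: int = 0,
) -> PolymorphismSummary:
    """Decide whether a snapshot carries a two-haplotype polymorphism and,
    if so, whether it is of the "type" kind (heterozygote phenotypically
    identical to one homozygote).

    A polymorphism requires the haplotype clouds to separate cleanly
    (silhouette >= ``min_silhouette``) and both homozygote genotypes to be
    present at >= ``min_homozygote_fraction`` of the population (each with
    at least 2 individuals).
    """
    n = len(population)
    labels, sil = assign_genotypes(population, random_state=random_state)
    counts = {g: int(np.count_nonzero(labels == g)) for g in ("AA", "AB", "BB")}

    psi = response_matrix(population.expressed(), env.signal_set.signals, omega)
    classes = classify_phenotype(psi)
    modal: Dict[str, Tuple[int, ...]] = {}
    for g in ("AA", "AB", "BB"):
        mask = labels == g
        if not np.any(mask):
            continue
        idx = class_index(classes[mask])
        top = int(np.bincount(idx).argmax())
        modal[g] = tuple(int(b) for b in np.binary_repr(top, classes.shape[1]))

    min_count = max(2, int(np.ceil(min_homozygote_fraction * n)))
    polymorphic = (
        sil >= min_silhouette
        and counts["AA"] >= min_count
        and counts["BB"] >= min_count
    )
    if not polymorphic:
        outcome = "monomorphic"
    elif (
        counts["AB"] > 0
        and modal["AA"] != modal["BB"]
        and (modal["AB"] == modal["AA"]) != (modal["AB"] == modal["BB"])
    ):
        outcome = "type_polymorphism"
    else:
        outcome = "non_type_polymorphism"
    return PolymorphismSummary(
        outcome=outcome,
        silhouette=sil,
        genotype_counts=counts,
        modal_classes=modal,
    )
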
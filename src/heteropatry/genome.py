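"""Genotype representation and the genotype -> phenotype map.

Each individual ("exploiter") carries two chromosome pairs:

* a *preference* chromosome pair: two haplotypes of 13 real-valued alleles
  that encode the weights of a 2-input / 3-hidden / 1-output perceptron.
  Alleles are codominant — the expressed weight at a locus is the mean of
  the two allelic values.
* a *mating* chromosome pair: two alleles from {r, a} (random / assortative
  mating), with ``a`` dominant over ``r`` by default.

The perceptron is applied to the two-channel signal of each of the four
resources, producing a response array Psi = (psi_1..psi_4) of preference
strengths in (0, 1).  Rounding Psi component-wise yields one of 16 binary
phenotype classes (e.g. [1,0,0,0] = niche-I specialist, [1,1,1,1] =
non-discriminating generalist).

Locus order on a preference haplotype (3 hidden nodes):

    w11, w21, bh1, w12, w22, bh2, w13, w23, bh3, wout1, wout2, wout3, bo

i.e. three blocks of (input weight 1, input weight 2, hidden bias) — one
block per hidden node — followed by the three hidden-to-output weights and
the output bias.  The four weights touching hidden node j (w1j, w2j, bhj,
woutj) form the "super-gene" controlling that node's discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "DEFAULT_SIGNALS",
    "DEFAULT_RESOURCE_VALUES",
    "DEFAULT_OMEGA",
    "GenomeStructureError",
    "SignalSet",
    "Environment",
    "Genome",
    "R_ALLELE",
    "A_ALLELE",
    "n_loci",
    "locus_names",
    "express_preference",
    "perceptron_response",
    "response_array",
    "response_matrix",
    "classify_phenotype",
    "class_index",
    "expressed_mating",
    "assortative_mask",
]

#: Two-channel signals of the four resources, lined up on the diagonal of
#: the unit signal square (the hardest 4-way discrimination task).
DEFAULT_SIGNALS: Tuple[Tuple[float, float], ...] = (
    (0.2, 0.8),
    (0.4, 0.6),
    (0.6, 0.4),
    (0.8, 0.2),
)

#: Carrying capacities of the four niches: two suitable (250) and two
#: unsuitable (0.01; slightly above zero to avoid division by zero).
DEFAULT_RESOURCE_VALUES: Tuple[float, ...] = (250.0, 0.01, 250.0, 0.01)

#: Slope of the sigmoidal node activation, sigma(omega * xi).
DEFAULT_OMEGA: float = 4.0

R_ALLELE = "r"
A_ALLELE = "a"


class GenomeStructureError(ValueError):
    """A genome does not have the expected chromosome structure."""


def n_loci(n_hidden: int = 3) -> int:
    """Number of loci on a preference haplotype for ``n_hidden`` hidden nodes."""
    if n_hidden < 1:
        raise GenomeStructureError(f"n_hidden must be >= 1, got {n_hidden}")
    return 4 * n_hidden + 1


def locus_names(n_hidden: int = 3) -> list[str]:
    """Locus labels in chromosome order."""
    names: list[str] = []
    for j in range(1, n_hidden + 1):
        names += [f"w1{j}", f"w2{j}", f"bh{j}"]
    names += [f"wout{j}" for j in range(1, n_hidden + 1)]
    names.append("bo")
    return names


def _hidden_count(length: int) -> int:
    h, rem = divmod(length - 1, 4)
    if rem != 0 or h < 1:
        raise GenomeStructureError(
            f"haplotype length {length} does not match any 2/h/1 perceptron "
            f"(expected 4*h + 1 loci)"
        )
    return h


@dataclass(frozen=True)
class SignalSet:
    """The two-channel signals (s_k1, s_k2) identifying each resource."""

    signals: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_SIGNALS, dtype=float)
    )

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2 or sig.shape[1] != 2:
            raise ValueError(f"signals must be (k, 2), got shape {sig.shape}")
        if np.any(sig < 0.0) or np.any(sig > 1.0):
            raise ValueError("signal channel values must lie in [0, 1]")
        sig.setflags(write=False)
        object.__setattr__(self, "signals", sig)

    @property
    def n_resources(self) -> int:
        return self.signals.shape[0]


@dataclass(frozen=True)
class Environment:
    """Resource carrying capacities N_k plus their signals.

    A niche is *suitable* when its carrying capacity reaches
    ``suitability_threshold``; the default resource vector
    [250, 0.01, 250, 0.01] makes niches I and III suitable.
    """

    resource_values: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_RESOURCE_VALUES, dtype=float)
    )
    signal_set: SignalSet = field(default_factory=SignalSet)
    suitability_threshold: float = 1.0

    def __post_init__(self) -> None:
        nk = np.asarray(self.resource_values, dtype=float)
        if nk.ndim != 1:
            raise ValueError("resource_values must be a 1-D vector")
        if nk.shape[0] != self.signal_set.n_resources:
            raise ValueError(
                f"{nk.shape[0]} resource values but "
                f"{self.signal_set.n_resources} signals"
            )
        if np.any(nk <= 0.0):
            raise ValueError(
                "all resource values must be > 0 (use a small positive value "
                "for unsuitable niches)"
            )
        nk.setflags(write=False)
        object.__setattr__(self, "resource_values", nk)

    @property
    def n_resources(self) -> int:
        return self.resource_values.shape[0]

    @property
    def suitability(self) -> np.ndarray:
        """Boolean vector: which niches are suitable (N_k >= threshold)."""
        return self.resource_values >= self.suitability_threshold


@dataclass
class Genome:
    """One diploid individual: a preference chromosome pair + a mating pair.

    ``pref`` has shape (2, L) — haplotype storage order is preserved, which
    is what makes AB and BA genotype rows distinguishable downstream.
    ``mating`` is a pair of characters from {'r', 'a'}.
    """

    pref: np.ndarray
    mating: Tuple[str, str] = (R_ALLELE, R_ALLELE)

    def __post_init__(self) -> None:
        pref = np.asarray(self.pref, dtype=float)
        if pref.ndim != 2 or pref.shape[0] != 2:
            raise GenomeStructureError(
                f"pref must have shape (2, L), got {pref.shape}"
            )
        _hidden_count(pref.shape[1])
        self.pref = pref
        mating = tuple(self.mating)
        if len(mating) != 2 or any(m not in (R_ALLELE, A_ALLELE) for m in mating):
            raise GenomeStructureError(
                f"mating alleles must be a pair from {{'r','a'}}, got {mating!r}"
            )
        self.mating = mating  # type: ignore[assignment]

    @property
    def n_loci(self) -> int:
        return self.pref.shape[1]

    def copy(self) -> "Genome":
        return Genome(self.pref.copy(), self.mating)


# ---------------------------------------------------------------------------
# Codominant expression and the perceptron forward pass
# ---------------------------------------------------------------------------

def express_preference(genome: Genome) -> np.ndarray:
    """Expressed weights: element-wise mean of the two preference haplotypes."""
    return genome.pref.mean(axis=0)


def _split_weights(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Split a flat weight vector into (input weights, hidden biases, output
    weights, output bias) following the chromosome locus order."""
    w = np.asarray(weights, dtype=float)
    h = _hidden_count(w.shape[-1])
    blocks = w[..., : 3 * h].reshape(*w.shape[:-1], h, 3)
    w_in = blocks[..., :2]      # (..., h, 2): w1j, w2j
    b_h = blocks[..., 2]        # (..., h)
    w_out = w[..., 3 * h : 4 * h]
    b_o = w[..., 4 * h]
    return w_in, b_h, w_out, b_o


def perceptron_response(
    weights: Sequence[float] | np.ndarray,
    signal: Sequence[float],
    omega: float = DEFAULT_OMEGA,
) -> float:
    """Forward pass of the preference perceptron for one resource signal.

    Hidden node j receives the activity
    ``xi_j = s1*w1j + s2*w2j - bhj`` and outputs ``theta_j =
    sigma(omega * xi_j)`` with ``sigma`` the logistic function; the output
    node receives ``xi_out = sum_j theta_j * woutj - bo`` and returns
    ``psi = sigma(omega * xi_out)``, a preference strength in (0, 1).
    """
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("perceptron weights must be finite")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    s1, s2 = float(signal[0]), float(signal[1])
    w_in, b_h, w_out, b_o = _split_weights(w)
    xi = s1 * w_in[..., 0] + s2 * w_in[..., 1] - b_h
    theta = expit(omega * xi)
    xi_out = theta @ w_out - b_o
    return float(expit(omega * xi_out))


def response_matrix(
    expressed: np.ndarray,
    signals: np.ndarray,
    omega: float = DEFAULT_OMEGA,
) -> np.ndarray:
    """Vectorised forward pass: (n, L) expressed weights x (k, 2) signals
    -> (n, k) response matrix.  Same arithmetic as `perceptron_response`."""
    W = np.atleast_2d(np.asarray(expressed, dtype=float))
    sig = np.asarray(signals, dtype=float)
    h = _hidden_count(W.shape[1])
    blocks = W[:, : 3 * h].reshape(W.shape[0], h, 3)
    # xi[n, k, j] = s_k1 * w1j + s_k2 * w2j - bhj
    xi = np.einsum("kc,njc->nkj", sig, blocks[:, :, :2]) - blocks[:, :, 2][:, None, :]
    theta = expit(omega * xi)
    w_out = W[:, 3 * h : 4 * h]
    xi_out = np.einsum("nkj,nj->nk", theta, w_out) - W[:, 4 * h][:, None]
    return expit(omega * xi_out)


def response_array(
    genome: Genome,
    signal_set: SignalSet | None = None,
    omega: float = DEFAULT_OMEGA,
) -> np.ndarray:
    """Response array Psi of one genome over every resource signal."""
    if signal_set is None:
        signal_set = SignalSet()
    expressed = express_preference(genome)
    if not np.all(np.isfinite(expressed)):
        raise ValueError("expressed weights must be finite")
    return response_matrix(expressed[None, :], signal_set.signals, omega)[0]


def classify_phenotype(psi: np.ndarray) -> np.ndarray:
    """Round a response array component-wise to its binary phenotype class.

    Exactly-0.5 components round up (to 1); with continuous weights this is
    a measure-zero tie-break.
    """
    psi = np.asarray(psi, dtype=float)
    return np.floor(psi + 0.5).astype(np.int8)


def class_index(classes: np.ndarray) -> np.ndarray:
    """Pack binary phenotype classes (..., 4) into integers 0..15.

    Bit order: psi_1 is the most significant bit, so [1,0,0,0] -> 8 and
    [1,1,1,1] -> 15.
    """
    c = np.asarray(classes, dtype=np.int64)
    k = c.shape[-1]
    weights = 1 << np.arange(k - 1, -1, -1)
    return c @ weights


def expressed_mating(genome: Genome, a_dominant: bool = True) -> str:
    """Expressed mating behaviour: 'assortative' or 'random'.

    With ``a`` dominant, any copy of ``a`` makes the carrier assortative
    (rr -> random); with dominance reversed, only aa is assortative.
    """
    n_a = sum(1 for m in genome.mating if m == A_ALLELE)
    if a_dominant:
        return "assortative" if n_a >= 1 else "random"
    return "assortative" if n_a == 2 else "random"


def assortative_mask(mating: np.ndarray, a_dominant: bool = True) -> np.ndarray:
    """Vectorised `expressed_mating` over an (n, 2) array of 0/1 mating
    alleles (0 = r, 1 = a); returns a boolean mask (True = assortative)."""
    mating = np.asarray(mating)
    if a_dominant:
        return mating.max(axis=1) == 1
    return mating.min(axis=1) == 1
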
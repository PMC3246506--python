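"""Reproductive-output allocation and density-dependent fitness.

An individual's response array Psi is converted into a per-niche
reproductive output

    e_k = phi * psi_k**2 / sum_l psi_l        (e = 0 when Psi = 0),

so output depends on both the relative response (psi_k against the sum)
and the absolute response (the squared psi).  Every all-or-none (binary)
response array therefore yields the same total output phi, while
intermediate responses are penalised — this selects for bimodal (0/1)
preferences rather than graded ones.

Fitness discounts each niche's contribution by crowding with a Hill-type
competition term,

    f_i = sum_k e_k,i / (1 + (E_k / (eps * N_k))**a),

where E_k is the population total of e_k, N_k the niche's carrying
capacity, eps the half-saturation coefficient and a the abruptness of the
onset of density dependence.  The niche contribution is exactly halved
when E_k = eps * N_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Environment

__all__ = [
    "EcologyParams",
    "reproductive_output",
    "niche_totals",
    "fitness",
    "population_fitness",
]


@dataclass(frozen=True)
class EcologyParams:
    """Ecological constants.

    phi : maximum reproductive output of one individual (default 3)
    epsilon : half-saturation coefficient — competition halves a niche's
        contribution when the niche load E_k reaches epsilon * N_k
        (default 1.5)
    abruptness : Hill exponent controlling how sharply density dependence
        sets in around the half-saturation load (default 2.5)
    """

    phi: float = 3.0
    epsilon: float = 1.5
    abruptness: float = 2.5

    def __post_init__(self) -> None:
        for name in ("phi", "epsilon", "abruptness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def reproductive_output(psi: np.ndarray, phi: float = 3.0) -> np.ndarray:
    """Per-niche reproductive output e_k = phi * psi_k^2 / sum(psi).

    Accepts a single response array (k,) or a population matrix (n, k);
    rows with sum(psi) = 0 get zero output everywhere.
    """
    if phi <= 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    psi = np.asarray(psi, dtype=float)
    total = psi.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = phi * psi**2 / total
    return np.where(total > 0, e, 0.0)


def niche_totals(outputs: np.ndarray) -> np.ndarray:
    """Niche loads E_k: column sums of the population's output matrix."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2 or outputs.shape[0] == 0:
        raise ValueError("outputs must be a non-empty (n, k) matrix")
    return outputs.sum(axis=0)


def crowding_discount(
    totals: np.ndarray, env: Environment, params: EcologyParams
) -> np.ndarray:
    """Per-niche competition factor 1 / (1 + (E_k / (eps*N_k))**a)."""
    totals = np.asarray(totals, dtype=float)
    half_sat = params.epsilon * env.resource_values
    return 1.0 / (1.0 + (totals / half_sat) ** params.abruptness)


def fitness(
    e_i: np.ndarray,
    totals: np.ndarray,
    env: Environment,
    params: EcologyParams,
) -> float:
    """Density-dependent fitness of one individual.

    ``e_i`` is the individual's reproductive-output vector and ``totals``
    the niche loads of the population containing it (the individual's own
    output included).  Bounded by 0 <= f_i <= sum_k e_k,i.
    """
    e_i = np.asarray(e_i, dtype=float)
    return float(e_i @ crowding_discount(totals, env, params))


def population_fitness(
    outputs: np.ndarray,
    env: Environment,
    params: EcologyParams,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised fitness for a whole (n, k) output matrix."""
    outputs = np.asarray(outputs, dtype=float)
    if totals is None:
        totals = niche_totals(outputs)
    return outputs @ crowding_discount(totals, env, params)
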
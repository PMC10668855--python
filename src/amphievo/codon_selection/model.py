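"""GY94-type codon rate matrices.

q_ij = 0 for multi-nucleotide changes, and otherwise proportional to the
target codon frequency, multiplied by kappa for transitions and by omega
for nonsynonymous changes. Matrices are scaled to one expected substitution
per codon per unit time unless a shared scale is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from amphievo.core import codes
from amphievo.core.models import ReversibleModel


@dataclass
class CodonModelParams:
    kappa: float
    omega: dict[str, float] | float  # per branch class, or a single ratio
    pi: np.ndarray | None = None  # 61 sense-codon frequencies
    alpha: float | None = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        omegas = (
            self.omega.values() if isinstance(self.omega, dict) else [self.omega]
        )
        if any(w < 0 for w in omegas):
            raise ValueError("omega must be non-negative")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if abs(self.pi.sum() - 1.0) > 1e-8:
                raise ValueError("pi must sum to 1")

    def omega_for(self, cls: str | None) -> float:
        if not isinstance(self.omega, dict):
            return float(self.omega)
        if cls not in self.omega:
            raise KeyError(f"no omega defined for branch class {cls!r}")
        return float(self.omega[cls])


def f3x4_frequencies(codon_states: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies from a codon-index matrix (missing = -1)."""
    pos_counts = np.full((3, 4), pseudocount)
    flat = codon_states[codon_states >= 0]
    for idx in flat:
        codon = codes.SENSE_CODONS[idx]
        for p in range(3):
            pos_counts[p, codes.NUC_INDEX[codon[p]]] += 1
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, codes.NUC_INDEX[c[0]]]
            * pos_freqs[1, codes.NUC_INDEX[c[1]]]
            * pos_freqs[2, codes.NUC_INDEX[c[2]]]
            for c in codes.SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(codes.N_CODONS, 1.0 / codes.N_CODONS)


def build_codon_Q(
    kappa: float, omega: float, pi: np.ndarray, scale: float | None = None
) -> tuple[np.ndarray, float]:
    """Unnormalized-then-scaled GY94 rate matrix.

    Returns (Q, rate) where ``rate`` is the pre-scaling expected
    substitutions/codon/unit time. If ``scale`` is given, Q is divided by it
    (a shared gauge across branch classes); otherwise by its own rate.
    """
    n = codes.N_CODONS
    Q = np.zeros((n, n))
    vals = pi[codes.PAIR_J].copy()
    vals[codes.PAIR_IS_TS] *= kappa
    vals[~codes.PAIR_IS_SYN] *= omega
    Q[codes.PAIR_I, codes.PAIR_J] = vals
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.sum(pi * np.diag(Q)))
    div = scale if scale is not None else rate
    if div <= 0:
        raise ValueError("degenerate codon matrix")
    return Q / div, rate


def codon_model(kappa: float, omega: float, pi: np.ndarray) -> ReversibleModel:
    Q, _ = build_codon_Q(kappa, omega, pi)
    return ReversibleModel(Q, pi, normalize=False)


def substitution_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractions of the total substitution rate."""
    vals = pi[codes.PAIR_I] * pi[codes.PAIR_J]
    vals[codes.PAIR_IS_TS] *= kappa
    syn = float(vals[codes.PAIR_IS_SYN].sum())
    nonsyn = float(vals[~codes.PAIR_IS_SYN].sum()) * omega
    total = syn + nonsyn
    return syn / total, nonsyn / total


def dn_ds_from_branch(
    t: float, kappa: float, omega: float, pi: np.ndarray
) -> tuple[float, float]:
    """PAML-style per-branch (dN, dS) from a branch length in expected
    substitutions/codon under the branch's own matrix.

    Site proportions are taken from the same matrix at omega=1, which makes
    dN/dS equal the model omega exactly.
    """
    rho_s, rho_n = substitution_fractions(kappa, omega, pi)
    rho_s1, rho_n1 = substitution_fractions(kappa, 1.0, pi)
    ds = t * rho_s / (3.0 * rho_s1)
    dn = t * rho_n / (3.0 * rho_n1)
    return dn, ds
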
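"""Reversible substitution models with eigendecomposition-based propagators."""

from __future__ import annotations

import importlib.resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from amphievo.core import codes


def discrete_gamma(alpha: float, k: int = 4) -> np.ndarray:
    """Equal-probability discrete gamma rates (median method), mean forced to 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k == 1:
        return np.ones(1)
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates * (k / rates.sum())


class ReversibleModel:
    """A time-reversible rate matrix Q with stationary distribution pi.

    Q is scaled so the expected substitution rate at stationarity is 1,
    unless ``normalize=False``. P(t) = exp(Qt) is computed through the
    symmetric eigendecomposition, so repeated calls at different t are cheap.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray, normalize: bool = True):
        pi = np.asarray(pi, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if normalize:
            rate = -np.sum(pi * np.diag(Q))
            if rate <= 0:
                raise ValueError("degenerate rate matrix")
            Q = Q / rate
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        S = 0.5 * (S + S.T)  # guard tiny asymmetries
        self._eval, evec = np.linalg.eigh(S)
        self._left = evec / sqrt_pi[:, None]   # diag(1/sqrt(pi)) U
        self._right = evec.T * sqrt_pi[None, :]  # U^T diag(sqrt(pi))

    @property
    def mean_rate(self) -> float:
        return -float(np.sum(self.pi * np.diag(self.Q)))

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._eval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def gtr_model(rates: np.ndarray, pi: np.ndarray) -> ReversibleModel:
    """GTR for nucleotides; ``rates`` = 6 exchangeabilities in the order
    AC, AG, AT, CG, CT, GT."""
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must sum to 1")
    Q = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for r, (i, j) in zip(rates, idx):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return ReversibleModel(Q, pi)


def hky_model(kappa: float, pi: np.ndarray) -> ReversibleModel:
    rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return gtr_model(rates, pi)


def load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Bundled JTT exchangeabilities and frequencies, reordered to the
    alphabetical one-letter residue order used package-wide."""
    source_order = "ARNDCQEGHILKMFPSTWYV"
    path = importlib.resources.files("amphievo") / "data" / "jtt.dat"
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    exch_src = np.zeros((20, 20))
    for i, line in enumerate(lines[:19], start=1):
        vals = [float(x) for x in line.split()]
        exch_src[i, : len(vals)] = vals
    exch_src = exch_src + exch_src.T
    freqs_src = np.array([float(x) for x in lines[19].split()])
    perm = [source_order.index(a) for a in codes.AA_ALPHABET]
    exch = exch_src[np.ix_(perm, perm)]
    freqs = freqs_src[perm]
    return exch, freqs / freqs.sum()


def empirical_aa_model(
    exch: np.ndarray | None = None, pi: np.ndarray | None = None
) -> ReversibleModel:
    """Empirical amino-acid model (default: bundled JTT with its frequencies)."""
    if exch is None or pi is None:
        jtt_exch, jtt_pi = load_jtt()
        exch = jtt_exch if exch is None else exch
        pi = jtt_pi if pi is None else np.asarray(pi, dtype=float)
    Q = exch * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return ReversibleModel(Q, pi)
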
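"""Approximately-unbiased topology testing via multiscale RELL bootstrap.

Per-site log-likelihood vectors for competing topologies are resampled at a
grid of scale factors; the bootstrap proportion of each topology being best
is fitted by weighted least squares to the signed-distance / curvature
parameterization z(r) = d*sqrt(r) + c/sqrt(r), and the AU p-value is
1 - Phi(d - c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = np.linspace(0.5, 1.4, 10)


@dataclass
class SiteLoglikMatrix:
    """Per-topology per-site log-likelihoods for one gene."""

    labels: list[str]
    matrix: np.ndarray  # (n_topologies, n_sites)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label / row mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def _bootstrap_proportions(
    matrix: np.ndarray, scales: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """BP[s, k]: proportion of replicates at scale s where topology k is best.

    Ties share the count equally, so duplicated log-likelihood vectors get
    identical proportions (and hence identical p-values).
    """
    n_topo, L = matrix.shape
    bp = np.zeros((len(scales), n_topo))
    p_uniform = np.full(L, 1.0 / L)
    for si, r in enumerate(scales):
        m = max(1, int(round(r * L)))
        counts = rng.multinomial(m, p_uniform, size=n_boot)  # (n_boot, L)
        totals = counts @ matrix.T  # (n_boot, n_topo)
        best = totals.max(axis=1, keepdims=True)
        is_best = np.isclose(totals, best, rtol=0, atol=1e-9)
        bp[si] = (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)
    return bp


def _au_pvalue(bp: np.ndarray, scales: np.ndarray, n_boot: int) -> float:
    """WLS fit of z(r) = d*sqrt(r) + c/sqrt(r); p = 1 - Phi(d - c).

    A topology that is never (always) best at every scale leaves the fit
    unidentified; the p-value degenerates to 0 (1)."""
    eps = 0.5 / n_boot
    if bp.max() < 1.0 / n_boot:
        return 0.0
    if bp.min() > 1 - 1.0 / n_boot:
        return 1.0
    bp = np.clip(bp, eps, 1 - eps)
    z = norm.ppf(1 - bp)
    dens = norm.pdf(z)
    var = bp * (1 - bp) / (n_boot * dens**2)
    w = 1.0 / var
    sq = np.sqrt(scales)
    X = np.column_stack([sq, 1.0 / sq])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    d, c = beta
    return float(norm.sf(d - c))


def au_test(
    m: SiteLoglikMatrix,
    scales: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """AU p-value per topology.

    The resampling stream is keyed only to (seed, n_sites), so p-values are
    invariant to site order.
    """
    if m.matrix.shape[0] < 2:
        raise ValueError("need at least two topologies")
    if n_boot < 100:
        raise ValueError("n_boot too small for a meaningful AU fit")
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, dtype=float)
    # canonical site order makes the test invariant to permutation of sites
    order = np.lexsort(m.matrix[::-1])
    matrix = m.matrix[:, order]
    # duplicate-topology degeneracy
    uniq: dict[bytes, list[int]] = {}
    for i in range(matrix.shape[0]):
        uniq.setdefault(matrix[i].tobytes(), []).append(i)
    if any(len(v) > 1 for v in uniq.values()):
        warnings.warn("identical site log-likelihood vectors; equal p-values assigned")
    rng = np.random.default_rng(seed)
    bp = _bootstrap_proportions(matrix, scales, n_boot, rng)
    pvals = np.empty(matrix.shape[0])
    for key, idxs in uniq.items():
        p = _au_pvalue(bp[:, idxs[0]], scales, n_boot)
        for i in idxs:
            pvals[i] = p
    return pd.Series(pvals, index=m.labels, name="au_p")


def hypothesis_support_counts(
    genes: list[SiteLoglikMatrix],
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-topology counts of genes whose AU p-value is >= alpha.

    Returns {"pvalues": DataFrame genes x topologies, "counts": Series}.
    """
    if not genes:
        raise ValueError("no genes supplied")
    labels = genes[0].labels
    for g in genes:
        if g.labels != labels:
            raise ValueError("inconsistent topology labels across genes")
    rows = []
    for i, g in enumerate(genes):
        rows.append(au_test(g, n_boot=n_boot, seed=seed + i))
    pmat = pd.DataFrame(rows, index=[f"gene{i}" for i in range(len(genes))])
    counts = (pmat >= alpha).sum(axis=0)
    counts.name = "n_supporting"
    return {"pvalues": pmat, "counts": counts}
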
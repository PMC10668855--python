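"""Maximum-likelihood evaluation of a fixed nucleotide topology (GTR+Gamma).

Branch lengths, GTR exchangeabilities and the gamma shape are optimized
jointly on the fixed topology by bounded quasi-Newton; base frequencies are
empirical (counted from the alignment). Per-site log-likelihoods at the
optimum feed the AU test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from amphievo.core.alignment import Alignment
from amphievo.core.models import discrete_gamma, gtr_model
from amphievo.core.pruning import leaf_state_matrix, mixture_site_log_likelihoods
from amphievo.core.results import FitResult
from amphievo.core.tree import Tree

_LOG_BL_BOUNDS = (np.log(1e-7), np.log(30.0))
_LOG_RATE_BOUNDS = (np.log(1e-3), np.log(1e3))
_LOG_ALPHA_BOUNDS = (np.log(0.02), np.log(50.0))


def empirical_base_freqs(states: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    counts = np.bincount(states[states >= 0].ravel(), minlength=4) + pseudocount
    return counts / counts.sum()


def fit_fixed_topology(
    aln: Alignment,
    topology: Tree,
    k: int = 4,
    fit_alpha: bool = True,
    maxiter: int = 200,
    init_branch_length: float = 0.1,
) -> FitResult:
    """Optimize GTR+Gamma(k) on a fixed topology; returns per-site logliks.

    The returned ``FitResult.params`` holds ``rates`` (6 GTR exchangeabilities,
    GT fixed at 1), ``alpha``, ``pi`` and ``branch_lengths`` keyed by the
    branch's child leaf set.
    """
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    tree = topology.unrooted_copy()
    tree_taxa = tree.leaf_names()
    missing = set(tree_taxa) - set(aln.taxa)
    if missing:
        raise ValueError(f"topology taxa absent from alignment: {sorted(missing)}")
    sub = aln.subset_taxa(tree_taxa)
    states = sub.state_indices()
    pi = empirical_base_freqs(states)
    leaf_states = leaf_state_matrix(tree, sub.taxa, states)
    branches = tree.branches()
    nb = len(branches)

    n_rate = 5
    x0 = np.concatenate(
        [
            np.full(nb, np.log(init_branch_length)),
            np.zeros(n_rate),
            [np.log(1.0)] if fit_alpha else [],
        ]
    )
    bounds = (
        [_LOG_BL_BOUNDS] * nb
        + [_LOG_RATE_BOUNDS] * n_rate
        + ([_LOG_ALPHA_BOUNDS] if fit_alpha else [])
    )

    def unpack(x):
        bl = np.exp(x[:nb])
        rates = np.concatenate([np.exp(x[nb : nb + n_rate]), [1.0]])
        alpha = float(np.exp(x[-1])) if fit_alpha else None
        return bl, rates, alpha

    def site_logliks(x) -> np.ndarray:
        bl, rates, alpha = unpack(x)
        model = gtr_model(rates, pi)
        cat_rates = discrete_gamma(alpha, k) if fit_alpha else np.ones(1)
        pmats = [
            {b.index: model.transition_matrix(bl[i] * r) for i, b in enumerate(branches)}
            for r in cat_rates
        ]
        weights = np.full(len(cat_rates), 1.0 / len(cat_rates))
        return mixture_site_log_likelihoods(tree, leaf_states, pmats, pi, weights)

    def nll(x) -> float:
        ll = site_logliks(x)
        if not np.all(np.isfinite(ll)):
            bad = int(np.nonzero(~np.isfinite(ll))[0][0])
            raise FloatingPointError(f"non-finite site log-likelihood at site {bad}")
        return -float(ll.sum())

    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    bl, rates, alpha = unpack(res.x)
    for b, t in zip(branches, bl):
        b.length = float(t)
    site_ll = site_logliks(res.x)
    out = FitResult(
        loglik=float(site_ll.sum()),
        params={
            "rates": rates,
            "alpha": alpha,
            "pi": pi,
            "branch_lengths": {
                frozenset(tree.leafset_below(b)): float(t) for b, t in zip(branches, bl)
            },
            "tree": tree,
        },
        site_logliks=site_ll,
        converged=bool(res.success),
    )
    if not res.success:
        out.flag(f"optimizer: {res.message}")
    return out
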
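"""Felsenstein pruning, marginal ancestral posteriors, and state simulation.

All functions take per-branch transition matrices keyed by node index (the
branch above each non-root node), a leaf-state matrix and a root
distribution. Site likelihood vectors are rescaled per site to avoid
underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from amphievo.core.tree import Tree


def leaf_state_matrix(tree: Tree, aln_taxa: list[str], states: np.ndarray) -> dict[str, np.ndarray]:
    """Map tree leaf names to their integer state rows."""
    lookup = {t: i for i, t in enumerate(aln_taxa)}
    out = {}
    for leaf in tree.leaves():
        if leaf.name not in lookup:
            raise ValueError(f"tree leaf {leaf.name!r} absent from alignment")
        out[leaf.name] = states[lookup[leaf.name]]
    return out


def _leaf_partial(state_row: np.ndarray, n_states: int) -> np.ndarray:
    L = state_row.shape[0]
    partial = np.zeros((n_states, L))
    ok = state_row >= 0
    partial[state_row[ok], np.nonzero(ok)[0]] = 1.0
    partial[:, ~ok] = 1.0
    return partial


def compute_partials(
    tree: Tree,
    leaf_states: dict[str, np.ndarray],
    pmats: dict[int, np.ndarray],
    n_states: int,
):
    """Downward (inside) partials for every node.

    Returns (partials, logscale) where ``partials[node.index]`` is the
    conditional likelihood matrix at that node and ``logscale`` the per-site
    accumulated log rescaling factor.
    """
    some = next(iter(leaf_states.values()))
    L = some.shape[0]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(L)
    for node in tree.postorder():
        if node.is_leaf:
            partials[node.index] = _leaf_partial(leaf_states[node.name], n_states)
            continue
        acc = np.ones((n_states, L))
        for child in node.children:
            acc *= pmats[child.index] @ partials[child.index]
        mx = acc.max(axis=0)
        mx[mx == 0] = 1.0
        acc /= mx
        logscale += np.log(mx)
        partials[node.index] = acc
    return partials, logscale


def site_log_likelihoods(
    tree: Tree,
    leaf_states: dict[str, np.ndarray],
    pmats: dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    partials, logscale = compute_partials(tree, leaf_states, pmats, len(pi))
    root = partials[tree.root.index]
    lik = pi @ root
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def mixture_site_log_likelihoods(
    tree: Tree,
    leaf_states: dict[str, np.ndarray],
    pmats_per_component: list[dict[int, np.ndarray]],
    pi: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """log sum_c w_c L_c(site) for a site-mixture (e.g. gamma categories)."""
    comps = np.stack(
        [
            site_log_likelihoods(tree, leaf_states, pm, pi)
            for pm in pmats_per_component
        ]
    )
    return logsumexp(comps + np.log(np.asarray(weights))[:, None], axis=0)


def marginal_posteriors(
    tree: Tree,
    leaf_states: dict[str, np.ndarray],
    pmats: dict[int, np.ndarray],
    pi: np.ndarray,
):
    """Single-component marginal state posteriors at every internal node.

    Returns (posteriors, site_logliks); ``posteriors[node.index]`` is an
    (n_states, L) matrix of P(state at node | data).
    """
    n_states = len(pi)
    partials, logscale = compute_partials(tree, leaf_states, pmats, n_states)
    L = logscale.shape[0]

    outside: dict[int, np.ndarray] = {tree.root.index: np.tile(pi[:, None], (1, L))}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        # cache child "sister messages": P_c @ D_c for each child
        msgs = {c.index: pmats[c.index] @ partials[c.index] for c in node.children}
        for child in node.children:
            sib = np.ones((n_states, L))
            for other in node.children:
                if other is not child:
                    sib *= msgs[other.index]
            contrib = outside[node.index] * sib
            o = pmats[child.index].T @ contrib
            mx = o.max(axis=0)
            mx[mx == 0] = 1.0
            outside[child.index] = o / mx

    posteriors = {}
    site_lik = pi @ partials[tree.root.index]
    with np.errstate(divide="ignore"):
        site_loglik = np.log(site_lik) + logscale
    for node in tree.postorder():
        if node.is_leaf:
            continue
        joint = outside[node.index] * partials[node.index]
        total = joint.sum(axis=0)
        total[total == 0] = 1.0
        posteriors[node.index] = joint / total
    return posteriors, site_loglik


def simulate_states(
    tree: Tree,
    pmats: dict[int, np.ndarray],
    pi: np.ndarray,
    n_sites: int,
    rng: np.random.Generator,
    site_scaler: np.ndarray | None = None,
):
    """Draw states at every node; returns dict node.index -> state vector.

    ``site_scaler`` is unused here (rate variation is handled by passing
    per-category pmats and splitting sites upstream).
    """
    n_states = len(pi)
    states: dict[int, np.ndarray] = {}
    states[tree.root.index] = rng.choice(n_states, size=n_sites, p=pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        P = pmats[node.index]
        parent_states = states[node.parent.index]
        out = np.empty(n_sites, dtype=np.int64)
        for s in np.unique(parent_states):
            mask = parent_states == s
            out[mask] = rng.choice(n_states, size=mask.sum(), p=P[s])
        states[node.index] = out
    return states
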
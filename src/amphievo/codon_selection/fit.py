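"""Maximum-likelihood branch models on codon alignments.

Supports the one-ratio, two-ratio (foreground/background) and free-ratio
parameterizations. Branch lengths are measured in expected substitutions
per codon under the branch's own matrix, so per-branch dN and dS follow
from the standard synonymous/nonsynonymous flux decomposition and
dN/dS equals the branch omega exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from amphievo.core.alignment import Alignment
from amphievo.core.pruning import leaf_state_matrix, site_log_likelihoods
from amphievo.core.results import FitResult
from amphievo.core.tree import Tree
from amphievo.codon_selection.model import (
    codon_model,
    dn_ds_from_branch,
    f3x4_frequencies,
)

_LOG_BL = (np.log(1e-6), np.log(20.0))
_LOG_KAPPA = (np.log(0.05), np.log(60.0))
_LOG_OMEGA = (np.log(1e-4), np.log(50.0))

MODELS = ("one_ratio", "two_ratio", "free_ratio")


@dataclass
class BranchRates:
    """Per-branch rate table: t, omega, dN, dS and class labels."""

    table: pd.DataFrame  # columns: branch, cls, t, omega, dN, dS

    def omega_by_class(self) -> pd.Series:
        return self.table.groupby("cls")["omega"].mean()


class CodonLikelihood:
    """Shared machinery: data preparation and the pruning likelihood."""

    def __init__(self, aln: Alignment, tree: Tree, pi: np.ndarray | None = None):
        if aln.alphabet != "CODON61":
            raise ValueError("codon alignment required")
        self.tree = tree.unrooted_copy()  # collapse the root-edge ridge
        tree_taxa = self.tree.leaf_names()
        if set(tree_taxa) != set(aln.taxa):
            raise ValueError("alignment taxa must match tree leaves")
        sub = aln.subset_taxa(tree_taxa)
        self.states = sub.state_indices()
        self.n_codons = self.states.shape[1]
        self.pi = f3x4_frequencies(self.states) if pi is None else np.asarray(pi)
        self.leaf_states = leaf_state_matrix(self.tree, sub.taxa, self.states)
        self.branches = self.tree.branches()

    def site_logliks(
        self, kappa: float, branch_omega: np.ndarray, bl: np.ndarray
    ) -> np.ndarray:
        models = {w: codon_model(kappa, w, self.pi) for w in np.unique(branch_omega)}
        pmats = {
            b.index: models[w].transition_matrix(t)
            for b, w, t in zip(self.branches, branch_omega, bl)
        }
        return site_log_likelihoods(self.tree, self.leaf_states, pmats, self.pi)


def _heuristic_starts(nb: int, n_omega: int, rng: np.random.Generator, n_random: int):
    """One heuristic start plus random restarts in (kappa, omegas, lengths)."""
    starts = [
        np.concatenate(
            [[np.log(2.0)], np.full(n_omega, np.log(0.3)), np.full(nb, np.log(0.15))]
        )
    ]
    for _ in range(n_random):
        starts.append(
            np.concatenate(
                [
                    [np.log(rng.uniform(0.5, 5.0))],
                    np.log(rng.uniform(0.05, 2.0, size=n_omega)),
                    np.log(rng.uniform(0.02, 0.5, size=nb)),
                ]
            )
        )
    return starts


def fit_branch_model(
    aln: Alignment,
    tree: Tree,
    model: str = "one_ratio",
    fg_class: str | None = None,
    n_restarts: int = 1,
    maxiter: int = 300,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[FitResult, BranchRates]:
    """Fit kappa, branch lengths and per-class omegas by ML.

    ``model`` is one of one_ratio / two_ratio / free_ratio; two_ratio
    requires branch classes on the tree with ``fg_class`` naming the
    foreground. Genes whose restarts disagree by more than 0.5 log-units
    are flagged (``restart_disagreement``).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    lik = CodonLikelihood(aln, tree)
    nb = len(lik.branches)

    if model == "one_ratio":
        classes = ["all"] * nb
    elif model == "two_ratio":
        if fg_class is None:
            raise ValueError("two_ratio requires fg_class")
        classes = []
        for b in lik.branches:
            if b.cls is None:
                raise ValueError(f"branch above {b.name or b.index} has no class label")
            classes.append("fg" if b.cls == fg_class else "bg")
        if "fg" not in classes:
            raise ValueError(f"no branch labelled {fg_class!r}")
    else:
        classes = [f"b{i}" for i in range(nb)]
    class_names = sorted(set(classes), key=classes.index)
    n_omega = len(class_names)
    class_idx = np.array([class_names.index(c) for c in classes])

    def unpack(x):
        kappa = float(np.exp(x[0]))
        omegas = np.exp(x[1 : 1 + n_omega])
        bl = np.exp(x[1 + n_omega :])
        return kappa, omegas, bl

    def nll(x):
        kappa, omegas, bl = unpack(x)
        ll = lik.site_logliks(kappa, omegas[class_idx], bl)
        return -float(ll.sum())

    bounds = [_LOG_KAPPA] + [_LOG_OMEGA] * n_omega + [_LOG_BL] * nb
    rng = np.random.default_rng(seed)
    starts = (
        [np.asarray(x0)]
        if x0 is not None
        else _heuristic_starts(nb, n_omega, rng, n_restarts)
    )
    results = []
    for s in starts:
        res = minimize(
            nll, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    kappa, omegas, bl = unpack(best.x)
    site_ll = lik.site_logliks(kappa, omegas[class_idx], bl)

    fit = FitResult(
        loglik=float(site_ll.sum()),
        params={
            "kappa": kappa,
            "omega": dict(zip(class_names, omegas.tolist())),
            "pi": lik.pi,
            "model": model,
            "_x": best.x,  # raw optimum (log kappa, log omegas, log lengths)
        },
        site_logliks=site_ll,
        converged=bool(best.success),
    )
    if len(results) > 1:
        spread = max(r.fun for r in results) - min(r.fun for r in results)
        if spread > 0.5:
            fit.flag("restart_disagreement")
    degenerate = bl.sum() < 1e-4
    if degenerate:
        fit.flag("degenerate_zero_length")

    rows = []
    for b, cls_i, t in zip(lik.branches, class_idx, bl):
        w = float(omegas[cls_i])
        if degenerate:
            w, dn, ds = np.nan, np.nan, np.nan
        else:
            dn, ds = dn_ds_from_branch(t, kappa, float(omegas[cls_i]), lik.pi)
        rows.append(
            {
                "branch": b.name or f"node{b.index}",
                "leafset": ",".join(sorted(lik.tree.leafset_below(b))),
                "cls": b.cls or class_names[cls_i],
                "t": float(t),
                "omega": w,
                "dN": dn,
                "dS": ds,
            }
        )
    return fit, BranchRates(pd.DataFrame(rows))
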
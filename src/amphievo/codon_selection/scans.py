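"""Selection scans: FEG (branch LRT), PSG (branch-site Model A LRT) and
group-level dN/dS summaries.

The branch-site alternative constrains the selected-class ratio to
omega2 >= 1 and the null fixes omega2 = 1, so the LRT statistic is
non-negative by construction and is referred to chi-square with 1 df (the
conservative applied choice). Site posteriors for the selected class are
naive empirical Bayes at the MLEs, not Bayes empirical Bayes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from amphievo.core.alignment import Alignment
from amphievo.core.pruning import site_log_likelihoods
from amphievo.core.tree import Tree
from amphievo.codon_selection.fit import (
    CodonLikelihood,
    fit_branch_model,
    _LOG_BL,
    _LOG_KAPPA,
)
from amphievo.codon_selection.model import codon_model


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScanResult:
    """Per-gene scan table plus optional per-site posteriors."""

    table: pd.DataFrame
    site_posteriors: list[np.ndarray] | None = None

    def calls(self) -> pd.Series:
        return self.table["call"]


# --------------------------------------------------------------------- FEG
def feg_scan(
    genes: list[Alignment],
    tree: Tree,
    fg_class: str,
    alpha: float = 0.05,
    n_restarts: int = 0,
    maxiter: int = 200,
    seed: int = 0,
) -> ScanResult:
    """One-ratio vs two-ratio LRT per gene with BH-FDR across genes.

    A gene is called FEG iff its adjusted p < alpha AND the foreground
    omega exceeds the background omega.
    """
    rows = []
    for i, gene in enumerate(genes):
        null_fit, _ = fit_branch_model(
            gene, tree, "one_ratio", n_restarts=n_restarts,
            maxiter=maxiter, seed=seed + i,
        )
        # warm-start the alternative at the null optimum (guarantees nesting
        # and converges in few iterations)
        alt_fit, alt_rates = fit_branch_model(
            gene, tree, "two_ratio", fg_class=fg_class,
            maxiter=maxiter, seed=seed + i,
            x0=_two_ratio_start_from_null(null_fit, tree),
        )
        if n_restarts > 0:
            alt_fit2, alt_rates2 = fit_branch_model(
                gene, tree, "two_ratio", fg_class=fg_class,
                n_restarts=n_restarts - 1, maxiter=maxiter, seed=seed + i,
            )
            if alt_fit2.loglik > alt_fit.loglik:
                alt_fit, alt_rates = alt_fit2, alt_rates2
        if alt_fit.loglik < null_fit.loglik:
            alt_fit.loglik = null_fit.loglik  # boundary: alt nests the null
        lrt = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
        p = float(chi2.sf(lrt, df=1))
        rows.append(
            {
                "gene": i,
                "loglik_null": null_fit.loglik,
                "loglik_alt": alt_fit.loglik,
                "lrt": lrt,
                "df": 1,
                "p": p,
                "omega_fg": alt_fit.params["omega"]["fg"],
                "omega_bg": alt_fit.params["omega"]["bg"],
                "flags": ";".join(null_fit.flags + alt_fit.flags),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"])
    table["call"] = np.where(
        (table["p_adj"] < alpha) & (table["omega_fg"] > table["omega_bg"]),
        "FEG",
        "none",
    )
    return ScanResult(table)


def _two_ratio_start_from_null(null_fit, tree: Tree) -> np.ndarray:
    x = null_fit.params["_x"]  # [log kappa, log omega, log lengths...]
    return np.concatenate([[x[0]], [x[1], x[1]], x[2:]])


# --------------------------------------------------- branch-site Model A
class _BranchSiteLikelihood:
    """Model A: 4 site classes over a foreground/background partition."""

    def __init__(self, aln: Alignment, tree: Tree, fg_class: str):
        self.lik = CodonLikelihood(aln, tree)
        self.fg = np.array([b.cls == fg_class for b in self.lik.branches])
        if not self.fg.any():
            raise ValueError(f"no branch labelled {fg_class!r}")
        self.nb = len(self.lik.branches)

    def class_site_logliks(self, kappa, w0, w2, bl):
        lk = self.lik
        m = {w: codon_model(kappa, w, lk.pi) for w in {w0, 1.0, w2}}
        P = {
            w: {b.index: m[w].transition_matrix(t) for b, t in zip(lk.branches, bl)}
            for w in m
        }

        def mixed(fg_w, bg_w):
            pm = {
                b.index: (P[fg_w][b.index] if is_fg else P[bg_w][b.index])
                for b, is_fg in zip(lk.branches, self.fg)
            }
            return site_log_likelihoods(lk.tree, lk.leaf_states, pm, lk.pi)

        return np.stack(
            [
                mixed(w0, w0),  # class 0
                mixed(1.0, 1.0),  # class 1
                mixed(w2, w0),  # class 2a
                mixed(w2, 1.0),  # class 2b
            ]
        )

    @staticmethod
    def proportions(a: float, b: float) -> np.ndarray:
        e = np.exp([a, b, 0.0])
        p0, p1, p2 = e / e.sum()
        denom = p0 + p1
        return np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])

    def site_logliks(self, x: np.ndarray, null: bool) -> np.ndarray:
        kappa = float(np.exp(x[0]))
        a, b = float(x[1]), float(x[2])
        w0 = float(1.0 / (1.0 + np.exp(-x[3])))  # constrained to (0, 1)
        w2 = 1.0 if null else float(1.0 + np.exp(x[4]))
        bl = np.exp(x[(4 if null else 5):])
        props = self.proportions(a, b)
        comp = self.class_site_logliks(kappa, w0, w2, bl)
        return logsumexp(comp + np.log(props)[:, None], axis=0)

    def fit(self, null: bool, maxiter: int = 200, x0: np.ndarray | None = None):
        def nll(x):
            return -float(self.site_logliks(x, null).sum())

        nb = self.nb
        if x0 is None:
            x0 = np.concatenate(
                [
                    [np.log(2.0), 1.0, 0.0, -1.0],
                    [] if null else [np.log(1.0)],
                    np.full(nb, np.log(0.15)),
                ]
            )
        bounds = (
            [_LOG_KAPPA, (-8, 8), (-8, 8), (-12, 12)]
            + ([] if null else [(-6.0, np.log(49.0))])
            + [_LOG_BL] * nb
        )
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        return res


def psg_scan(
    genes: list[Alignment],
    tree: Tree,
    fg_class: str,
    alpha: float = 0.05,
    maxiter: int = 200,
    n_alt_starts: int = 3,
) -> ScanResult:
    """Branch-site positive-selection scan with naive-empirical-Bayes site
    posteriors (P(selected class | site) at the alternative MLEs).

    ``n_alt_starts`` controls how many alternative-model starting points are
    tried (the full set of 3 guards against the p2/omega2 saddle; 2 is a
    cheaper setting for calibration studies where power is not at stake).
    """
    rows, posteriors = [], []
    for i, gene in enumerate(genes):
        bs = _BranchSiteLikelihood(gene, tree, fg_class)
        res_null = bs.fit(null=True, maxiter=maxiter)
        x_null = res_null.x
        ll_null = -res_null.fun
        # the (p2, omega2) pair is a saddle when the null collapses p2 to ~0,
        # so try several alternative starts and keep the best
        alt_starts = [
            np.concatenate([x_null[:4], [np.log(0.5)], x_null[4:]]),
            np.concatenate(
                [[x_null[0], 0.0, 0.0, x_null[3]], [np.log(3.0)], x_null[4:]]
            ),
            np.concatenate([x_null[:4], [-5.9], x_null[4:]]),
        ]
        res_alt = None
        for s in alt_starts[: max(1, n_alt_starts)]:
            r = bs.fit(null=False, maxiter=maxiter, x0=s)
            if res_alt is None or r.fun < res_alt.fun:
                res_alt = r
        ll_alt = -res_alt.fun
        lrt = max(0.0, 2.0 * (ll_alt - ll_null))
        p = float(chi2.sf(lrt, df=1))
        x = res_alt.x
        kappa = float(np.exp(x[0]))
        w0 = float(1.0 / (1.0 + np.exp(-x[3])))
        w2 = float(1.0 + np.exp(x[4]))
        bl = np.exp(x[5:])
        props = bs.proportions(float(x[1]), float(x[2]))
        comp = bs.class_site_logliks(kappa, w0, w2, bl)
        log_joint = comp + np.log(props)[:, None]
        log_total = logsumexp(log_joint, axis=0)
        post_sel = np.exp(logsumexp(log_joint[2:], axis=0) - log_total)
        posteriors.append(post_sel)
        rows.append(
            {
                "gene": i,
                "loglik_null": ll_null,
                "loglik_alt": max(ll_alt, ll_null),
                "lrt": lrt,
                "df": 1,
                "p": p,
                "omega_fg": w2,
                "omega_bg": w0,
                "p_selected_class": float(props[2] + props[3]),
                "flags": "",
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"])
    table["call"] = np.where(table["p_adj"] < alpha, "PSG", "none")
    return ScanResult(table, site_posteriors=posteriors)


# ----------------------------------------------------------- group means
def group_mean_dnds(
    rates: pd.DataFrame | list,
    group_map: dict[str, str],
    value: str = "omega",
    exclude_above: float = 5.0,
):
    """Group-level summaries of terminal-branch rates.

    ``rates``: concatenated per-branch tables from free-ratio fits (or a
    list of BranchRates); ``group_map``: leaf name -> group. Values above
    ``exclude_above`` are dropped before averaging (dN/dS > 5 rule). Returns
    a dict with per-group means, the surviving per-branch values, and a
    gene-by-group matrix for clustering/heatmaps.
    """
    if isinstance(rates, list):
        frames = []
        for g, br in enumerate(rates):
            df = br.table.copy() if hasattr(br, "table") else br.copy()
            df["gene"] = g
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
    else:
        df = rates.copy()
        if "gene" not in df.columns:
            df["gene"] = 0
    if "leafset" in df.columns:
        is_terminal = ~df["leafset"].astype(str).str.contains(",")
        unmapped = set(df.loc[is_terminal, "branch"]) - set(group_map)
        if unmapped:
            raise ValueError(f"terminal branches without a group: {sorted(unmapped)}")
    terminal = df[df["branch"].isin(group_map)].copy()
    terminal["group"] = terminal["branch"].map(group_map)
    vals = terminal[np.isfinite(terminal[value]) & (terminal[value] <= exclude_above)]
    means = vals.groupby("group")[value].mean()
    for group in set(group_map.values()) - set(means.index):
        warnings.warn(f"group {group!r} has no surviving branches; mean is NA")
        means.loc[group] = np.nan
    gene_by_group = vals.pivot_table(
        index="gene", columns="group", values=value, aggfunc="mean"
    )
    return {"means": means.sort_index(), "values": vals, "gene_by_group": gene_by_group}
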
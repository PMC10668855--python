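"""Supermatrix quality-control statistics and gene filtration.

Implements the four filtration statistics applied to ortholog sets before
phylogenomic analysis: per-taxon completeness, relative composition
frequency variability (RCFV), chi-square composition tests against the
pooled frequencies, and matched-pairs (Bowker) symmetry tests on pairwise
divergence matrices. Thresholded filtration with per-gene removal reasons
ties them together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from amphievo.core.alignment import Alignment


@dataclass
class CompositionReport:
    frequencies: pd.DataFrame  # taxa x states
    rcfv_per_taxon: pd.Series
    rcfv: float
    chi2_stat: pd.Series | None = None
    chi2_p: pd.Series | None = None
    excluded_taxa: list[str] = field(default_factory=list)


@dataclass
class SymmetryMatrix:
    stats: pd.DataFrame
    dof: pd.DataFrame
    pvalues: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.pvalues.to_csv(path, sep="\t")


def _state_alphabet(aln: Alignment) -> list[str]:
    if aln.alphabet == "AA20":
        from amphievo.core.codes import AA_ALPHABET

        return list(AA_ALPHABET)
    return list("ACGT")


def completeness_score(aln: Alignment) -> tuple[pd.Series, float]:
    """Proportion of non-missing cells per taxon, and overall."""
    if aln.n_sites == 0 or aln.n_taxa == 0:
        raise ValueError("empty alignment")
    present = ~aln.missing_mask()
    per_taxon = pd.Series(present.mean(axis=1), index=aln.taxa, name="completeness")
    return per_taxon, float(present.mean())


def _taxon_state_counts(aln: Alignment) -> pd.DataFrame:
    states = _state_alphabet(aln)
    sites = np.char.upper(aln.sites.astype("<U1"))
    counts = np.zeros((aln.n_taxa, len(states)))
    for j, s in enumerate(states):
        counts[:, j] = (sites == s).sum(axis=1)
    return pd.DataFrame(counts, index=aln.taxa, columns=states)


def rcfv(aln: Alignment) -> CompositionReport:
    """Relative composition frequency variability.

    RCFV = sum over taxa and states of |f(taxon, state) - mean f(state)|
    divided by the number of taxa, on non-missing cells. Taxa with zero
    non-missing cells are excluded with a warning.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    counts = _taxon_state_counts(aln)
    totals = counts.sum(axis=1)
    excluded = list(counts.index[totals == 0])
    if excluded:
        warnings.warn(f"taxa with no data excluded from RCFV: {excluded}")
        counts = counts[totals > 0]
        totals = totals[totals > 0]
    freqs = counts.div(totals, axis=0)
    mean_f = freqs.mean(axis=0)
    n_taxa = freqs.shape[0]
    contrib = (freqs - mean_f).abs().sum(axis=1) / n_taxa
    return CompositionReport(
        frequencies=freqs,
        rcfv_per_taxon=contrib.rename("rcfv_contribution"),
        rcfv=float(contrib.sum()),
        excluded_taxa=excluded,
    )


def chi2_composition_test(aln: Alignment) -> pd.DataFrame:
    """Per-taxon chi-square of state counts against the pooled composition.

    States whose expected count is zero for a taxon are dropped from that
    taxon's test with the degrees of freedom adjusted accordingly.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    counts = _taxon_state_counts(aln)
    pooled = counts.sum(axis=0)
    pooled_freq = pooled / pooled.sum()
    rows = []
    for taxon in counts.index:
        obs = counts.loc[taxon].to_numpy()
        n = obs.sum()
        exp = pooled_freq.to_numpy() * n
        keep = exp > 0
        stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
        df = int(keep.sum()) - 1
        p = float(chi2.sf(stat, df)) if df > 0 else np.nan
        rows.append({"taxon": taxon, "chi2": stat, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("taxon")


def bowker_test(seq_a: np.ndarray, seq_b: np.ndarray, states: list[str]):
    """Bowker matched-pairs symmetry test for one taxon pair.

    Returns (statistic, df, p); (nan, 0, nan) when no shared informative
    sites exist, and p=nan with df=0 when the divergence matrix has no
    off-diagonal counts.
    """
    lookup = {s: i for i, s in enumerate(states)}
    k = len(states)
    table = np.zeros((k, k))
    for a, b in zip(seq_a, seq_b):
        ia, ib = lookup.get(a.upper()), lookup.get(b.upper())
        if ia is None or ib is None:
            continue
        table[ia, ib] += 1
    if table.sum() == 0:
        return np.nan, 0, np.nan
    stat, df = 0.0, 0
    for i in range(k):
        for j in range(i + 1, k):
            tot = table[i, j] + table[j, i]
            if tot > 0:
                stat += (table[i, j] - table[j, i]) ** 2 / tot
                df += 1
    if df == 0:
        return 0.0, 0, np.nan
    return float(stat), df, float(chi2.sf(stat, df))


def bowker_pairwise_matrix(aln: Alignment) -> SymmetryMatrix:
    """Bowker statistics, dof and p-values for every taxon pair."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    states = _state_alphabet(aln)
    n = aln.n_taxa
    stats = np.full((n, n), np.nan)
    dof = np.zeros((n, n))
    pvals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            s, d, p = bowker_test(aln.sites[i], aln.sites[j], states)
            stats[i, j] = stats[j, i] = s
            dof[i, j] = dof[j, i] = d
            pvals[i, j] = pvals[j, i] = p
    idx = list(aln.taxa)
    return SymmetryMatrix(
        stats=pd.DataFrame(stats, index=idx, columns=idx),
        dof=pd.DataFrame(dof, index=idx, columns=idx),
        pvalues=pd.DataFrame(pvals, index=idx, columns=idx),
    )


@dataclass
class FilterThresholds:
    min_completeness: float | None = 0.7
    max_rcfv: float | None = 0.025
    chi2_alpha: float | None = 0.01
    bowker_alpha: float = 0.05
    max_bowker_violation_fraction: float | None = 0.5


def filter_genes(
    genes: dict[str, Alignment] | list[Alignment],
    thresholds: FilterThresholds | None = None,
) -> tuple[dict[str, Alignment], pd.DataFrame]:
    """Apply the QC thresholds gene-wise; returns (retained, report).

    Each gene failing an enabled criterion is removed with the reason
    recorded. Disabled criteria (None) are skipped. Raises if every gene is
    removed.
    """
    thresholds = thresholds or FilterThresholds()
    if isinstance(genes, list):
        genes = {f"gene{i}": g for i, g in enumerate(genes)}
    retained: dict[str, Alignment] = {}
    rows = []
    for name, aln in genes.items():
        reasons = []
        _, overall = completeness_score(aln)
        if thresholds.min_completeness is not None and overall < thresholds.min_completeness:
            reasons.append(f"completeness {overall:.3f} < {thresholds.min_completeness}")
        report = rcfv(aln)
        if thresholds.max_rcfv is not None and report.rcfv >= thresholds.max_rcfv:
            reasons.append(f"rcfv {report.rcfv:.4f} >= {thresholds.max_rcfv}")
        if thresholds.chi2_alpha is not None:
            comp = chi2_composition_test(aln)
            n_het = int((comp["p"] < thresholds.chi2_alpha).sum())
            if n_het > 0:
                reasons.append(f"chi2 heterogeneous taxa: {n_het}")
        if thresholds.max_bowker_violation_fraction is not None:
            sym = bowker_pairwise_matrix(aln)
            tri = sym.pvalues.to_numpy()[np.triu_indices(aln.n_taxa, k=1)]
            valid = tri[~np.isnan(tri)]
            if valid.size:
                frac = float((valid < thresholds.bowker_alpha).mean())
                if frac > thresholds.max_bowker_violation_fraction:
                    reasons.append(f"bowker violation fraction {frac:.2f}")
        rows.append(
            {
                "gene": name,
                "retained": not reasons,
                "completeness": overall,
                "rcfv": report.rcfv,
                "reasons": "; ".join(reasons),
            }
        )
        if not reasons:
            retained[name] = aln
    report_df = pd.DataFrame(rows).set_index("gene")
    if not retained:
        raise ValueError("all genes removed; relax the QC thresholds")
    return retained, report_df


def parsimony_informative_fraction(aln: Alignment) -> float:
    """Proxy for information content: fraction of parsimony-informative
    sites (NOT the quartet-geometry metric of MARE)."""
    mask = aln.missing_mask()
    count = 0
    for j in range(aln.n_sites):
        col = aln.sites[~mask[:, j], j]
        if col.size < 4:
            continue
        vals, cnts = np.unique(np.char.upper(col.astype("<U1")), return_counts=True)
        if (cnts >= 2).sum() >= 2:
            count += 1
    return count / aln.n_sites if aln.n_sites else 0.0
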
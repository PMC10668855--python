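"""Rapidly evolving GO category (REGO) detection.

Gene-level dN/dS values are aggregated per GO term (with annotation
propagated to ancestor terms), each term's distribution is compared to the
background of all other genes by a one-sided Wilcoxon rank-sum test, and
terms significant after BH-FDR are flagged as REGOs. The development
proportion summarizes how many REGOs descend from a designated
developmental-process root term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from amphievo.codon_selection.scans import bh_adjust


@dataclass
class GOAnnotation:
    """gene -> GO terms plus a term -> parents DAG slice."""

    gene_terms: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict[str, int] = {}

        def visit(term):
            if state.get(term) == 1:
                raise ValueError(f"GO DAG contains a cycle through {term}")
            if state.get(term) == 2:
                return
            state[term] = 1
            for p in self.parents.get(term, ()):
                visit(p)
            state[term] = 2

        for t in list(self.parents):
            visit(t)

    def ancestors(self, term: str) -> set[str]:
        out, stack = set(), [term]
        while stack:
            for p in self.parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def descendants(self, term: str) -> set[str]:
        children: dict[str, set[str]] = {}
        for child, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(child)
        out, stack = set(), [term]
        while stack:
            for c in children.get(stack.pop(), ()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def propagated_gene_terms(self) -> dict[str, set[str]]:
        out = {}
        for gene, terms in self.gene_terms.items():
            full = set(terms)
            for t in terms:
                full |= self.ancestors(t)
            out[gene] = full
        return out

    @classmethod
    def from_tables(cls, gene_term: pd.DataFrame, term_parent: pd.DataFrame | None = None):
        """gene_term: columns (gene, term); term_parent: columns (term, parent)."""
        gt: dict[str, set[str]] = {}
        for gene, term in gene_term.iloc[:, :2].itertuples(index=False):
            gt.setdefault(str(gene), set()).add(str(term))
        parents: dict[str, set[str]] = {}
        if term_parent is not None:
            for term, parent in term_parent.iloc[:, :2].itertuples(index=False):
                parents.setdefault(str(term), set()).add(str(parent))
        return cls(gt, parents)


def category_dnds(
    gene_omega: pd.Series,
    annotation: GOAnnotation,
    min_genes: int = 5,
    propagate: bool = True,
) -> dict[str, pd.Series]:
    """Per-GO-term vectors of member-gene omega values.

    Genes annotated to a child term are counted at ancestor terms when
    ``propagate`` is on; terms with fewer than ``min_genes`` members are
    skipped. Annotated genes missing from the omega table are dropped with
    a warning.
    """
    if not annotation.gene_terms:
        raise ValueError("empty annotation")
    import warnings

    gt = annotation.propagated_gene_terms() if propagate else annotation.gene_terms
    dropped = [g for g in gt if g not in gene_omega.index]
    if dropped:
        warnings.warn(f"{len(dropped)} annotated genes missing omega values; dropped")
    term_genes: dict[str, list[str]] = {}
    for gene, terms in gt.items():
        if gene not in gene_omega.index:
            continue
        for t in terms:
            term_genes.setdefault(t, []).append(gene)
    out = {}
    for term, members in term_genes.items():
        if len(members) < min_genes:
            continue
        out[term] = gene_omega.loc[sorted(set(members))]
    return out


def rego_scan(
    categories: dict[str, pd.Series],
    gene_omega: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (greater) Wilcoxon rank-sum per term vs all other genes.

    Background for each term = genes not annotated to the term. BH-FDR
    across terms; REGO iff adjusted p < alpha.
    """
    rows = []
    for term, vals in categories.items():
        background = gene_omega.drop(index=vals.index, errors="ignore")
        if len(background) == 0 or len(vals) == 0:
            continue
        try:
            stat, p = mannwhitneyu(vals, background, alternative="greater")
        except ValueError:  # all values identical
            stat, p = np.nan, 1.0
        rows.append(
            {
                "term": term,
                "n_genes": len(vals),
                "median_omega": float(vals.median()),
                "mean_omega": float(vals.mean()),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = bh_adjust(table["p"])
    table["rego"] = table["p_adj"] < alpha
    return table.set_index("term").sort_values("p")


def rego_by_group(
    group_gene_omega: dict[str, pd.Series],
    annotation: GOAnnotation,
    min_genes: int = 5,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """REGO scan per group, with a unique-to-group flag (exclusive
    significance across groups)."""
    results = {}
    for group, omega in group_gene_omega.items():
        cats = category_dnds(omega, annotation, min_genes=min_genes)
        results[group] = rego_scan(cats, omega, alpha=alpha)
    rego_sets = {
        g: set(t.index[t["rego"]]) if not t.empty else set()
        for g, t in results.items()
    }
    for group, table in results.items():
        if table.empty:
            continue
        others = set().union(*(s for g, s in rego_sets.items() if g != group))
        table["unique_to_group"] = table["rego"] & ~table.index.isin(others)
    return results


def development_proportion(rego_table: pd.DataFrame, annotation: GOAnnotation, root: str):
    """Fraction of REGO terms at or below the developmental-process root."""
    regos = set(rego_table.index[rego_table["rego"]]) if not rego_table.empty else set()
    if not regos:
        return np.nan
    dev = annotation.descendants(root) | {root}
    return len(regos & dev) / len(regos)
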
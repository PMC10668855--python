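"""Neutral rates from 4-fold degenerate third codon positions.

A codon column qualifies as 4-fold degenerate when every non-missing taxon
carries the same first two nucleotides and that dinucleotide prefix admits
all four third bases as sense, synonymous codons. The extracted third
positions form a nucleotide alignment on which GTR branch lengths are
fitted; those lengths are the per-branch neutral rates.
"""

from __future__ import annotations

import numpy as np

from amphievo.core import codes
from amphievo.core.alignment import Alignment
from amphievo.core.tree import Tree
from amphievo.topology_tests.likelihood import fit_fixed_topology

LOW_CONFIDENCE_SITES = 50


def fourfold_sites(aln: Alignment) -> Alignment:
    """Extract third positions of conserved 4-fold degenerate codon columns."""
    if aln.alphabet != "CODON61":
        raise ValueError("codon alignment required")
    n_codons = aln.n_sites // 3
    keep_cols = []
    for c in range(n_codons):
        block = aln.sites[:, 3 * c : 3 * c + 3]
        prefixes = set()
        ok = True
        for row in block:
            codon = "".join(row).upper()
            if any(ch in aln.missing for ch in codon):
                continue
            prefix = codon[:2]
            if prefix not in codes.FOURFOLD_PREFIXES:
                ok = False
                break
            prefixes.add(prefix)
        if ok and len(prefixes) == 1:
            keep_cols.append(3 * c + 2)
    if not keep_cols:
        sites = np.empty((aln.n_taxa, 0), dtype="<U1")
    else:
        sites = aln.sites[:, keep_cols]
    return Alignment(list(aln.taxa), sites, "DNA4")


def fourfold_rates(aln: Alignment, tree: Tree, maxiter: int = 200):
    """Per-branch substitution rates at 4D sites (GTR branch lengths).

    Returns (rates dict keyed by branch leaf set, fit, flags).
    """
    sub = fourfold_sites(aln)
    flags = []
    if sub.n_sites < LOW_CONFIDENCE_SITES:
        flags.append(f"low_confidence: only {sub.n_sites} 4D sites")
    if sub.n_sites == 0:
        raise ValueError("no 4-fold degenerate sites found")
    fit = fit_fixed_topology(sub, tree, fit_alpha=False, maxiter=maxiter)
    return fit.params["branch_lengths"], fit, flags
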
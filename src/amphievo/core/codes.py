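"""Genetic code tables and codon bookkeeping.

The standard code with 61 sense codons is used throughout; stop codons are
never simulated and are rejected on input. Codons are indexed in
lexicographic ACGT order over the sense codons.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

MISSING_SYMBOLS = frozenset("-?NnXx.")


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _build_code(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    sense = sorted(c for c in table.forward_table if c not in stops)
    aa = {c: table.forward_table[c] for c in sense}
    return sense, aa, stops


SENSE_CODONS, CODON_TO_AA, STOP_CODONS = _build_code(1)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA_INDEX = np.array([AA_INDEX[CODON_TO_AA[c]] for c in SENSE_CODONS])


def _pair_structure():
    """Classify all single-nucleotide codon pairs.

    Returns index arrays (i, j) of sense-codon pairs differing at exactly one
    position, with parallel boolean arrays for transition and synonymous
    status, plus the position of the difference.
    """
    ii, jj, ts, syn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[k], cj[k]))
            syn.append(CODON_TO_AA[ci] == CODON_TO_AA[cj])
            pos.append(k)
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
        np.array(pos),
    )


PAIR_I, PAIR_J, PAIR_IS_TS, PAIR_IS_SYN, PAIR_POS = _pair_structure()


def fourfold_degenerate_prefixes() -> set[str]:
    """Dinucleotide prefixes whose four codons are sense and synonymous."""
    out = set()
    for a in NUCS:
        for b in NUCS:
            codons = [a + b + c for c in NUCS]
            if any(c in STOP_CODONS for c in codons):
                continue
            aas = {CODON_TO_AA[c] for c in codons}
            if len(aas) == 1:
                out.add(a + b)
    return out


FOURFOLD_PREFIXES = fourfold_degenerate_prefixes()


def codons_to_indices(seq: str) -> np.ndarray:
    """Translate a nucleotide string into sense-codon indices; -1 = missing.

    Raises ValueError on in-frame stop codons.
    """
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3].upper()
        if codon in CODON_INDEX:
            out[k // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at codon position {k // 3}")
        else:
            out[k // 3] = -1
    return out
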
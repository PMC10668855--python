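"""Taxon-labelled character matrices with FASTA / relaxed-PHYLIP IO."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from amphievo.core import codes

ALPHABETS = ("DNA4", "AA20", "CODON61")


@dataclass
class Alignment:
    """An aligned character matrix.

    ``sites`` is an (n_taxa, n_columns) array of single characters; for
    CODON61 alignments columns are nucleotides and the length is divisible
    by 3 with no in-frame stop codons among non-missing triplets.
    """

    taxa: list[str]
    sites: np.ndarray
    alphabet: str = "DNA4"
    missing: frozenset = field(default_factory=lambda: codes.MISSING_SYMBOLS)

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype="<U1")
        if self.sites.ndim != 2:
            raise ValueError("sites must be 2-D")
        if len(self.taxa) != self.sites.shape[0]:
            raise ValueError("taxa / row count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "CODON61":
            if self.sites.shape[1] % 3:
                raise ValueError("codon alignment length not divisible by 3")
            self._check_no_stops()

    def _check_no_stops(self):
        for row, taxon in zip(self.sites, self.taxa):
            seq = "".join(row)
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3].upper()
                if codon in codes.STOP_CODONS:
                    raise ValueError(f"stop codon {codon} in {taxon} at codon {k // 3}")

    # ------------------------------------------------------------------ views
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.sites[self.taxa.index(taxon)])

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        mask = np.zeros(self.sites.shape, dtype=bool)
        for sym in self.missing:
            mask |= self.sites == sym
        return mask

    def state_indices(self) -> np.ndarray:
        """Integer state matrix, -1 for missing / unrecognized symbols.

        For CODON61 the result has one column per codon.
        """
        if self.alphabet == "DNA4":
            lookup = codes.NUC_INDEX
        elif self.alphabet == "AA20":
            lookup = codes.AA_INDEX
        else:
            out = np.empty((self.n_taxa, self.n_sites // 3), dtype=np.int64)
            for i in range(self.n_taxa):
                out[i] = codes.codons_to_indices("".join(self.sites[i]))
            return out
        out = np.full(self.sites.shape, -1, dtype=np.int64)
        for sym, idx in lookup.items():
            out[self.sites == sym] = idx
            out[self.sites == sym.lower()] = idx
        return out

    def subset_taxa(self, keep: list[str]) -> "Alignment":
        rows = [self.taxa.index(t) for t in keep]
        return Alignment(list(keep), self.sites[rows].copy(), self.alphabet)

    def n_states(self) -> int:
        return {"DNA4": 4, "AA20": 20, "CODON61": 61}[self.alphabet]

    # --------------------------------------------------------------------- IO
    def to_fasta(self, path=None) -> str | None:
        records = [
            SeqRecord(Seq("".join(row)), id=taxon, description="")
            for taxon, row in zip(self.taxa, self.sites)
        ]
        if path is None:
            buf = io.StringIO()
            SeqIO.write(records, buf, "fasta")
            return buf.getvalue()
        SeqIO.write(records, str(path), "fasta")
        return None

    @classmethod
    def from_fasta(cls, source, alphabet: str = "DNA4") -> "Alignment":
        if isinstance(source, str) and source.lstrip().startswith(">"):
            handle = io.StringIO(source)
        else:
            handle = open(source)
        try:
            records = list(SeqIO.parse(handle, "fasta"))
        finally:
            handle.close()
        if not records:
            raise ValueError("no sequences found")
        taxa = [r.id for r in records]
        rows = [list(str(r.seq)) for r in records]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("unequal sequence lengths")
        return cls(taxa, np.array(rows, dtype="<U1"), alphabet)

    @classmethod
    def from_phylip(cls, source, alphabet: str = "DNA4") -> "Alignment":
        """Relaxed sequential PHYLIP: header line then `name  sequence` rows."""
        if isinstance(source, str) and "\n" in source:
            lines = source.splitlines()
        else:
            with open(source) as fh:
                lines = fh.read().splitlines()
        header = lines[0].split()
        n, length = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in lines[1:]:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.replace(" ", "")
            taxa.append(name)
            rows.append(list(seq))
            if len(taxa) == n:
                break
        aln = cls(taxa, np.array(rows, dtype="<U1"), alphabet)
        if aln.n_sites != length:
            raise ValueError("PHYLIP header length mismatch")
        return aln
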
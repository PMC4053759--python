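"""In-memory multiple alignment with integer-coded bases.

Bases are coded A=0, C=1, G=2, T=3, '-'=4, 'N'=5.  Ambiguity codes other
than N are treated as N.  Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "GAP", "NCODE", "encode", "decode"]

_ALPHABET = "ACGT-N"
GAP = 4
NCODE = 5

_ENC = np.full(256, NCODE, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_ENC[ord(".")] = GAP

_DEC = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to a string."""
    return _DEC[codes].tobytes().decode()


class Alignment:
    """Ordered taxa x columns matrix of coded bases (may be ungapped)."""

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise ValueError("matrix must be (n_taxa, n_columns)")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        self.taxa = list(taxa)
        self.matrix = matrix
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_strings(cls, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> "Alignment":
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        lengths = {len(s) for _, s in items}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        mat = np.vstack([encode(s) for _, s in items]) if items else np.zeros((0, 0), np.uint8)
        return cls([n for n, _ in items], mat)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        return cls.from_strings([(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")])

    # -- access ------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self._index[taxon]]

    def sequence(self, taxon: str) -> str:
        return decode(self.row(taxon))

    def to_dict(self) -> dict[str, str]:
        return {t: decode(self.matrix[i]) for i, t in enumerate(self.taxa)}

    def take_columns(self, cols: np.ndarray) -> "Alignment":
        return Alignment(self.taxa, self.matrix[:, cols])

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self._index[t] for t in taxa]
        return Alignment(list(taxa), self.matrix[idx])

    # -- io ----------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(decode(self.matrix[i])), id=t, description="")
            for i, t in enumerate(self.taxa)
        ]
        SeqIO.write(records, str(path), "fasta")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa x {len(self)} columns)"
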
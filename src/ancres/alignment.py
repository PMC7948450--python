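"""Aligned amino-acid matrix backed by an integer-coded numpy array."""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substitution import AMINO_ACIDS, GAP_CODE, N_STATES, encode_residue

_DECODE = np.array(list(AMINO_ACIDS) + ["-", "X"])


@dataclass
class Alignment:
    """A protein multiple sequence alignment.

    ``codes`` is a (n_taxa, n_sites) int8 matrix over the 20 amino-acid codes
    plus ``GAP_CODE`` (20) and ``UNKNOWN_CODE`` (21).  Site coordinates are
    1-based in all reports, 0-based internally.
    """

    ids: list[str]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("one id per row required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.ids.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(_DECODE[np.minimum(self.row(taxon), N_STATES + 1)])

    @classmethod
    def from_sequences(cls, items) -> "Alignment":
        """Build from an iterable of (id, aligned sequence) pairs."""
        ids, rows = [], []
        length = None
        for name, seq in items:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            ids.append(name)
            rows.append([encode_residue(c) for c in seq])
        if not ids:
            raise ValueError("empty alignment")
        return cls(ids=ids, codes=np.array(rows, dtype=np.int8))

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences(records)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(name)), id=name, description="")
            for name in self.ids
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_fasta_string(self) -> str:
        buf = StringIO()
        records = [
            SeqRecord(Seq(self.sequence(name)), id=name, description="")
            for name in self.ids
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_sites) matrix, True where a cell is a gap."""
        return self.codes == GAP_CODE
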
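"""DNA sequence container and FASTA I/O.

Sequences are plain uppercase strings over {A, C, G, T, N}. Coordinates
throughout the package are 0-based, half-open, on the + strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DnaSequence:
    """A labelled DNA sequence.

    Parameters
    ----------
    id : str
        Record label.
    seq : str
        Sequence over {A, C, G, T, N}; lower-case input is canonicalised.
    origin : str
        Provenance note (file path, generator call, ...).
    """

    id: str
    seq: str
    origin: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        canonical = self.seq.upper()
        bad = set(canonical) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", canonical)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.id, revcomp(self.seq), origin=self.origin)


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a (multi-record) FASTA file into DnaSequence records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(DnaSequence(rec.id, str(rec.seq), origin=str(path)))
    return records


def write_fasta(records: Iterable[DnaSequence], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.origin) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
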
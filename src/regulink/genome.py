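"""In-memory genome sequence with FASTA I/O.

The genomes this package works on (either the synthetic study genomes or
small extracted regions) are megabase-scale, so whole-genome in-memory
storage with plain string slicing is the simplest correct representation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataFormatError

__all__ = ["Genome", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Chromosome name -> uppercase sequence mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise DataFormatError(f"no sequences found in FASTA file {path}")
        return cls(records)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            SeqIO.write(
                (
                    SeqRecord(Seq(seq), id=name, description="")
                    for name, seq in self._seqs.items()
                ),
                fh,
                "fasta",
            )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> Iterable[str]:
        return self._seqs.keys()

    def length(self, chrom: str) -> int:
        self._require(chrom)
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end) on ``chrom`` (0-based half-open)."""
        self._require(chrom)
        return self._seqs[chrom][max(0, start):end]

    def sequence(self, chrom: str) -> str:
        self._require(chrom)
        return self._seqs[chrom]

    def _require(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise DataFormatError(
                f"chromosome {chrom!r} absent from genome "
                f"(has: {', '.join(sorted(self._seqs))})"
            )
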
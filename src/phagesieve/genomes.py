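"""Reference genome records and FASTA input/output."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence with a stable identifier.

    Used both for full reference genomes and for query contigs; ``length``
    is always the literal sequence length in base pairs.
    """

    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Load all records from a FASTA file, preserving order."""
    return [
        GenomeRecord(genome_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[GenomeRecord], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.genome_id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")
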
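"""Contig container and FASTA input/output.

A :class:`Contig` is the unit of every curation step: a named sequence with an
optional circular flag (set for trimmed organelle replicons).  FASTA handling
goes through Biopython; output is wrapped at 80 columns and written in input
order so that fixed-seed runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Contig:
    name: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def rename(self, name: str) -> "Contig":
        return replace(self, name=name)


def read_fasta(path: str | Path) -> list[Contig]:
    contigs = [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = (SeqRecord(Seq(c.seq), id=c.name, description="") for c in contigs)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def total_length(contigs: Iterable[Contig]) -> int:
    return sum(len(c) for c in contigs)
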
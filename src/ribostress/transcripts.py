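"""Transcript records and their on-disk representations.

Everything downstream works in transcript coordinates: position 0 is the
transcript 5' end, the CDS is a 0-based half-open interval ``[cds_start,
cds_end)`` that includes the stop codon, the 5' leader is ``[0, cds_start)``
and the 3' trailer is ``[cds_end, len)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = set("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

ANNOTATION_COLUMNS = ["gene_id", "tx_id", "cds_start", "cds_end", "coding_flag"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: sequence plus CDS interval, the coordinate frame for
    read counting, uORF discovery and metagene aggregation."""

    tx_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    coding_flag: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= VALID_ALPHABET:
            bad = sorted(set(seq) - VALID_ALPHABET)
            raise ValueError(f"{self.tx_id}: invalid characters in sequence: {bad}")
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"{self.tx_id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"transcript of length {len(seq)}"
            )
        if self.coding_flag and (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.tx_id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def leader_length(self) -> int:
        return self.cds_start

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def trailer_length(self) -> int:
        return self.length - self.cds_end

    @property
    def leader_seq(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds_seq(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.tx_id, description=f"gene={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_annotation(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "tx_id": r.tx_id,
                "cds_start": r.cds_start,
                "cds_end": r.cds_end,
                "coding_flag": int(r.coding_flag),
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_transcripts(
    fasta_path: str | Path, annotation_path: str | Path
) -> dict[str, TranscriptRecord]:
    """Join a transcript FASTA with the CDS annotation TSV.

    Sequences present in the FASTA but absent from the annotation (e.g. the
    spike-in oligo) are ignored; annotated transcripts missing from the FASTA
    raise.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t")
    out: dict[str, TranscriptRecord] = {}
    for row in ann.itertuples(index=False):
        if row.tx_id not in seqs:
            raise KeyError(f"annotated transcript {row.tx_id!r} missing from FASTA")
        out[row.tx_id] = TranscriptRecord(
            tx_id=row.tx_id,
            gene_id=row.gene_id,
            sequence=seqs[row.tx_id],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            coding_flag=bool(getattr(row, "coding_flag", True)),
        )
    return out


def by_gene(transcripts: Iterable[TranscriptRecord]) -> dict[str, list[TranscriptRecord]]:
    genes: dict[str, list[TranscriptRecord]] = {}
    for rec in transcripts:
        genes.setdefault(rec.gene_id, []).append(rec)
    return genes
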
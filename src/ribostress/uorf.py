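"""Upstream open reading frames and ribosome-density geometry.

A uORF is an AUG-initiated run of sense codons in the 5' leader,
uninterrupted by a stop codon.  A uORF that reaches the annotated CDS
without terminating is truncated at the CDS start (to keep read attribution
unambiguous), and nested uORFs - those starting inside an accepted uORF in
the same frame, which would share its stop - are excluded.  A uORF counts
as translated when more than five footprints place their A-site inside it.

The module also computes the centre of ribosome density (the median
coordinate of the footprint distribution along a transcript) and its
stress-induced shift normalized by CDS length, initiation-context frequency
tables, and per-class leader statistics.
"""

from __future__ import annotations

import re
import subprocess
from collections import Counter
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcripts import STOP_CODONS, TranscriptRecord

DEFAULT_START_CODONS = ("ATG",)
NEAR_COGNATE_START_CODONS = ("ATG", "CTG", "GTG", "TTG", "ACG", "ATT", "ATA", "ATC", "AGG", "AAG")
TRANSLATED_MIN_READS = 5


@dataclass(frozen=True)
class UorfRecord:
    tx_id: str
    start: int  # 0-based A of the start codon
    end: int  # half-open; first nt after the last sense codon, or cds_start
    start_codon: str
    length_codons: int  # sense codons including the initiator, excluding stop
    truncated_flag: bool
    ribo_reads: int = 0
    te: float = float("nan")
    translated_flag: bool = False

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ShiftResult:
    gene_id: str
    center_control: int
    center_stress: int
    cds_length: int
    shift: float


def find_uorfs(
    transcript: TranscriptRecord,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[UorfRecord]:
    """Scan the 5' leader for uORFs.

    Every start-codon occurrence wholly upstream of the CDS opens a
    candidate, which extends codon by codon until an in-frame stop or, if
    none occurs before the CDS, is truncated at ``cds_start``.  Candidates
    whose start falls inside an already-accepted uORF in the same frame are
    skipped.  Records come back sorted by start coordinate.
    """
    seq = transcript.sequence
    cs = transcript.cds_start
    starts = tuple(c.upper().replace("U", "T") for c in start_codons)
    accepted: list[UorfRecord] = []
    for i in range(0, max(cs - 2, 0)):
        if seq[i : i + 3] not in starts:
            continue
        if i + 3 > cs:  # initiator codon must fit in the leader
            continue
        if any(
            u.start <= i < u.end and (i - u.start) % 3 == 0 for u in accepted
        ):
            continue  # nested in the same frame: shares a downstream stop
        j = i + 3
        truncated = True
        end = cs
        while j + 3 <= cs:
            if seq[j : j + 3] in STOP_CODONS:
                end = j
                truncated = False
                break
            j += 3
        length = (cs - i) // 3 if truncated else (end - i) // 3
        accepted.append(
            UorfRecord(
                tx_id=transcript.tx_id,
                start=i,
                end=end,
                start_codon=seq[i : i + 3],
                length_codons=length,
                truncated_flag=truncated,
            )
        )
    return accepted


def call_translated(
    uorf: UorfRecord,
    ribo_vector: np.ndarray,
    min_reads: int = TRANSLATED_MIN_READS,
) -> UorfRecord:
    """Attach the A-site read count and the translated call (> min_reads)."""
    reads = int(np.asarray(ribo_vector)[uorf.start : uorf.end].sum())
    return replace(uorf, ribo_reads=reads, translated_flag=reads > min_reads)


def uorf_te(
    uorf: UorfRecord, ribo_vector: np.ndarray, rna_vector: np.ndarray
) -> float:
    """uORF TE: footprint density over the uORF / mRNA density over the
    whole transcript.  NaN when the transcript has no RNA reads."""
    rna_total = float(np.asarray(rna_vector).sum())
    tx_len = len(rna_vector)
    if rna_total <= 0 or tx_len == 0:
        return float("nan")
    ribo_reads = float(np.asarray(ribo_vector)[uorf.start : uorf.end].sum())
    return (ribo_reads / uorf.length_nt) / (rna_total / tx_len)


def best_uorf(records: Iterable[UorfRecord]) -> UorfRecord:
    """Among translated uORFs, the one with the most footprints (ties go to
    the 5'-most)."""
    translated = [u for u in records if u.translated_flag]
    if not translated:
        raise ValueError("no translated uORF to choose from")
    return min(translated, key=lambda u: (-u.ribo_reads, u.start))


def density_center(vector: np.ndarray) -> int | None:
    """Minimal coordinate c with at least as many reads at positions <= c as
    at positions > c; None for an empty profile."""
    v = np.asarray(vector, dtype=np.int64)
    total = int(v.sum())
    if total == 0:
        return None
    cum = np.cumsum(v)
    return int(np.searchsorted(2 * cum, total, side="left"))


def density_shift(
    gene_id: str, center_control: int, center_stress: int, cds_length: int
) -> ShiftResult:
    """3'-ward (positive) or 5'-ward (negative) displacement of the density
    centre, divided by CDS length so long ORFs do not dominate."""
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    return ShiftResult(
        gene_id=gene_id,
        center_control=center_control,
        center_stress=center_stress,
        cds_length=cds_length,
        shift=(center_stress - center_control) / cds_length,
    )


@dataclass
class ContextTable:
    window: tuple[int, int]  # inclusive positions relative to the A of the start
    table: pd.DataFrame  # columns: sequence, count, percent
    n_sites_used: int
    n_skipped: int


def relative_frequency(count: int, total: int) -> float:
    """Relative frequency in percent: count / total * 100."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total * 100.0


def context_frequencies(
    transcripts: Mapping[str, TranscriptRecord],
    sites: Iterable[tuple[str, int]],
    window: tuple[int, int] = (-4, 4),
) -> ContextTable:
    """Tabulate initiation-context sequences around start-codon sites.

    ``sites`` are (tx_id, position-of-the-A) pairs; the window is inclusive
    on both ends relative to that A (the default -4..+4 spans the start
    codon itself).  Sites whose window does not fit inside the transcript
    are skipped and counted.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must be (low, high) with low <= high")
    counter: Counter[str] = Counter()
    skipped = 0
    for tx_id, pos in sites:
        seq = transcripts[tx_id].sequence
        a, b = pos + lo, pos + hi + 1
        if a < 0 or b > len(seq):
            skipped += 1
            continue
        counter[seq[a:b]] += 1
    total = sum(counter.values())
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["sequence", "count"])
    table["percent"] = [relative_frequency(c, total) for c in table["count"]] if total else []
    return ContextTable(window=window, table=table, n_sites_used=total, n_skipped=skipped)


def position_frequency_matrix(ctx: ContextTable) -> pd.DataFrame:
    """Per-position nucleotide frequencies (for logo rendering)."""
    lo, hi = ctx.window
    positions = list(range(lo, hi + 1))
    mat = pd.DataFrame(0.0, index=positions, columns=list("ACGT"))
    for row in ctx.table.itertuples(index=False):
        for p, nt in zip(positions, row.sequence):
            if nt in "ACGT":
                mat.loc[p, nt] += row.count
    total = ctx.table["count"].sum()
    return mat / total if total else mat


def leader_stats(
    transcripts: Mapping[str, TranscriptRecord],
    chosen: Mapping[str, str],
    class_labels: pd.Series,
    uorfs_by_gene: Mapping[str, list[UorfRecord]],
) -> pd.DataFrame:
    """Per-class leader length and uORF prevalence summary."""
    rows = []
    for gene_id, label in class_labels.items():
        rec = transcripts[chosen[gene_id]]
        uorfs = uorfs_by_gene.get(gene_id, [])
        rows.append(
            {
                "gene_id": gene_id,
                "class_label": label,
                "leader_length": rec.leader_length,
                "has_uorf": len(uorfs) > 0,
                "has_translated_uorf": any(u.translated_flag for u in uorfs),
            }
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby("class_label").agg(
        n_genes=("gene_id", "size"),
        leader_mean=("leader_length", "mean"),
        leader_median=("leader_length", "median"),
        uorf_prevalence=("has_uorf", "mean"),
        translated_uorf_prevalence=("has_translated_uorf", "mean"),
    )
    return grouped


@dataclass(frozen=True)
class FoldResult:
    energy: float | None
    status: str  # computed | not_computed | leader_too_short


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def structure_energy_hook(
    leader_sequence: str,
    window_nt: int = 240,
    folder: str | Callable[[str], float] | None = None,
) -> FoldResult:
    """Optional leader folding-energy hook.

    Only the first ``window_nt`` nucleotides are folded (free energy scales
    with length); shorter leaders are excluded.  No folding algorithm is
    implemented here: ``folder`` may be a callable or the name of an
    external RNAfold-style executable whose last output line ends in
    ``(<energy>)``.  Without a folder the pipeline records 'not_computed'
    and proceeds.
    """
    if len(leader_sequence) < window_nt:
        return FoldResult(None, "leader_too_short")
    sub = leader_sequence[:window_nt].upper().replace("T", "U")
    if folder is None:
        return FoldResult(None, "not_computed")
    if callable(folder):
        return FoldResult(float(folder(sub)), "computed")
    proc = subprocess.run(
        [folder, "--noPS"], input=sub + "\n", capture_output=True, text=True, check=True
    )
    for line in reversed(proc.stdout.strip().splitlines()):
        m = _ENERGY_RE.search(line)
        if m:
            return FoldResult(float(m.group(1)), "computed")
    raise ValueError(f"could not parse energy from {folder!r} output")


def uorf_table(records: Iterable[UorfRecord], gene_of_tx: Mapping[str, str]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": gene_of_tx.get(u.tx_id, ""),
            "tx_id": u.tx_id,
            "start": u.start,
            "end": u.end,
            "start_codon": u.start_codon,
            "length_codons": u.length_codons,
            "truncated": u.truncated_flag,
            "ribo_reads": u.ribo_reads,
            "te": u.te,
            "translated": u.translated_flag,
        }
        for u in records
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tx_id", "start", "end", "start_codon", "length_codons",
                 "truncated", "ribo_reads", "te", "translated"],
    )
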
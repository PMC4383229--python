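"""From alignments to A-site-resolved count vectors.

The input is a table of positive-strand transcript alignments with mapping
multiplicity metadata (no re-alignment happens here).  Ribosome footprints
are restricted to monosome lengths 29-35 nt, ambiguous mappers are discarded,
and each footprint contributes one count at its inferred A-site codon.
mRNA-seq reads contribute one count at their 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .transcripts import TranscriptRecord

READ_COLUMNS = ["tx_id", "pos5", "length", "n_gene_hits", "n_tx_hits"]

#: id under which spike-in oligo alignments travel in read tables
SPIKE_ID = "spikein"
SPIKE_SEQUENCE = "ATGTACACGGAGTCGACCCGCAACGCGA"

RIBO_LENGTH_MIN = 29
RIBO_LENGTH_MAX = 35

# A-site offset from the read 5' end, zero-based: the A-site first nt is the
# 17th nt for the shorter footprints and the 18th for the longer ones.
DEFAULT_OFFSETS: dict[int, int] = {29: 16, 30: 16, 31: 16, 32: 16, 33: 17, 34: 17, 35: 17}

ASSAYS = ("ribo", "rna")


@dataclass
class SampleProfile:
    """Per-transcript count vectors for one library.

    ``counts[tx_id][i]`` is the number of ribo-seq A-sites (ribo assay) or
    mRNA-seq read 5' ends (rna assay) at transcript position ``i``.
    """

    sample_id: str
    assay: str
    condition: str
    replicate: int
    counts: dict[str, np.ndarray]
    total_mapped: int = 0
    spike_count: int = 0
    discard_ledger: dict[str, int] = field(default_factory=dict)

    def transcript_total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))


def _validate_reads(reads: pd.DataFrame, transcripts: Mapping[str, TranscriptRecord]) -> None:
    non_spike = reads[reads["tx_id"] != SPIKE_ID]
    ids = pd.unique(non_spike["tx_id"])
    unknown = [t for t in ids if t not in transcripts]
    if unknown:
        raise KeyError(f"reads reference unknown transcript id {unknown[0]!r}")
    tx_len = non_spike["tx_id"].map({t: transcripts[t].length for t in ids})
    bad = (non_spike["pos5"] < 0) | (non_spike["pos5"] + non_spike["length"] > tx_len)
    if bad.any():
        row = non_spike[bad].iloc[0]
        raise ValueError(
            f"read outside transcript bounds: {row.tx_id} pos5={row.pos5} "
            f"length={row.length}"
        )


def filter_reads(
    reads: pd.DataFrame,
    assay: str,
    transcripts: Mapping[str, TranscriptRecord] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the footprint-length and unique-mapping filters.

    Spike-in rows are exempt from the length rule (the oligo is 28 nt) and
    are passed through so that downstream counting can record them.  The
    ledger accounts for every input read: ``kept + spike + discarded = input``.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    if transcripts is not None:
        _validate_reads(reads, transcripts)
    ledger = {"input": len(reads), "discard_length": 0, "discard_multimap_gene": 0,
              "discard_multimap_tx": 0}
    spike_mask = (reads["tx_id"] == SPIKE_ID).to_numpy()
    spike = reads[spike_mask]
    rest = reads[~spike_mask]

    if assay == "ribo":
        ok_len = (rest["length"] >= RIBO_LENGTH_MIN) & (rest["length"] <= RIBO_LENGTH_MAX)
        ledger["discard_length"] = int((~ok_len).sum())
        rest = rest[ok_len]
    ok_gene = rest["n_gene_hits"] == 1
    ledger["discard_multimap_gene"] = int((~ok_gene).sum())
    rest = rest[ok_gene]
    ok_tx = rest["n_tx_hits"] == 1
    ledger["discard_multimap_tx"] = int((~ok_tx).sum())
    rest = rest[ok_tx]

    ledger["spike"] = len(spike)
    ledger["kept"] = len(rest)
    kept = pd.concat([rest, spike], ignore_index=True) if len(spike) else rest.reset_index(drop=True)
    return kept, ledger


def infer_asite(pos5, length, offsets: Mapping[int, int] | None = None):
    """Transcript coordinate of the first nt of the A-site codon.

    Accepts scalars or arrays.  Lengths outside the footprint range raise.
    """
    offsets = DEFAULT_OFFSETS if offsets is None else dict(offsets)
    if np.isscalar(length):
        if int(length) not in offsets:
            raise ValueError(f"no A-site offset for read length {length}")
        return int(pos5) + offsets[int(length)]
    length = np.asarray(length)
    pos5 = np.asarray(pos5)
    known = np.array(sorted(offsets))
    if not np.isin(length, known).all():
        bad = length[~np.isin(length, known)][0]
        raise ValueError(f"no A-site offset for read length {bad}")
    lut = np.full(int(known.max()) + 1, -1, dtype=np.int64)
    for k, v in offsets.items():
        lut[k] = v
    return pos5 + lut[length]


def build_profile(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptRecord],
    assay: str,
    sample_id: str = "sample",
    condition: str = "na",
    replicate: int = 1,
    offsets: Mapping[int, int] | None = None,
) -> SampleProfile:
    """Filter reads and accumulate per-transcript count vectors.

    Ribo-seq reads are counted at the inferred A-site; reads whose A-site
    would fall beyond the transcript end are discarded and ledgered.
    mRNA-seq reads are counted at their 5' end.  Spike-in reads are excluded
    from transcript vectors and tallied in ``spike_count``.
    """
    kept, ledger = filter_reads(reads, assay, transcripts)
    spike_count = ledger["spike"]
    body = kept[kept["tx_id"] != SPIKE_ID]

    tx_ids = sorted(transcripts)
    lengths = np.array([transcripts[t].length for t in tx_ids], dtype=np.int64)
    offsets_arr = np.concatenate([[0], np.cumsum(lengths)])
    index_of = {t: i for i, t in enumerate(tx_ids)}

    tx_idx = body["tx_id"].map(index_of).to_numpy(dtype=np.int64) if len(body) else np.empty(0, np.int64)
    pos5 = body["pos5"].to_numpy(dtype=np.int64) if len(body) else np.empty(0, np.int64)
    if assay == "ribo" and len(body):
        coord = np.asarray(infer_asite(pos5, body["length"].to_numpy(), offsets))
        overrun = coord >= lengths[tx_idx]
        ledger["discard_asite_overrun"] = int(overrun.sum())
        ledger["kept"] -= int(overrun.sum())
        coord = coord[~overrun]
        tx_idx = tx_idx[~overrun]
    else:
        ledger["discard_asite_overrun"] = 0
        coord = pos5

    flat = np.bincount(offsets_arr[tx_idx] + coord, minlength=int(offsets_arr[-1]))
    counts = {
        t: flat[offsets_arr[i] : offsets_arr[i + 1]].astype(np.int64)
        for i, t in enumerate(tx_ids)
    }
    return SampleProfile(
        sample_id=sample_id,
        assay=assay,
        condition=condition,
        replicate=replicate,
        counts=counts,
        total_mapped=ledger["kept"] + spike_count,
        spike_count=spike_count,
        discard_ledger=ledger,
    )


def select_variant(
    transcripts: Mapping[str, TranscriptRecord],
    control_ribo_profiles: Iterable[SampleProfile],
) -> dict[str, str]:
    """Pick one transcript per gene: the coding variant with the highest
    control ribo-seq read density (reads per nt), ties broken by tx_id.

    Genes without any coding transcript are omitted (with a warning).
    """
    profiles = list(control_ribo_profiles)
    density: dict[str, float] = {}
    for tx_id, rec in transcripts.items():
        if not rec.coding_flag:
            continue
        n = sum(int(p.counts[tx_id].sum()) for p in profiles if tx_id in p.counts)
        density[tx_id] = n / rec.length
    chosen: dict[str, str] = {}
    skipped = []
    genes: dict[str, list[str]] = {}
    for tx_id, rec in transcripts.items():
        genes.setdefault(rec.gene_id, []).append(tx_id)
    for gene_id, txs in genes.items():
        coding = [t for t in txs if transcripts[t].coding_flag]
        if not coding:
            skipped.append(gene_id)
            continue
        chosen[gene_id] = min(coding, key=lambda t: (-density[t], t))
    if skipped:
        warnings.warn(f"{len(skipped)} gene(s) without coding transcript excluded")
    return chosen


def region_counts(
    profile: SampleProfile, transcripts: Mapping[str, TranscriptRecord]
) -> pd.DataFrame:
    """Per-transcript read totals over leader / CDS / trailer."""
    rows = []
    for tx_id, vec in profile.counts.items():
        rec = transcripts[tx_id]
        rows.append(
            {
                "tx_id": tx_id,
                "leader": int(vec[: rec.cds_start].sum()),
                "cds": int(vec[rec.cds_start : rec.cds_end].sum()),
                "trailer": int(vec[rec.cds_end :].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["tx_id", "leader", "cds", "trailer"]).set_index("tx_id")


# ---------------------------------------------------------------------------
# I/O


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table {path} missing columns {missing}")
    return df[READ_COLUMNS]


def write_alignment_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: SampleProfile, path: str | Path) -> None:
    """Sparse per-position dump of a profile (tx_id, position, count),
    non-zero positions only."""
    rows = []
    for tx_id in sorted(profile.counts):
        vec = profile.counts[tx_id]
        (pos,) = np.nonzero(vec)
        rows.append(
            pd.DataFrame({"tx_id": tx_id, "position": pos, "count": vec[pos]})
        )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["tx_id", "position", "count"])
    )
    out.to_csv(path, sep="\t", index=False)


def read_profile_tsv(
    path: str | Path, transcripts: Mapping[str, TranscriptRecord]
) -> dict[str, np.ndarray]:
    """Load a sparse profile dump back into dense per-transcript vectors."""
    df = pd.read_csv(path, sep="\t")
    out = {t: np.zeros(rec.length, dtype=np.int64) for t, rec in transcripts.items()}
    for tx_id, grp in df.groupby("tx_id"):
        out[tx_id][grp["position"].to_numpy()] = grp["count"].to_numpy()
    return out


def read_alignment_sam(path: str | Path) -> pd.DataFrame:
    """Read transcriptome-space alignments from SAM.

    Mapping multiplicities travel in the ``XG`` (genes hit) and ``XT``
    (positions within the transcript) integer tags; absent tags mean unique.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append(
                {
                    "tx_id": aln.reference_name,
                    "pos5": aln.reference_start,
                    "length": aln.query_length or aln.infer_read_length(),
                    "n_gene_hits": aln.get_tag("XG") if aln.has_tag("XG") else 1,
                    "n_tx_hits": aln.get_tag("XT") if aln.has_tag("XT") else 1,
                }
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_alignment_sam(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptRecord],
    path: str | Path,
) -> None:
    import pysam

    names = sorted(transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": transcripts[t].length} for t in names]
        + [{"SN": SPIKE_ID, "LN": len(SPIKE_SEQUENCE)}],
    }
    tid = {t: i for i, t in enumerate(names)}
    tid[SPIKE_ID] = len(names)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = tid[row.tx_id]
            a.reference_start = int(row.pos5)
            a.cigarstring = f"{int(row.length)}M"
            a.mapping_quality = 255
            a.flag = 0
            a.set_tag("XG", int(row.n_gene_hits))
            a.set_tag("XT", int(row.n_tx_hits))
            out.write(a)
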
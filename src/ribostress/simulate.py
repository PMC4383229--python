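"""Synthetic transcriptomes and ribo-seq / mRNA-seq libraries.

The generator emulates the count structure the analysis assumes: two assays
(ribosome footprints, fragmented mRNA) in two conditions (control, arsenite
stress) with replicates; footprints of 29-35 nt with triplet periodicity;
AUG uORFs planted in 5' leaders; a global ~5.4-fold repression of CDS
ribosome occupancy under stress with a small resistant subset whose uORF
density partially redistributes onto the CDS; gamma-Poisson (negative
binomial) count noise; and a spike-in oligo whose absolute amount is
constant across libraries, so spike-relative rescaling can recover the
absolute occupancy changes that fixed sequencing depth otherwise hides.

Leaders are built AUG-free except for the planted uORF, so the ground truth
about uORF content is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import profiles as prof
from .profiles import DEFAULT_OFFSETS, READ_COLUMNS, SPIKE_ID, SPIKE_SEQUENCE, SampleProfile
from .transcripts import (
    STOP_CODONS,
    TranscriptRecord,
    write_annotation,
    write_fasta,
)

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

DEFAULT_LENGTH_PROBS = {29: 0.08, 30: 0.15, 31: 0.30, 32: 0.20, 33: 0.14, 34: 0.08, 35: 0.05}

CONDITIONS = ("control", "stress")
ASSAYS = ("ribo", "rna")


@dataclass
class SyntheticConfig:
    """Free parameters of the simulation.

    Lengths are nt unless stated; the CDS and uORF length units are sense
    codons.  ``repression_factor`` divides the stress-condition CDS TE of
    every non-resistant gene; ``spike_fraction`` sets the expected share of
    spike-in reads in a control library (the spike's absolute amount is then
    held constant across conditions).
    """

    n_genes: int = 2000
    seed: int = 0
    leader_length_dist: tuple[float, float] = (170.0, 80.0)
    cds_length_dist: tuple[float, float] = (400.0, 120.0)
    trailer_length_dist: tuple[float, float] = (120.0, 60.0)
    uorf_prob: float = 0.3
    uorf_length_dist: tuple[int, int] = (3, 60)
    resistant_fraction: float = 0.02
    repression_factor: float = 5.4
    dispersion: float = 0.05
    library_size: int = 6_000_000
    spike_fraction: float = 1e-4
    n_replicates: int = 2
    # secondary knobs
    min_leader: int = 30
    min_trailer: int = 30
    min_cds_codons: int = 60
    uorf_density_ratio: float = 3.0  # uORF / CDS footprint density in control
    uorf_shift_fraction: float = 0.6  # uORF occupancy moved to CDS in resistant genes
    periodicity: float = 0.9  # probability a footprint 5' end sits in the preferred frame
    length_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_PROBS))
    rna_log2_sd: float = 2.0
    te_log2_sd: float = 0.7
    rna_effects: dict[str, float] = field(default_factory=dict)  # gene_id -> stress RNA fold
    multimap_fraction: float = 0.0  # fraction of emitted reads flagged multi-gene
    offtarget_length_fraction: float = 0.0  # fraction of ribo reads given length 26
    max_uorf_redraws: int = 50

    def __post_init__(self) -> None:
        for name in ("uorf_prob", "resistant_fraction", "spike_fraction", "periodicity",
                     "multimap_fraction", "offtarget_length_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.repression_factor < 1.0:
            raise ValueError("repression_factor must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for name in ("leader_length_dist", "cds_length_dist", "trailer_length_dist"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} mean must be positive")
        lo, hi = self.uorf_length_dist
        if not (1 <= lo <= hi):
            raise ValueError("uorf_length_dist must satisfy 1 <= min <= max")
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


TRUTH_COLUMNS = [
    "gene_id", "tx_id", "resistant", "has_uorf", "uorf_start", "uorf_end",
    "uorf_codons", "rna_control", "rna_stress", "te_control", "te_stress",
    "te_uorf_control", "te_uorf_stress", "leader_length", "cds_start", "cds_end",
]


def _random_nt(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=n)


def _scrub_leader_augs(leader: np.ndarray, uorf_start: int | None, protect: set[int]) -> None:
    """Remove every ATG in the leader except the planted start, in place.

    The offending window's G is mutated to C (or its A, when the G sits in a
    protected planted codon).  A C can participate in neither ATG nor a stop
    codon, so the edit never creates new start codons, never destroys the
    planted stop, and leaves uORF body codons sense codons.
    """
    s = "".join(leader)
    i = s.find("ATG")
    while i != -1:
        if i + 3 <= len(leader) and i != uorf_start:
            if i + 2 not in protect:
                leader[i + 2] = "C"
            else:
                leader[i] = "C"
            s = "".join(leader)
            i = s.find("ATG", i)
        else:
            i = s.find("ATG", i + 1)


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Draw transcripts and the ground truth used as recovery oracle.

    Every transcript has a leader, an AUG...stop CDS and a trailer; a
    fraction ``uorf_prob`` of leaders carries exactly one AUG uORF of the
    drawn length (sense codons, stop included downstream in the leader), and
    the leader carries no other AUG.  Resistant flags are drawn only among
    uORF-bearing genes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(2)[0]))
    records: list[TranscriptRecord] = []
    truth_rows = []
    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)

    for g in range(config.n_genes):
        gene_id = f"G{g:05d}"
        tx_id = f"T{g:05d}"
        cds_codons = max(
            config.min_cds_codons,
            int(round(rng.normal(*config.cds_length_dist))),
        )
        trailer_len = max(
            config.min_trailer, int(round(rng.normal(*config.trailer_length_dist)))
        )
        has_uorf = rng.random() < config.uorf_prob
        uorf_codons = 0
        if has_uorf:
            uorf_codons = int(rng.integers(config.uorf_length_dist[0],
                                           config.uorf_length_dist[1] + 1))
        needed = 3 * uorf_codons + 3 if has_uorf else 0
        leader_len = 0
        for _ in range(config.max_uorf_redraws + 1):
            leader_len = max(config.min_leader, int(round(rng.normal(*config.leader_length_dist))))
            if leader_len >= needed:
                break
        if has_uorf and leader_len < needed:
            raise ValueError(
                f"{gene_id}: drawn leader ({leader_len} nt) cannot host a "
                f"{uorf_codons}-codon uORF after {config.max_uorf_redraws} redraws; "
                "increase leader_length_dist or shorten uorf_length_dist"
            )

        leader = _random_nt(rng, leader_len)
        u0 = -1
        uend = -1
        protect: set[int] = set()
        if has_uorf:
            u0 = int(rng.integers(0, leader_len - needed + 1))
            uend = u0 + 3 * uorf_codons
            body = rng.choice(sense, size=uorf_codons - 1)
            uorf_seq = "ATG" + "".join(body) + str(rng.choice(stops))
            leader[u0 : u0 + needed] = list(uorf_seq)
            protect = set(range(u0, u0 + 3)) | set(range(uend, uend + 3))
        _scrub_leader_augs(leader, u0 if has_uorf else None, protect)

        cds_body = "".join(rng.choice(sense, size=cds_codons - 1))
        cds_seq = "ATG" + cds_body + str(rng.choice(stops))
        trailer = "".join(_random_nt(rng, trailer_len))
        sequence = "".join(leader) + cds_seq + trailer
        cds_start = leader_len
        cds_end = cds_start + len(cds_seq)
        records.append(
            TranscriptRecord(
                tx_id=tx_id,
                gene_id=gene_id,
                sequence=sequence,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

        resistant = bool(has_uorf and rng.random() < config.resistant_fraction)
        rna = float(np.power(2.0, rng.normal(0.0, config.rna_log2_sd)))
        te_control = float(np.power(2.0, rng.normal(0.0, config.te_log2_sd)))
        te_uorf_control = config.uorf_density_ratio * te_control if has_uorf else 0.0
        uorf_nt = 3 * uorf_codons
        cds_nt = cds_end - cds_start
        if resistant:
            moved = config.uorf_shift_fraction * te_uorf_control * uorf_nt / cds_nt
            te_stress = te_control + moved
            te_uorf_stress = te_uorf_control * (1.0 - config.uorf_shift_fraction)
        else:
            te_stress = te_control / config.repression_factor
            te_uorf_stress = te_uorf_control
        rna_stress = rna * config.rna_effects.get(gene_id, 1.0)
        truth_rows.append(
            {
                "gene_id": gene_id, "tx_id": tx_id, "resistant": resistant,
                "has_uorf": has_uorf, "uorf_start": u0, "uorf_end": uend,
                "uorf_codons": uorf_codons, "rna_control": rna,
                "rna_stress": rna_stress, "te_control": te_control,
                "te_stress": te_stress, "te_uorf_control": te_uorf_control,
                "te_uorf_stress": te_uorf_stress, "leader_length": leader_len,
                "cds_start": cds_start, "cds_end": cds_end,
            }
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if len(truth):
        truth = truth.set_index("gene_id", drop=False)
        truth.index.name = None
    return records, truth


def design_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{assay}_{condition}_{rep}",
            "assay": assay,
            "condition": condition,
            "replicate": rep,
        }
        for assay in ASSAYS
        for condition in CONDITIONS
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


class _OccupancyModel:
    """Per-condition footprint placement weights, shared across replicates."""

    def __init__(self, transcriptome, truth, config: SyntheticConfig):
        self.config = config
        self.records = list(transcriptome)
        self.tx_ids = np.array([r.tx_id for r in self.records], dtype=object)
        self.tx_len = np.array([r.length for r in self.records], dtype=np.int64)
        t = truth
        self.rna = {
            "control": t["rna_control"].to_numpy(float),
            "stress": t["rna_stress"].to_numpy(float),
        }
        self.te_cds = {
            "control": t["te_control"].to_numpy(float),
            "stress": t["te_stress"].to_numpy(float),
        }
        self.te_uorf = {
            "control": t["te_uorf_control"].to_numpy(float),
            "stress": t["te_uorf_stress"].to_numpy(float),
        }
        self.truth = t

    def ribo_positions(self, condition: str):
        """Concatenated candidate A-site positions and weights per gene."""
        pos_blocks, w_blocks, block_gene = [], [], []
        t = self.truth
        for i, rec in enumerate(self.records):
            cds_pos = np.arange(rec.cds_start, rec.cds_end, 3)
            w = np.full(len(cds_pos), self.rna[condition][i] * self.te_cds[condition][i])
            if t["has_uorf"].iloc[i]:
                u0, uend = int(t["uorf_start"].iloc[i]), int(t["uorf_end"].iloc[i])
                upos = np.arange(u0, uend, 3)
                uw = np.full(len(upos), self.rna[condition][i] * self.te_uorf[condition][i])
                cds_pos = np.concatenate([upos, cds_pos])
                w = np.concatenate([uw, w])
            pos_blocks.append(cds_pos)
            w_blocks.append(w)
            block_gene.append(np.full(len(cds_pos), i, dtype=np.int64))
        return (
            np.concatenate(pos_blocks),
            np.concatenate(w_blocks),
            np.concatenate(block_gene),
        )

    def rna_weights(self, condition: str) -> np.ndarray:
        return self.rna[condition] * self.tx_len

    def gene_occupancy(self, assay: str, condition: str) -> np.ndarray:
        """Expected absolute occupancy per gene (arbitrary units)."""
        if assay == "rna":
            return self.rna_weights(condition)
        t = self.truth
        cds_nt = (t["cds_end"] - t["cds_start"]).to_numpy(float)
        uorf_nt = np.where(t["has_uorf"], 3.0 * t["uorf_codons"], 0.0)
        return self.rna[condition] * (
            self.te_cds[condition] * cds_nt + self.te_uorf[condition] * uorf_nt
        )


def _sample_block_positions(
    rng: np.random.Generator,
    gene_counts: np.ndarray,
    block_pos: np.ndarray,
    block_w: np.ndarray,
    block_gene: np.ndarray,
    n_genes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw, for each gene g, gene_counts[g] positions from its weight block.

    Works by inverse-CDF lookup on a single concatenated array: the within-
    gene CDF of gene g is mapped onto (g, g+1] so one global searchsorted
    resolves all genes at once.
    """
    # per-block cumulative weights normalized to (0, 1]
    order = np.argsort(block_gene, kind="stable")
    bg, bp, bw = block_gene[order], block_pos[order], block_w[order]
    cum = np.cumsum(bw)
    totals = np.zeros(n_genes)
    np.add.at(totals, bg, bw)
    block_starts = np.searchsorted(bg, np.arange(n_genes), side="left")
    offsets = np.concatenate([[0.0], cum])[block_starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = (cum - np.repeat(offsets, np.bincount(bg, minlength=n_genes))) / np.repeat(
            np.where(totals > 0, totals, 1.0), np.bincount(bg, minlength=n_genes)
        )
    # force exact block ends so no draw spills into the next gene
    block_ends = np.searchsorted(bg, np.arange(n_genes), side="right") - 1
    valid_ends = block_ends >= block_starts
    norm[block_ends[valid_ends]] = 1.0
    M = bg + norm

    gene_counts = gene_counts.copy()
    gene_counts[totals <= 0] = 0  # genes with no candidate positions
    read_gene = np.repeat(np.arange(n_genes), gene_counts)
    u = rng.random(len(read_gene))
    idx = np.searchsorted(M, read_gene + u, side="right")
    idx = np.clip(idx, 0, len(bp) - 1)
    return bp[idx], read_gene


def simulate_sample_reads(
    model: _OccupancyModel,
    assay: str,
    condition: str,
    rng: np.random.Generator,
    spike_amount: float,
) -> pd.DataFrame:
    """One library: a table of aligned reads including spike-in rows."""
    cfg = model.config
    occ = model.gene_occupancy(assay, condition)
    pool = occ.sum() + spike_amount
    p_gene = occ / pool
    # gamma-Poisson gene counts (negative binomial with dispersion alpha)
    if cfg.dispersion > 0:
        gamma = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion, size=len(occ))
    else:
        gamma = np.ones(len(occ))
    lam = cfg.library_size * p_gene * gamma
    counts = rng.poisson(lam)
    spike_count = int(rng.poisson(cfg.library_size * spike_amount / pool))

    lens = np.array(sorted(cfg.length_probs))
    lprobs = np.array([cfg.length_probs[k] for k in lens])

    if assay == "ribo":
        bp, bw, bg = model.ribo_positions(condition)
        asite, read_gene = _sample_block_positions(rng, counts, bp, bw, bg, len(occ))
        # frame jitter: deviate from the preferred frame with prob 1 - periodicity
        r = rng.random(len(asite))
        half = (1.0 - cfg.periodicity) / 2.0
        asite = asite + np.where(r < half, -1, np.where(r >= 1.0 - half, 1, 0))
        length = rng.choice(lens, p=lprobs, size=len(asite))
        offset_lut = np.zeros(int(lens.max()) + 1, dtype=np.int64)
        for k, v in DEFAULT_OFFSETS.items():
            offset_lut[k] = v
        pos5 = asite - offset_lut[length]
        txlen = model.tx_len[read_gene]
        ok = (pos5 >= 0) & (pos5 + length <= txlen)
        pos5, length, read_gene = pos5[ok], length[ok], read_gene[ok]
    else:
        read_gene = np.repeat(np.arange(len(occ)), counts)
        length = rng.choice(lens, p=lprobs, size=len(read_gene))
        txlen = model.tx_len[read_gene]
        span = np.maximum(txlen - length + 1, 1)
        pos5 = np.floor(rng.random(len(read_gene)) * span).astype(np.int64)
        length = np.minimum(length, txlen)

    n = len(read_gene)
    n_gene_hits = np.ones(n, dtype=np.int64)
    if cfg.multimap_fraction > 0:
        n_gene_hits[rng.random(n) < cfg.multimap_fraction] = 2
    if assay == "ribo" and cfg.offtarget_length_fraction > 0:
        short = rng.random(n) < cfg.offtarget_length_fraction
        length = np.where(short & (pos5 + 26 <= model.tx_len[read_gene]), 26, length)

    reads = pd.DataFrame(
        {
            "tx_id": model.tx_ids[read_gene],
            "pos5": pos5.astype(np.int64),
            "length": np.asarray(length, dtype=np.int64),
            "n_gene_hits": n_gene_hits,
            "n_tx_hits": np.ones(n, dtype=np.int64),
        }
    )
    if spike_count:
        spike = pd.DataFrame(
            {
                "tx_id": [SPIKE_ID] * spike_count,
                "pos5": np.zeros(spike_count, dtype=np.int64),
                "length": np.full(spike_count, len(SPIKE_SEQUENCE), dtype=np.int64),
                "n_gene_hits": np.ones(spike_count, dtype=np.int64),
                "n_tx_hits": np.ones(spike_count, dtype=np.int64),
            }
        )
        reads = pd.concat([reads, spike], ignore_index=True)
    return reads[READ_COLUMNS]


def simulate_reads(
    transcriptome: list[TranscriptRecord],
    truth: pd.DataFrame,
    config: SyntheticConfig,
) -> dict[str, pd.DataFrame]:
    """All libraries of the design, keyed by sample id.

    The spike-in absolute amount is calibrated per assay so that its
    expected read share in a control library equals ``spike_fraction``; the
    same amount is then used in the stress libraries, where the shrunken
    footprint pool inflates the spike share.
    """
    if config.library_size <= 0:
        raise ValueError("library_size must be positive")
    if len(transcriptome) == 0:
        empty = pd.DataFrame({c: [] for c in READ_COLUMNS})
        return {sid: empty.copy() for sid in design_table(config).index}
    model = _OccupancyModel(transcriptome, truth, config)
    ss = np.random.SeedSequence(config.seed)
    _, counts_seed = ss.spawn(2)
    design = design_table(config)
    children = counts_seed.spawn(len(design))
    spike_amount = {
        assay: config.spike_fraction
        / (1.0 - config.spike_fraction)
        * max(model.gene_occupancy(assay, "control").sum(), 1e-300)
        for assay in ASSAYS
    }
    out: dict[str, pd.DataFrame] = {}
    for child, (sample_id, row) in zip(children, design.iterrows()):
        rng = np.random.Generator(np.random.PCG64(child))
        out[sample_id] = simulate_sample_reads(
            model, row["assay"], row["condition"], rng, spike_amount[row["assay"]]
        )
    return out


def simulate_counts(
    transcriptome: list[TranscriptRecord],
    truth: pd.DataFrame,
    config: SyntheticConfig,
) -> list[SampleProfile]:
    """Reads pushed through the profile builder: one SampleProfile per
    library of the design."""
    reads = simulate_reads(transcriptome, truth, config)
    transcripts = {r.tx_id: r for r in transcriptome}
    design = design_table(config)
    out = []
    for sample_id, row in design.iterrows():
        out.append(
            prof.build_profile(
                reads[sample_id],
                transcripts,
                row["assay"],
                sample_id=sample_id,
                condition=row["condition"],
                replicate=int(row["replicate"]),
            )
        )
    return out


def write_fixture(
    out_dir: str | Path,
    config: SyntheticConfig,
    transcriptome: list[TranscriptRecord] | None = None,
    truth: pd.DataFrame | None = None,
    reads: Mapping[str, pd.DataFrame] | None = None,
    sam: bool = False,
) -> dict[str, Path]:
    """Write the dataset as plain-text files that round-trip losslessly.

    Emits transcripts.fasta (including the spike-in oligo), annotation.tsv,
    truth.tsv, design.tsv and per-sample alignment TSVs (optionally SAM).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if transcriptome is None or truth is None:
        transcriptome, truth = generate_transcriptome(config)
    if reads is None:
        reads = simulate_reads(transcriptome, truth, config)

    paths = {"fasta": out_dir / "transcripts.fasta",
             "annotation": out_dir / "annotation.tsv",
             "truth": out_dir / "truth.tsv",
             "design": out_dir / "design.tsv"}
    spike_rec = TranscriptRecord(
        tx_id=SPIKE_ID, gene_id=SPIKE_ID, sequence=SPIKE_SEQUENCE,
        cds_start=0, cds_end=27, coding_flag=False,
    )
    write_fasta(list(transcriptome) + [spike_rec], paths["fasta"])
    write_annotation(transcriptome, paths["annotation"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    design = design_table(config)
    design.to_csv(paths["design"], sep="\t")
    align_dir = out_dir / "alignments"
    align_dir.mkdir(exist_ok=True)
    transcripts = {r.tx_id: r for r in transcriptome}
    for sample_id, table in reads.items():
        p = align_dir / f"{sample_id}.tsv"
        prof.write_alignment_tsv(table, p)
        paths[f"reads:{sample_id}"] = p
        if sam:
            sp = align_dir / f"{sample_id}.sam"
            prof.write_alignment_sam(table, transcripts, sp)
            paths[f"sam:{sample_id}"] = sp
    return paths


def read_fixture(in_dir: str | Path):
    """Load a fixture directory back into in-memory objects."""
    from .transcripts import load_transcripts

    in_dir = Path(in_dir)
    transcripts = load_transcripts(in_dir / "transcripts.fasta", in_dir / "annotation.tsv")
    truth = pd.read_csv(in_dir / "truth.tsv", sep="\t")
    if len(truth):
        truth = truth.set_index("gene_id", drop=False)
        truth.index.name = None
    design = pd.read_csv(in_dir / "design.tsv", sep="\t").set_index("sample_id")
    reads = {
        p.stem: prof.read_alignment_tsv(p)
        for p in sorted((in_dir / "alignments").glob("*.tsv"))
    }
    return transcripts, truth, design, reads
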
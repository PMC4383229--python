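"""End-to-end orchestration: alignments -> profiles -> normalized counts ->
differential translation -> uORF and density-shift analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import diffexpr, normalization, profiles, uorf
from .normalization import CountTable
from .profiles import SampleProfile
from .simulate import SyntheticConfig, generate_transcriptome, simulate_reads, design_table
from .transcripts import TranscriptRecord


@dataclass
class PipelineResult:
    transcripts: dict[str, TranscriptRecord]
    design: pd.DataFrame
    profiles: dict[str, SampleProfile]
    chosen: dict[str, str]
    count_table: CountTable
    diff: pd.DataFrame
    uorfs: pd.DataFrame = field(default_factory=pd.DataFrame)
    shifts: pd.DataFrame = field(default_factory=pd.DataFrame)
    concordance: diffexpr.ConcordanceResult | None = None


def _pooled_vectors(
    result_profiles: Mapping[str, SampleProfile],
    design: pd.DataFrame,
    assay: str,
    condition: str,
    tx_id: str,
) -> np.ndarray:
    """Sum a transcript's count vector over the replicates of one assay and
    condition."""
    sel = design[(design["assay"] == assay) & (design["condition"] == condition)]
    vecs = [result_profiles[s].counts[tx_id] for s in sel.index]
    return np.sum(vecs, axis=0)


def uorf_analysis(
    transcripts: Mapping[str, TranscriptRecord],
    chosen: Mapping[str, str],
    sample_profiles: Mapping[str, SampleProfile],
    design: pd.DataFrame,
    min_reads: int = uorf.TRANSLATED_MIN_READS,
    start_codons=uorf.DEFAULT_START_CODONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect uORFs on the chosen variants, call translation from pooled
    control footprints, compute uORF TE, and the control->stress density
    shift per gene.

    Returns (uorf table, shift table).  The uORF table has one row per
    detected uORF with a ``best`` flag marking, per transcript, the
    translated uORF with the most footprints.
    """
    uorf_rows = []
    shift_rows = []
    for gene_id in sorted(chosen):
        tx = transcripts[chosen[gene_id]]
        ribo_c = _pooled_vectors(sample_profiles, design, "ribo", "control", tx.tx_id)
        ribo_s = _pooled_vectors(sample_profiles, design, "ribo", "stress", tx.tx_id)
        rna_c = _pooled_vectors(sample_profiles, design, "rna", "control", tx.tx_id)

        found = uorf.find_uorfs(tx, start_codons)
        annotated = []
        for u in found:
            u = uorf.call_translated(u, ribo_c, min_reads)
            te = uorf.uorf_te(u, ribo_c, rna_c)
            annotated.append(uorf.UorfRecord(
                tx_id=u.tx_id, start=u.start, end=u.end, start_codon=u.start_codon,
                length_codons=u.length_codons, truncated_flag=u.truncated_flag,
                ribo_reads=u.ribo_reads, te=te, translated_flag=u.translated_flag,
            ))
        best = None
        if any(u.translated_flag for u in annotated):
            best = uorf.best_uorf(annotated)
        for u in annotated:
            uorf_rows.append({
                "gene_id": gene_id, "tx_id": u.tx_id, "start": u.start, "end": u.end,
                "start_codon": u.start_codon, "length_codons": u.length_codons,
                "truncated": u.truncated_flag, "ribo_reads": u.ribo_reads,
                "te": u.te, "translated": u.translated_flag,
                "best": best is not None and u.start == best.start,
            })

        cc = uorf.density_center(ribo_c)
        cs = uorf.density_center(ribo_s)
        if cc is not None and cs is not None:
            res = uorf.density_shift(gene_id, cc, cs, tx.cds_length)
            shift_rows.append({
                "gene_id": gene_id, "center_control": res.center_control,
                "center_stress": res.center_stress, "cds_length": res.cds_length,
                "shift": res.shift,
            })
    uorf_cols = ["gene_id", "tx_id", "start", "end", "start_codon", "length_codons",
                 "truncated", "ribo_reads", "te", "translated", "best"]
    shift_cols = ["gene_id", "center_control", "center_stress", "cds_length", "shift"]
    return (
        pd.DataFrame(uorf_rows, columns=uorf_cols),
        pd.DataFrame(shift_rows, columns=shift_cols),
    )


def run_from_reads(
    transcripts: Mapping[str, TranscriptRecord],
    reads_by_sample: Mapping[str, pd.DataFrame],
    design: pd.DataFrame,
    normalization_method: str | Mapping[int, str] = "spike",
    bin_size: int = diffexpr.DEFAULT_BIN_SIZE,
    min_expr_threshold: float = diffexpr.DEFAULT_MIN_EXPR,
    z_threshold: float = diffexpr.DEFAULT_Z_THRESHOLD,
    compute_uorfs: bool = True,
) -> PipelineResult:
    """The full analysis from alignment tables.

    Builds per-sample profiles, selects one transcript variant per gene by
    control ribo-seq density, aggregates and rescales counts, computes the
    binned TE Z-scores and class labels, and (optionally) runs the uORF and
    density-shift analysis.
    """
    sample_profiles: dict[str, SampleProfile] = {}
    for sample_id, row in design.iterrows():
        sample_profiles[sample_id] = profiles.build_profile(
            reads_by_sample[sample_id],
            transcripts,
            row["assay"],
            sample_id=sample_id,
            condition=row["condition"],
            replicate=int(row["replicate"]),
        )
    control_ribo = [
        sample_profiles[s]
        for s in design[(design["assay"] == "ribo") & (design["condition"] == "control")].index
    ]
    chosen = profiles.select_variant(transcripts, control_ribo)
    table = normalization.aggregate_counts(sample_profiles.values(), transcripts, chosen)
    factors = normalization.compute_factors(table.samples, normalization_method)
    table = normalization.apply_rescale(table, factors)
    diff = diffexpr.differential_translation(
        table, mode="te", bin_size=bin_size,
        min_expr_threshold=min_expr_threshold, z_threshold=z_threshold,
    )
    concordance = None
    rep_cols = [c for c in diff.columns if c.startswith("zscore_rep")]
    if len(rep_cols) >= 2:
        concordance = diffexpr.replicate_concordance(diff[rep_cols[0]], diff[rep_cols[1]])
    result = PipelineResult(
        transcripts=dict(transcripts),
        design=design,
        profiles=sample_profiles,
        chosen=chosen,
        count_table=table,
        diff=diff,
        concordance=concordance,
    )
    if compute_uorfs:
        result.uorfs, result.shifts = uorf_analysis(
            transcripts, chosen, sample_profiles, design
        )
    return result


def run_synthetic(
    config: SyntheticConfig,
    normalization_method: str | Mapping[int, str] = "spike",
    compute_uorfs: bool = True,
    **kwargs,
) -> tuple[PipelineResult, pd.DataFrame]:
    """Simulate a dataset and push it through the full pipeline.

    Returns the pipeline result and the generator's ground truth.
    """
    transcriptome, truth = generate_transcriptome(config)
    reads = simulate_reads(transcriptome, truth, config)
    transcripts = {r.tx_id: r for r in transcriptome}
    design = design_table(config)
    result = run_from_reads(
        transcripts, reads, design,
        normalization_method=normalization_method,
        compute_uorfs=compute_uorfs,
        **kwargs,
    )
    return result, truth


def recovered_median_fold_reduction(diff: pd.DataFrame) -> float:
    """Median TE fold *reduction* (control/stress) over eligible genes."""
    fc = diff.loc[diff["eligible"], "fold_change"]
    return float(1.0 / fc.median())
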
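"""Metagene aggregation, triplet-periodicity diagnostics and reporting."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .profiles import RIBO_LENGTH_MAX, RIBO_LENGTH_MIN, SPIKE_ID, SampleProfile
from .transcripts import TranscriptRecord

DEFAULT_START_WINDOW = (-50, 100)
DEFAULT_STOP_WINDOW = (-100, 50)


@dataclass
class MetageneMatrix:
    """Read 5'-end (or A-site) counts aggregated across transcripts after
    re-indexing relative to the CDS start and stop."""

    start: pd.Series  # index: offset relative to cds_start
    stop: pd.Series  # index: offset relative to cds_end
    n_transcripts: int


def metagene(
    profile: SampleProfile,
    transcripts: Mapping[str, TranscriptRecord],
    start_window: tuple[int, int] = DEFAULT_START_WINDOW,
    stop_window: tuple[int, int] = DEFAULT_STOP_WINDOW,
) -> MetageneMatrix:
    """Aggregate counts around CDS boundaries.

    Offsets a transcript cannot cover (short leader/trailer) simply receive
    no contribution from it, so totals equal the in-window count sum.
    """
    s_lo, s_hi = start_window
    e_lo, e_hi = stop_window
    start_acc = np.zeros(s_hi - s_lo + 1, dtype=np.int64)
    stop_acc = np.zeros(e_hi - e_lo + 1, dtype=np.int64)
    n = 0
    for tx_id, vec in profile.counts.items():
        rec = transcripts[tx_id]
        n += 1
        for acc, anchor, lo, hi in (
            (start_acc, rec.cds_start, s_lo, s_hi),
            (stop_acc, rec.cds_end, e_lo, e_hi),
        ):
            a = max(anchor + lo, 0)
            b = min(anchor + hi + 1, rec.length)
            if a < b:
                acc[a - anchor - lo : b - anchor - lo] += vec[a:b]
    return MetageneMatrix(
        start=pd.Series(start_acc, index=np.arange(s_lo, s_hi + 1), name="count"),
        stop=pd.Series(stop_acc, index=np.arange(e_lo, e_hi + 1), name="count"),
        n_transcripts=n,
    )


def periodicity(
    reads: pd.DataFrame, transcripts: Mapping[str, TranscriptRecord]
) -> pd.DataFrame:
    """Per-length frame distribution of footprint 5' ends.

    Frame is (pos5 - cds_start) mod 3 for the read's transcript.  Rows cover
    lengths 29-35; columns frame_0..frame_2 plus total and modal fraction.
    """
    body = reads[reads["tx_id"] != SPIKE_ID]
    cds_start = body["tx_id"].map({t: r.cds_start for t, r in transcripts.items()})
    frame = ((body["pos5"] - cds_start) % 3).astype(int)
    tab = (
        pd.crosstab(body["length"], frame)
        .reindex(index=range(RIBO_LENGTH_MIN, RIBO_LENGTH_MAX + 1), columns=[0, 1, 2])
        .fillna(0)
        .astype(int)
    )
    tab.columns = [f"frame_{c}" for c in tab.columns]
    tab.index.name = "length"
    tab["total"] = tab.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tab["modal_fraction"] = np.where(
            tab["total"] > 0,
            tab[["frame_0", "frame_1", "frame_2"]].max(axis=1) / tab["total"].replace(0, 1),
            np.nan,
        )
    return tab


def transcript_plot(
    gene_id: str,
    tx: TranscriptRecord,
    control: dict[str, np.ndarray],
    stress: dict[str, np.ndarray],
    out_path: str | Path,
    uorfs=(),
    factors: Mapping[str, float] | None = None,
) -> Path:
    """Mirrored per-position profile figure: control up, stress down.

    ``control``/``stress`` map assay name ('ribo', 'rna') to a per-position
    vector; vectors are divided by the matching rescale factor if given.
    CDS is shaded grey, uORF intervals orange.
    """

    def scaled(vecs: dict[str, np.ndarray], key: str) -> np.ndarray:
        v = np.asarray(vecs.get("ribo" if key.startswith("ribo") else "rna",
                                np.zeros(tx.length)), dtype=float)
        if factors and key in factors:
            v = v / factors[key]
        return v

    fig, ax = plt.subplots(figsize=(9, 3.2))
    x = np.arange(tx.length)
    ax.bar(x, scaled(control, "rna_control"), width=1.0, color="0.8")
    ax.bar(x, -scaled(stress, "rna_stress"), width=1.0, color="0.8")
    ax.bar(x, scaled(control, "ribo_control"), width=1.0, color="tab:blue")
    ax.bar(x, -scaled(stress, "ribo_stress"), width=1.0, color="tab:red")
    ax.axvspan(tx.cds_start, tx.cds_end, color="0.6", alpha=0.25, lw=0)
    for u in uorfs:
        ax.axvspan(u.start, u.end, color="tab:orange", alpha=0.35, lw=0)
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("reads (control +, stress -)")
    ax.set_title(f"{gene_id} ({tx.tx_id})")
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def report(
    out_dir: str | Path,
    diff_results: pd.DataFrame,
    uorf_results: pd.DataFrame | None = None,
    shift_results: pd.DataFrame | None = None,
    config_meta: dict | None = None,
    top_n: int = 25,
) -> Path:
    """Write ranked tables and a machine-readable run summary.

    Deterministic for fixed inputs: tables are sorted, the summary JSON has
    sorted keys, and the config hash covers the full configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diff_sorted = diff_results.sort_values(
        ["zscore", "gene_id"] if "gene_id" in diff_results.columns else "zscore",
        ascending=False,
        kind="mergesort",
    )
    diff_sorted.to_csv(out_dir / "differential_translation.tsv", sep="\t")
    if uorf_results is not None:
        uorf_results.to_csv(out_dir / "uorfs.tsv", sep="\t", index=False)
    if shift_results is not None:
        shift_results.to_csv(out_dir / "density_shifts.tsv", sep="\t", index=False)

    import ribostress

    eligible = diff_results[diff_results["eligible"]] if len(diff_results) else diff_results
    top = diff_sorted.head(top_n)
    summary = {
        "package_version": ribostress.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_genes": int(len(diff_results)),
        "n_eligible": int(eligible["eligible"].sum()) if len(diff_results) else 0,
        "class_counts": diff_results["class_label"].value_counts().to_dict()
        if len(diff_results)
        else {},
        "top_genes_by_te_zscore": list(top.index.astype(str)),
        "config": config_meta or {},
        "config_hash": hashlib.sha256(
            json.dumps(config_meta or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    return path
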
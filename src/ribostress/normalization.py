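"""Between-sample rescaling by total mapped reads or spike-in counts.

Raw counts are divided by a per-sample factor F; within a group of samples
(one assay, one replicate) F is the ratio of that sample's total (or spike
count) to the smallest total in the group, so the shallowest sample keeps
its raw counts and all factors are >= 1.  Spike-in rescaling recovers
absolute occupancy changes that total-count rescaling cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .profiles import SampleProfile
from .transcripts import TranscriptRecord

LAYERS = ("cds_ribo", "tx_rna", "leader_ribo")


@dataclass
class CountTable:
    """Per-gene counts for the chosen transcript variant across samples.

    ``cds_ribo`` and ``leader_ribo`` have ribo-seq sample columns, ``tx_rna``
    mRNA-seq sample columns; all are indexed by gene_id.  ``samples`` holds
    the design plus per-sample totals and spike counts.  Raw counts are never
    mutated; the rescaled view lives in ``rescaled``.
    """

    cds_ribo: pd.DataFrame
    tx_rna: pd.DataFrame
    leader_ribo: pd.DataFrame
    samples: pd.DataFrame
    chosen_tx: dict[str, str] = field(default_factory=dict)
    factors: pd.Series | None = None
    rescaled: dict[str, pd.DataFrame] | None = None

    def layer(self, name: str, rescaled: bool = True) -> pd.DataFrame:
        if rescaled:
            if self.rescaled is None:
                raise ValueError("rescaling has not been applied")
            return self.rescaled[name]
        return getattr(self, name)


def aggregate_counts(
    profiles: Iterable[SampleProfile],
    transcripts: Mapping[str, TranscriptRecord],
    chosen: Mapping[str, str],
) -> CountTable:
    """Aggregate per-position profiles to per-gene region counts.

    CDS ribo counts are A-site counts within [cds_start, cds_end); RNA counts
    cover the whole transcript; leader ribo counts cover [0, cds_start).
    """
    profiles = list(profiles)
    genes = sorted(chosen)
    ribo = [p for p in profiles if p.assay == "ribo"]
    rna = [p for p in profiles if p.assay == "rna"]

    def frame(samples: list[SampleProfile], region: str) -> pd.DataFrame:
        data = {}
        for p in samples:
            col = np.zeros(len(genes), dtype=np.int64)
            for i, g in enumerate(genes):
                rec = transcripts[chosen[g]]
                vec = p.counts[rec.tx_id]
                if region == "cds":
                    col[i] = vec[rec.cds_start : rec.cds_end].sum()
                elif region == "leader":
                    col[i] = vec[: rec.cds_start].sum()
                else:
                    col[i] = vec.sum()
            data[p.sample_id] = col
        return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))

    samples = pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "assay": p.assay,
                "condition": p.condition,
                "replicate": p.replicate,
                "total_mapped": p.total_mapped,
                "spike_count": p.spike_count,
            }
            for p in profiles
        ]
    ).set_index("sample_id")

    return CountTable(
        cds_ribo=frame(ribo, "cds"),
        tx_rna=frame(rna, "tx"),
        leader_ribo=frame(ribo, "leader"),
        samples=samples,
        chosen_tx=dict(chosen),
    )


def rescale_factor_total(totals: pd.Series) -> pd.Series:
    """F_n = total_n / min(total) over the samples of one assay group."""
    if len(totals) < 2:
        raise ValueError("need at least two samples to compute rescale factors")
    if (totals <= 0).any():
        bad = totals[totals <= 0].index[0]
        raise ValueError(f"sample {bad!r} has non-positive total mapped reads")
    return totals / totals.min()


def rescale_factor_spike(spikes: pd.Series) -> pd.Series:
    """F_n = spike_n / min(spike); requires spike reads in every sample."""
    if len(spikes) < 2:
        raise ValueError("need at least two samples to compute rescale factors")
    if (spikes <= 0).any():
        bad = spikes[spikes <= 0].index[0]
        raise ValueError(
            f"sample {bad!r} has no spike-in reads; fall back to rescale_factor_total"
        )
    return spikes / spikes.min()


def compute_factors(
    samples: pd.DataFrame, method: str | Mapping[int, str] = "spike"
) -> pd.Series:
    """Per-sample factors, computed within each (assay, replicate) group.

    ``method`` is 'total', 'spike', or a mapping replicate -> method, which
    allows one replicate to be normalized by library size and another by its
    spike-in counts.
    """
    factors = pd.Series(np.nan, index=samples.index, dtype=float)
    for (assay, rep), grp in samples.groupby(["assay", "replicate"], sort=True):
        m = method[rep] if isinstance(method, Mapping) else method
        if m == "total":
            f = rescale_factor_total(grp["total_mapped"].astype(float))
        elif m == "spike":
            f = rescale_factor_spike(grp["spike_count"].astype(float))
        else:
            raise ValueError(f"unknown normalization method {m!r}")
        factors.loc[f.index] = f
    return factors


def apply_rescale(table: CountTable, factors: pd.Series) -> CountTable:
    """Return a new CountTable carrying rescaled (raw / F) layers."""
    missing = [s for layer in LAYERS for s in getattr(table, layer).columns if s not in factors.index]
    if missing:
        raise KeyError(f"no rescale factor for sample {missing[0]!r}")
    if (factors.dropna() <= 0).any():
        raise ValueError("rescale factors must be positive")
    rescaled = {}
    for layer in LAYERS:
        raw = getattr(table, layer)
        rescaled[layer] = raw / factors[raw.columns]
    return replace(table, factors=factors.copy(), rescaled=rescaled)


def rescale_profile(vector: np.ndarray, factor: float) -> np.ndarray:
    """Rescale a per-position profile vector (used for transcript plots)."""
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    return np.asarray(vector, dtype=float) / factor


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Genes x samples TSV with raw and (if present) rescaled blocks."""
    blocks = []
    for layer in LAYERS:
        raw = getattr(table, layer).add_prefix(f"raw_{layer}.")
        blocks.append(raw)
        if table.rescaled is not None:
            blocks.append(table.rescaled[layer].add_prefix(f"rescaled_{layer}."))
    pd.concat(blocks, axis=1).to_csv(path, sep="\t")
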
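"""Differential translation via the expression-binned Z-score statistic.

Translation efficiency (TE) is the rescaled CDS ribo-seq count divided by
the rescaled whole-transcript mRNA-seq count; CDS-only footprint counting
keeps uORF translation out of the numerator.  Fold changes (stress/control)
are standardized within bins of genes of similar sequencing depth: genes are
ranked by their minimum normalized count across the relevant samples,
grouped into bins of 300, and each gene's log2 fold change is turned into a
Z-score using its bin's mean and standard deviation.  Because the count
noise of a fold change depends strongly on depth, this empirical
standardization makes genes comparable across the whole expression range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import CountTable

DEFAULT_BIN_SIZE = 300
DEFAULT_MIN_EXPR = 2.0
DEFAULT_Z_THRESHOLD = 4.0

CLASS_LABELS = ("preferential", "resistant", "sensitive", "unchanged", "low_coverage")

MODES = ("te", "rna", "ribo")


def compute_te(cds_ribo, tx_rna):
    """TE = rescaled CDS ribo count / rescaled transcript RNA count.

    Returns NaN where the RNA count is zero (flagged low coverage upstream).
    """
    cds_ribo = np.asarray(cds_ribo, dtype=float)
    tx_rna = np.asarray(tx_rna, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(tx_rna > 0, cds_ribo / np.where(tx_rna > 0, tx_rna, 1.0), np.nan)
    if te.ndim == 0:
        return float(te)
    return te


def min_expression(counts: pd.DataFrame, mode: str = "te") -> pd.Series:
    """Minimum normalized count per gene across the mode's samples.

    ``counts`` must already be restricted to the relevant sample columns:
    four columns in TE mode (ribo and RNA in both conditions), two in the
    rna or ribo modes.
    """
    expected = {"te": 4, "rna": 2, "ribo": 2}
    if mode not in expected:
        raise ValueError(f"unknown mode {mode!r}")
    if counts.shape[1] != expected[mode]:
        raise ValueError(
            f"mode {mode!r} expects {expected[mode]} sample columns, "
            f"got {counts.shape[1]}"
        )
    return counts.min(axis=1)


def binned_zscore(
    values: pd.Series,
    min_expr: pd.Series,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_expr_threshold: float = DEFAULT_MIN_EXPR,
) -> pd.DataFrame:
    """Standardize per-gene changes within expression bins.

    Genes below the minimum-expression threshold are excluded.  Eligible
    genes are sorted by ascending minimum expression (ties broken by gene
    id), cut into consecutive bins of ``bin_size``, and standardized with
    their bin's mean and sample standard deviation (ddof=1).  A trailing
    partial bin borrows the previous full bin's parameters; if fewer than
    ``bin_size`` genes are eligible in total, a single bin covers them all.
    A zero-variance bin yields Z = 0 for its members.

    Returns a frame aligned to the input index with columns ``zscore``
    (NaN for ineligible genes), ``bin_index`` (-1 for ineligible) and
    ``eligible``.
    """
    values = values.astype(float)
    out = pd.DataFrame(
        {"zscore": np.nan, "bin_index": -1, "eligible": False}, index=values.index
    )
    eligible = (min_expr >= min_expr_threshold) & values.notna()
    out.loc[eligible, "eligible"] = True
    order = (
        pd.DataFrame({"min_expr": min_expr[eligible], "gene": min_expr[eligible].index})
        .sort_values(["min_expr", "gene"], kind="mergesort")
        .index
    )
    n = len(order)
    if n == 0:
        return out
    if n < bin_size:
        warnings.warn(
            f"only {n} genes pass the expression threshold; using a single bin"
        )
        edges = [(0, n)]
    else:
        n_full = n // bin_size
        edges = [(k * bin_size, (k + 1) * bin_size) for k in range(n_full)]
        if n_full * bin_size < n:
            edges.append((n_full * bin_size, n))

    prev_mean, prev_sd = 0.0, 0.0
    for bin_idx, (lo, hi) in enumerate(edges):
        members = order[lo:hi]
        vals = values[members].to_numpy()
        full = (hi - lo) == bin_size or len(edges) == 1
        if full:
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            prev_mean, prev_sd = mean, sd
        else:  # trailing partial bin: borrow the previous bin's parameters
            mean, sd = prev_mean, prev_sd
        z = (vals - mean) / sd if sd > 0 else np.zeros_like(vals)
        out.loc[members, "zscore"] = z
        out.loc[members, "bin_index"] = bin_idx
    return out


def classify(
    zscore: pd.Series,
    fold_change: pd.Series,
    eligible: pd.Series,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.Series:
    """Class labels from the TE Z-score and the linear TE fold change.

    Z > threshold with fold change above 1 is 'preferential' (TE rises under
    stress); Z > threshold with fold change below 1 is 'resistant' (TE falls
    less than the bulk); Z < -threshold is 'sensitive'; anything else is
    'unchanged', and genes failing the expression threshold 'low_coverage'.
    """
    labels = pd.Series("unchanged", index=zscore.index, dtype=object)
    labels[~eligible.astype(bool)] = "low_coverage"
    el = eligible.astype(bool)
    labels[el & (zscore > z_threshold) & (fold_change > 1)] = "preferential"
    labels[el & (zscore > z_threshold) & (fold_change < 1)] = "resistant"
    labels[el & (zscore < -z_threshold)] = "sensitive"
    return labels


@dataclass
class ConcordanceResult:
    pearson: float
    spearman: float
    combined: pd.Series


def replicate_concordance(z_rep1: pd.Series, z_rep2: pd.Series) -> ConcordanceResult:
    """Correlate per-gene Z between replicates and average them."""
    common = z_rep1.index.intersection(z_rep2.index)
    if len(common) < len(z_rep1.index.union(z_rep2.index)):
        warnings.warn("replicates cover different gene sets; intersecting")
    a, b = z_rep1[common], z_rep2[common]
    ok = a.notna() & b.notna()
    if ok.sum() >= 2:
        pearson = float(np.corrcoef(a[ok], b[ok])[0, 1])
        spearman = float(stats.spearmanr(a[ok], b[ok]).statistic)
    else:
        pearson = spearman = float("nan")
    combined = (a + b) / 2.0
    return ConcordanceResult(pearson=pearson, spearman=spearman, combined=combined)


def _mode_layers(table: CountTable, mode: str, replicate: int):
    """Sample columns entering a given analysis mode for one replicate."""
    s = table.samples
    def col(assay, condition):
        match = s[(s["assay"] == assay) & (s["condition"] == condition) & (s["replicate"] == replicate)]
        if len(match) != 1:
            raise ValueError(
                f"expected exactly one {assay}/{condition} sample in replicate {replicate}"
            )
        return match.index[0]

    ribo = table.layer("cds_ribo")
    rna = table.layer("tx_rna")
    if mode == "te":
        return {
            "ribo_control": ribo[col("ribo", "control")],
            "ribo_stress": ribo[col("ribo", "stress")],
            "rna_control": rna[col("rna", "control")],
            "rna_stress": rna[col("rna", "stress")],
        }
    if mode == "rna":
        return {"control": rna[col("rna", "control")], "stress": rna[col("rna", "stress")]}
    if mode == "ribo":
        return {"control": ribo[col("ribo", "control")], "stress": ribo[col("ribo", "stress")]}
    raise ValueError(f"unknown mode {mode!r}")


def differential_translation(
    table: CountTable,
    mode: str = "te",
    bin_size: int = DEFAULT_BIN_SIZE,
    min_expr_threshold: float = DEFAULT_MIN_EXPR,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Run the binned Z-score analysis across all replicates.

    Each replicate is analysed independently (its own minimum expression,
    bins and Z-scores); per-gene Z and log2 fold changes are then averaged
    across replicates for the final calls.  A gene must pass the expression
    threshold in every replicate to be eligible.  The pseudocount enters only
    the displayed fold change of genes with a zero count (such genes cannot
    pass the threshold, so standardized values are always finite).
    """
    replicates = sorted(table.samples["replicate"].unique())
    per_rep: dict[int, pd.DataFrame] = {}
    for rep in replicates:
        layers = _mode_layers(table, mode, rep)
        if mode == "te":
            te_c = pd.Series(
                compute_te(layers["ribo_control"], layers["rna_control"]),
                index=layers["ribo_control"].index,
            )
            te_s = pd.Series(
                compute_te(layers["ribo_stress"], layers["rna_stress"]),
                index=layers["ribo_stress"].index,
            )
            num_c, num_s = layers["ribo_control"], layers["ribo_stress"]
            den_c, den_s = layers["rna_control"], layers["rna_stress"]
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc = np.log2(te_s / te_c)
                disp_fc = ((num_s.where(num_s > 0, pseudocount) / den_s.where(den_s > 0, pseudocount))
                           / (num_c.where(num_c > 0, pseudocount) / den_c.where(den_c > 0, pseudocount)))
            minexp = min_expression(pd.DataFrame(layers), mode="te")
        else:
            c, s_ = layers["control"], layers["stress"]
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc = np.log2(s_ / c)
                disp_fc = s_.where(s_ > 0, pseudocount) / c.where(c > 0, pseudocount)
            te_c = te_s = pd.Series(np.nan, index=c.index)
            minexp = min_expression(pd.DataFrame(layers), mode=mode)
        log2fc = pd.Series(log2fc, index=minexp.index).replace([np.inf, -np.inf], np.nan)
        zres = binned_zscore(log2fc, minexp, bin_size, min_expr_threshold)
        per_rep[rep] = pd.DataFrame(
            {
                "log2fc": log2fc,
                "disp_fc": disp_fc,
                "min_expr": minexp,
                "te_control": te_c,
                "te_stress": te_s,
                "zscore": zres["zscore"],
                "bin_index": zres["bin_index"],
                "eligible": zres["eligible"],
            }
        )

    first = per_rep[replicates[0]]
    eligible = pd.concat([per_rep[r]["eligible"] for r in replicates], axis=1).all(axis=1)
    zscore = pd.concat([per_rep[r]["zscore"] for r in replicates], axis=1).mean(axis=1)
    zscore[~eligible] = np.nan
    log2fc = pd.concat([per_rep[r]["log2fc"] for r in replicates], axis=1).mean(axis=1)
    disp_fc = pd.concat([per_rep[r]["disp_fc"] for r in replicates], axis=1).mean(axis=1)
    fold_change = np.power(2.0, log2fc)
    fold_change = fold_change.where(log2fc.notna(), disp_fc)
    result = pd.DataFrame(
        {
            "min_expression": pd.concat(
                [per_rep[r]["min_expr"] for r in replicates], axis=1
            ).min(axis=1),
            "te_control": pd.concat(
                [per_rep[r]["te_control"] for r in replicates], axis=1
            ).mean(axis=1),
            "te_stress": pd.concat(
                [per_rep[r]["te_stress"] for r in replicates], axis=1
            ).mean(axis=1),
            "log2fc": log2fc,
            "fold_change": fold_change,
            "zscore": zscore,
            "bin_index": first["bin_index"],
            "eligible": eligible,
        }
    )
    result["class_label"] = classify(
        result["zscore"], result["fold_change"], result["eligible"], z_threshold
    )
    # umbrella flag: any significant positive TE shift relative to the bulk
    result["stress_resistant"] = result["eligible"] & (result["zscore"] > z_threshold)
    for rep in replicates:
        result[f"zscore_rep{rep}"] = per_rep[rep]["zscore"]
    result.index.name = "gene_id"
    return result


def ranking_auroc(scores: pd.Series, labels: pd.Series) -> float:
    """Area under the ROC curve of a score ranking against binary labels,
    computed from the Mann-Whitney U statistic (ties handled by mid-ranks).
    NaN scores are dropped."""
    ok = scores.notna()
    s, y = scores[ok].to_numpy(), labels[ok].astype(bool).to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))
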
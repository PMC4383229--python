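# ribostress

Ribosome-profiling analysis of translation under eIF2 inactivation.

When eIF2α is phosphorylated (arsenite stress, the integrated stress
response), ternary-complex levels fall and bulk translation initiation
collapses — yet a handful of mRNAs, typically carrying translated upstream
ORFs in long 5′ leaders, keep or increase their ribosome load. This
package implements the computational side of a ribo-seq/mRNA-seq
experiment that finds those mRNAs:

- **Footprint processing** — 29–35 nt monosome filter, unique-mapper
  filter, A-site assignment (17th nt of the footprint for 29–32 nt reads,
  18th for 33–35), per-transcript count vectors, transcript-variant
  selection by control footprint density.
- **Normalization** — per-sample rescale factor `F_n = x_n / min_n x_n`
  computed from total mapped reads or from spike-in counts; spike
  rescaling recovers *absolute* occupancy changes that equal-depth
  sequencing otherwise hides.
- **Differential translation** — TE = CDS footprints / transcript mRNA
  reads; genes ranked by minimum normalized count, cut into bins of 300,
  and each gene's log2 TE fold change standardized by its bin's mean and
  sd (the **binned Z-score**); |Z| > 4 with the fold-change sign splits
  genes into preferential / resistant / sensitive / unchanged.
- **uORF analysis** — AUG-initiated sense-codon runs in the leader
  (CDS-overlap truncation, same-frame nesting exclusion), translated call
  at > 5 footprints, uORF TE, best-uORF rule, centre-of-ribosome-density
  shift normalized by CDS length, initiation-context frequency tables,
  leader statistics, and an RNAfold hook for leader folding energy.
- **QC** — region distribution, metagene profiles around CDS boundaries,
  per-length triplet periodicity, mirrored per-transcript profile plots.
- **Synthetic study generator** — transcriptomes with planted uORFs and a
  gamma-Poisson read simulator (two assays × two conditions × replicates,
  5.4-fold stress repression with a resistant subset, spike-in at
  1:10,000, triplet-periodic footprints) providing exact ground truth for
  every downstream statistic.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a reduced study (600 genes, 1M reads per library) and run the
differential-translation analysis:

```sh
python analysis/01_simulate.py --seed 2 --n-genes 600 \
    --library-size 1000000 --out results/sim_demo
python analysis/03_differential_translation.py --data results/sim_demo \
    --out results/diff_demo
```

```
595 of 600 genes pass the minimum-expression threshold
class counts: {'unchanged': 594, 'low_coverage': 5, 'preferential': 1}
median TE fold reduction under stress: 4.60 (simulated: 5.4)
replicate Z concordance: pearson 0.095, spearman 0.003
resistant-gene recovery AUROC by TE Z-score: 1.000
genes called stress-resistant (TE Z > 4):
         min_expression  fold_change  zscore   class_label
gene_id                                                   
G00170          175.481        1.845    4.32  preferential
```

The median eligible gene lost ~4.6× of its translation efficiency under
stress (the simulation planted 5.4×; at this reduced depth the estimate is
limited by the ~110 spike-in reads per library that anchor the rescale
factors). The three genes simulated as resistant rank at the very top of
the TE Z-score (AUROC 1.000); one clears the Z > 4 significance threshold
— at 600 genes most genes share a single expression bin, which dilutes
power, and the full 2000-gene study recovers the subset much more
completely. The replicate Z correlation is near zero because, apart from
the three resistant genes, every gene's fold change is pure noise.

`analysis/02_qc.py` prints the read-region distribution and per-length
periodicity, `analysis/04_uorf_analysis.py` the uORF landscape and density
shifts (on the same run: `resistant median shift +0.032 vs other −0.008;
100% of resistant genes shift 3′-ward`), and `analysis/05_report.py`
bundles ranked tables, a profile figure of the top resistant gene and a
run summary.

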
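# Methods

## The problem

Phosphorylation of eIF2α (the integrated stress response) depletes the
ternary complex that delivers initiator Met-tRNAi to the 40S subunit and
represses cap-dependent initiation globally, yet a small set of mRNAs keeps
or increases its ribosome load. Ribosome profiling measures this directly:
footprint density over an ORF divided by mRNA abundance density gives the
translation efficiency (TE), and comparing TE between a stressed and a
control culture identifies the resistant transcripts. This package
implements that comparison — from transcript-space alignments to gene
classes — together with the upstream-ORF and ribosome-geometry statistics
used to characterize the resistant class, and a synthetic-data generator
that reproduces the count structure of such an experiment so the whole
chain is testable without sequencing data.

## Read processing (`profiles`)

Input alignments are positive-strand, transcript-space records
(tx, 5′ position, length, mapping multiplicities). Footprints outside
29–35 nt (monosome-protected size) and reads mapping to more than one gene
or to multiple positions of a transcript are discarded; a ledger accounts
for every input read. The ribosomal A-site is taken as the 17th nt of the
footprint (zero-based offset +16) for lengths 29–32 and the 18th (+17) for
33–35 — a monotone, midpoint-centred assignment, configurable as a
length→offset table. Ribo-seq vectors count A-sites, mRNA-seq vectors count
read 5′ ends. Footprints whose A-site would fall past the transcript end
are discarded and ledgered. Among a gene's coding isoforms the variant with
the highest control footprint density (reads/nt) is carried forward; ties
break lexicographically.

## Between-sample rescaling (`normalization`)

Within one assay and replicate, each sample's counts are divided by
F = value_sample / min(value), where value is either the total mapped read
count or the spike-in read count; the shallowest sample keeps raw counts
and min(F) = 1. Total-count rescaling equalizes depth but is blind to
uniform absolute changes: when every CDS loses ~80% of its ribosomes and
the library is sequenced to the same depth, relative counts barely move.
A spike-in oligo added in constant absolute amount before library
preparation breaks that degeneracy — its read share inflates exactly as
the footprint pool shrinks — so spike rescaling recovers absolute
occupancy. The synthetic study therefore defaults to spike rescaling;
both methods (and a per-replicate mix) are available. Rescaled counts are
real-valued and kept alongside immutable raw counts.

## Differential translation (`diffexpr`)

TE = rescaled CDS footprint count / rescaled whole-transcript mRNA count;
CDS-only counting keeps uORF footprints out of the numerator. The change
statistic is the binned Z-score: per replicate, each gene's minimum
normalized count across the four relevant samples (two for RNA-only or
ribo-only analyses) is its minimum expression level; genes below 2 are
excluded; the rest are sorted ascending, cut into bins of 300, and the
log2 fold change is standardized by its bin's mean and sample sd (ddof 1).
A trailing partial bin borrows the previous bin's parameters; fewer than
300 eligible genes total form a single bin; a zero-sd bin yields Z = 0.
Standardizing on the log2 scale makes up- and down-regulation symmetric;
the reported fold change stays linear. Replicates are analysed
independently and their Z and log2 FC averaged; a gene must pass the
expression threshold in every replicate. With |Z| > 4 as the significance
threshold, genes split into: preferential (Z > 4, FC > 1), resistant
(Z > 4, FC < 1), sensitive (Z < −4), unchanged, low_coverage; an umbrella
flag (Z > 4) covers both positive classes.

## uORFs and density geometry (`uorf`)

A uORF is an AUG-initiated (optionally near-cognate) run of sense codons in
the 5′ leader: each start-codon occurrence wholly upstream of the CDS
extends codon-by-codon to an in-frame stop, or is truncated at the CDS
start if none intervenes; candidates starting inside an accepted uORF in
the same frame (which would share its stop) are dropped. Length counts
sense codons including the initiator, excluding the stop; truncated uORFs
get floor((cds_start − start)/3). A uORF is called translated when more
than five footprints place their A-site inside it; its TE is footprint
density over the uORF divided by mRNA density over the whole transcript;
when several uORFs are translated, the one with the most footprints
represents the transcript (ties to the 5′-most).

The centre of ribosome density is the minimal coordinate c with at least as
many footprints at positions ≤ c as at positions > c ("5′ of c" read
inclusively; the alternative reading changes the result by at most 1 nt).
The stress-induced shift is (centre_stress − centre_control)/CDS-length,
positive meaning 3′-ward — the signature of ribosomes vacating a leader
uORF for the CDS. Initiation-context tables count window sequences around
start-codon A positions (default −4..+4, spanning the codon; −4..+3 and
−3..+4 variants selectable); relative frequency is count/total × 100.
Leader folding energy is exposed only as a hook (first 240 nt, shorter
leaders excluded) delegating to an external RNAfold-style executable or
callable; no folding algorithm is implemented.

## The synthetic study (`simulate`)

The generator encodes the study conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes (one transcript each) |
| leader/CDS/trailer | N(170, 80) nt / N(400, 120) codons / N(120, 60) nt | transcript architecture (floors 30 nt / 60 codons / 30 nt) |
| uorf_prob | 0.3 | leaders carrying one planted AUG uORF |
| uorf_length_dist | 3–60 codons | uniform draw |
| resistant_fraction | 0.02 | of uORF-bearing genes |
| repression_factor | 5.4 | stress CDS-TE divisor for non-resistant genes |
| uorf_density_ratio | 3.0 | uORF/CDS footprint density in control |
| uorf_shift_fraction | 0.6 | uORF occupancy moved to the CDS in resistant genes under stress |
| dispersion | 0.05 | gamma-Poisson overdispersion per gene × sample |
| library_size | 6e6 | reads per library |
| spike_fraction | 1e-4 | expected spike read share in a control library |
| periodicity | 0.9 | probability a footprint sits in its length's preferred frame |
| n_replicates | 2 | per condition |

Leaders are AUG-free except the planted uORF (stray ATGs are scrubbed by a
C substitution that can neither create a start nor a stop), so the uORF
ground truth is exact. RNA abundances are log-normal (log2 sd 2), control
TE log-normal (log2 sd 0.7), and RNA levels are unchanged under stress
unless a per-gene effect list is supplied. Footprint A-sites are drawn
from per-codon weights (CDS uniform; uORF at the density ratio), jittered
off-frame with probability 1 − periodicity, assigned a length from a
29–35 categorical peaked at 31, and converted to 5′ ends by the offset
table; mRNA reads are uniform. Counts are gamma-Poisson around
depth × pool-share. The spike oligo has a constant absolute amount per
assay (calibrated to a 1e-4 read share in control), so its share inflates
under stress in proportion to the lost footprint mass.

Numerical design choices: dispersion 0.05 makes between-condition log2 FC
noise ≈ 0.46, so the simulated 5.4-fold effect (2.43 log2 units) stands
about 5 sd above the bulk — a resistant subset that is actually detectable
at the Z = 4 threshold, as in a well-controlled cell-line experiment
(at dispersion 0.1 the effect would sit below 4 sd and the design could
not produce its own phenotype). library_size 6e6 with spike share 1e-4
gives ~600 expected spike reads; the Poisson error of the four spike
counts (~4–8% on a replicate's fold change, common to all genes) is the
dominant uncertainty in the recovered median fold, and at this depth a
three-seed mean resolves a 5.4-fold effect to well within 10%.

What the generator does not emulate: sequencing errors and quality,
rRNA/contaminant reads, UMI duplicates, spliced genome-space alignment,
isoform mixtures (one transcript per gene is generated, although the
variant-selection code handles many), nucleotide-level coverage biases
(ligation/RNase preferences), and reinitiation mechanics — the resistant
uORF→CDS redistribution is a linear parameter, not a mechanistic model,
and is not calibrated against any measured profile. Passing recovery tests
therefore shows the statistics are implemented and powered as designed,
not that the biological model is complete.

## Validation

- The uORF scanner and the density centre are checked exactly against
  independent brute-force enumerations (1000 random leaders / 1000 random
  sparse vectors).
- Null calibration: with repression 1 and no resistant genes (5000 genes,
  3 seeds), the fraction of |Z| > 4 is ≤ 0.001 and every full bin
  standardizes to mean 0, sd 1 by construction.
- Recovery: on defaults (2000 genes, 3 seeds) the pipeline's median TE
  fold reduction is within 10% of the simulated 5.4, simulated-resistant
  genes rank above the rest by TE Z (AUROC ≥ 0.9), and ≥ 80% of them show
  a positive density shift.
- Degenerate inputs: empty read sets, empty transcriptomes, zero spike
  counts (error directing to total-count rescaling), zero RNA coverage
  (low-coverage flag), all-zero profiles (undefined centre, flagged).

Problem sizes in tests and in `scripts/acceptance.py` (2000/5000 genes,
6e6 reads, 3 seeds) are the package's chosen study scale; the generator
accepts larger values unchanged.
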
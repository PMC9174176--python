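# Methods

`pluroadmap` implements the bespoke computational layer of a chromatin- and
transcriptome-based roadmap analysis of the human primed-to-naive pluripotency
transition: empirical-FDR-calibrated open/closed chromatin charting,
accessibility-dynamics classification, min–max gene-signature scoring,
log-ratio marker selection, single-cell QC and lineage assignment, and
temporal expression clustering. This note records the models, the defaults
and why, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Open/closed threshold calibration

ATAC signal over candidate loci is RPKM-normalized
(`count × 10⁹ / (length_bp × library_size)`). To decide where "background"
ends and "open" begins, length- and chromosome-matched background regions are
placed by rejection sampling, excluding the peak set and previously placed
backgrounds (a bedtools-shuffle-style exclusion shuffle; cross-chromosome
placement is an option flag). Pooling all entries of the peak matrix and the
background matrix, the empirical FDR at a candidate threshold `t` is

    eFDR(t) = (#{background ≥ t} · N_peak / N_bg) / #{peak ≥ t}

and `t*` is the smallest observed value with a nonzero peak exceedance and
`eFDR(t) ≤ α` (default `α = 0.01`). Numerical choices:

- **Candidates are restricted to observed values.** eFDR is a step function
  of `t`, so this loses nothing and makes an exhaustive oracle finite; the
  implementation (sorted pools + `searchsorted`) is tested for exact equality
  against that brute-force sweep.
- **Pooled, not per-sample.** A single genome-wide threshold is calibrated
  over all matrix entries; a per-sample variant would be a straightforward
  extension but is not implemented.
- **Equality at the threshold counts as open.** "Below → closed, above →
  open" leaves ties undefined; the inclusive-open rule is fixed and tested.
- On real data of this design the same procedure yields thresholds in the
  ~14 RPKM range; on the synthetic null (exponential, scale 1) it lands near
  5 RPKM. The procedure, not the constant, is the deliverable.

## Dynamics classification (CO/OC/PO/PC)

Replicate RPKM columns are averaged into one column per stage (the matrix
analogue of merging replicate alignments before analysis), binarized at
`t*`, and each region's stage-wise pattern is classified: PO = open at every
stage, PC = closed at every stage, CO = exactly one closed→open switch,
OC = exactly one open→closed switch. Patterns with two or more switches are
reported as COMPLEX rather than forced into the four canonical groups, since
no rule for non-monotone loci is prescribed by the four-group scheme;
stage-order reversal therefore maps CO↔OC and fixes PO/PC/COMPLEX, a
symmetry the tests assert exactly.

Promoter assignment uses TSS ± 3 kb windows, half-open `[tss−w, tss+w)`,
clipped to chromosome bounds; for minus-strand genes the annotated
transcript end coordinate is the TSS. With `w = 0` only regions containing
the TSS position qualify.

## Signature scoring

Bulk samples are scored per gene set by min–max scaling each gene across the
sample panel, `s = (x − min)/(max − min)`, then averaging over genes, giving
panel-relative scores in [0, 1]. Genes must reach FPKM ≥ 5 (inclusive) in at
least one panel sample; genes with `max = min` are dropped from the mean
(the formula is undefined there) and counted in the returned report. Min and
max are taken over exactly the panel passed in — scores are panel-relative
by construction, so panel membership is an explicit argument, never a global
default. Symbol matching is exact and case-sensitive.

Single cells get a control-set module score: counts are log-normalized
(`log(1 + count/cell_total × 10⁴)`), genes are binned by mean expression
(24 rank-based bins), and the score is the mean over set genes minus the
mean over a size-matched control pool (100 controls per set gene, drawn
without replacement from the gene's bin, seeded). Under a null set the score
is centered at zero within Monte-Carlo error.

TSC markers are selected from a five-condition FPKM panel by four strict
log2-ratio cutoffs with a +1 pseudocount: `log2((nTSC+1)/(hES+1)) > 3`,
`log2((nTSC+1)/(pTSC+1)) > 2.5`, `log2((EVT+1)/(nTSC+1)) < −1.5`,
`log2((ST+1)/(nTSC+1)) < −1.5`. A ratio exactly at a cutoff is excluded.

## Expression profiles

Expressed-gene filtering keeps rows with FPKM ≥ 5 in ≥ 1 sample (idempotent).
Temporal clustering runs Lloyd's k-means (k = 6, k-means++ init, 10
restarts, seeded, via scikit-learn) on per-gene z-scored log2(FPKM+1): the
grouping targets profile *shape*, which requires per-gene standardization;
whether to cluster raw, log, or standardized values was an open choice and
the z-scored-log variant is this package's documented decision. Top-variance
selection ranks features by variance of log2(value+1) with lexicographic id
tie-breaks; sample correlation is Pearson on log2(FPKM+1) over expressed
genes.

## Single-cell QC and lineage proportions

Cells pass QC iff nFeature > 2500, 1000 < nCount < 100,000, and pctMT < 10
(all strict); then genes detected (≥ 1 count) in ≥ 10 surviving cells are
kept and ribosomal genes are removed. Mitochondrial genes are identified by
the `MT-` symbol prefix and ribosomal genes by `RPL`/`RPS` (the standard
human conventions; both configurable). The order — cell gates first, then
gene filters — changes results and is therefore fixed.

Lineage assignment is per-cell argmax over the four signature scores
(naive, primed, TE, PrE), with exact ties or margins below a configurable
minimum left unassigned; a cluster-majority mode would sit on top of this
but per-cell argmax is the testable primitive. Proportion tables always sum
to 1 per stage; dropping unassigned cells and renormalizing is an explicit
option, never silent.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and return truth
objects sufficient to predict every downstream output.

- **Accessibility**: background and closed entries ~ Exponential(scale 1.0);
  open entries ~ Normal(μ = 50, σ = 5) truncated at 0. No distributional
  form is prescribed for real RPKM; these were chosen once as a simple,
  separable null/signal pair with tunable overlap (μ is > 10× the background
  99th percentile, ~4.6). σ is a free noise parameter, not inferred from
  data. Label counts use largest-remainder allocation so planted proportions
  are exact; CO/OC switch stages are drawn uniformly over interior
  boundaries. The default design is 3 replicates per stage, merged before
  binarization — matching the emulated assay design; with single replicates
  the calibrated threshold leaves ~0.5% of background draws open and
  per-region recovery drops below 99%.
- **Bulk FPKM**: lognormal baseline (log-mean 1, log-sd 1) with signature
  genes multiplied by per-stage effect factors ≥ 1.
- **Marker panel**: true markers are constructed to pass all four ratio
  cutoffs with ≥ 0.5 log2 units of margin, non-markers to fail ≥ 1 by the
  same margin, so exact set recovery is a construction guarantee.
- **Single-cell counts**: gamma-Poisson (negative binomial, size 10) around
  gene means = 5 × lognormal(0, 0.3) gene factor × lognormal(0, 0.15)
  library factor, with the cell's own lineage markers elevated 8×; 13 `MT-`
  and 20 `RPL`/`RPS` genes are emitted for QC testing. The 3000-gene
  universe and base mean 5 were chosen so nominal cells clear the absolute
  nFeature > 2500 gate with a wide margin (min observed ≈ 2790); planted QC
  failures shrink the library 50× (low-feature mode) or inflate
  mitochondrial means 100× (pctMT ≈ 30% mode), far beyond the gates. The
  planted-failure fraction defaults to 0 and is raised explicitly in QC
  benchmarks.

Not emulated: read-level data, doublets, ambient RNA, batch effects,
chromatin–expression coupling, and realistic gene–gene correlation. Passing
the recovery benchmarks therefore demonstrates correctness of the decision
rules and calibration logic under a clean generative model — not performance
on real libraries, where QC cutoff placement and signature composition
dominate.

## Problem sizes

The shipped benchmarks run on 2,000 regions × 5 stages × 3 replicates
(accessibility), 100 random matrices for the calibration oracle, 500-region
shuffles, 500-gene bulk panels, 50-gene marker panels, and 500–2,000-cell
count matrices over 3,000 genes — sizes at which the exhaustive oracles
(full threshold sweeps, all-pairs interval intersection, per-cell rule
scans) remain exact and cheap while every code path is exercised.

## Known limitations

- Replicate merging averages RPKM columns; merging alignments before
  re-quantification (the upstream convention) is not identical, and the
  divergence is accepted and documented here.
- The eFDR is calibrated on pooled entries; per-sample calibration is listed
  as a variant, not implemented.
- Signature gene sets are user input; the package ships only synthetic
  example sets.
- Cluster-count selection for temporal profiles is fixed at k = 6 by
  default, not chosen by any model-selection criterion.
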
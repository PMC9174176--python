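# pluroadmap

Chromatin accessibility dynamics charting and lineage-signature scoring for
studies of the human primed-to-naive pluripotency transition.

When primed pluripotent stem cells are reset toward the naive state, the
culture passes through intermediates carrying trophectoderm (TE) and
primitive endoderm (PrE) signatures before most cells reach naive
pluripotency. Mapping that roadmap from stage-ordered ATAC-seq and RNA-seq
requires a handful of bespoke computations that sit between the standard
upstream tools (alignment, peak calling, quantification) and the biology:

- **Open/closed threshold calibration.** Length-matched background regions
  are shuffled into the genome (excluding the peak set), and the open/closed
  RPKM threshold *t\** is the smallest observed value at which the empirical
  FDR — scaled background exceedances over peak exceedances,
  `eFDR(t) = (#{bg ≥ t}·N_peak/N_bg) / #{peak ≥ t}` — drops to α (default 1%).
- **Accessibility dynamics classes.** Stage-wise open/closed calls per locus
  are classified as CO (closed→open), OC (open→closed), PO (permanently
  open), PC (permanently closed), or COMPLEX (multi-switch), with promoter
  assignment via TSS ± 3 kb windows.
- **Signature scores.** Bulk samples are scored per gene set by min–max
  scaling each gene across the panel, `s = (x − min)/(max − min)`, averaged
  over genes with FPKM ≥ 5 in ≥ 1 sample — scores live in [0, 1]. Single
  cells get a seeded control-set module score. TSC markers are selected by
  four strict log2-ratio cutoffs against hES/pTSC/EVT/ST conditions.
- **Single-cell QC and lineage tracking.** Cells pass with nFeature > 2500,
  1000 < nCount < 100,000, pctMT < 10; genes need ≥ 1 count in ≥ 10 cells
  and ribosomal genes are removed. Per-cell argmax over the four lineage
  scores (naive/primed/TE/PrE) feeds stage-wise proportion tables.
- **Temporal expression clustering.** k-means (k = 6) over z-scored
  log2(FPKM+1) profiles, plus top-variance feature selection and sample
  correlation.

Because the real datasets live behind repository accessions, the package
ships seeded synthetic generators that plant CO/OC/PO/PC dynamics, signature
effects, marker panels and lineage-labelled count matrices with full ground
truth, so every stage is benchmarked end-to-end against exact oracles.

The core stages are scikit-learn-style estimators
(`OpenThresholdCalibrator`, `TemporalProfileKMeans`, `SignatureScorer`,
`CellModuleScorer`, `CellQC`, `LineageAssigner`) with plain-function
wrappers, and a `pluroadmap` CLI wires them into a reproducible run.

## Worked example

```python
import collections
import pluroadmap as pr
from pluroadmap.simulate import replicate_stage_map

sm = replicate_stage_map(("pESC", "day6", "day8", "day10", "naive"))
regions, peaks, background, truth = pr.simulate_cad_dataset(
    pr.toy_genome(), 2000,
    {"CO": 0.25, "OC": 0.25, "PO": 0.25, "PC": 0.25},
    sm, pr.CadParams(), seed=7)

thr = pr.calibrate_open_threshold(peaks, background, alpha=0.01)
print(f"t* = {thr.t_star:.2f} RPKM (eFDR = {thr.efdr_at_t:.4f})")

merged = pr.merge_replicates(peaks, sm)
labels = pr.classify_dynamics(pr.binarize_accessibility(merged, thr))
print(dict(collections.Counter(l.value for l in labels.values())))
n_ok = sum(labels[r].value == truth.labels[r] for r in truth.labels)
print(f"planted-label recovery: {n_ok}/{len(truth.labels)}")
```

prints

```
t* = 5.19 RPKM (eFDR = 0.0100)
{'CO': 499, 'COMPLEX': 1, 'OC': 500, 'PO': 500, 'PC': 500}
planted-label recovery: 1999/2000
```

The calibrated threshold (5.19 RPKM here) is the smallest observed value at
which scaled background exceedances fall to 1% of peak exceedances; 500 loci
per dynamics class were planted, and after replicate merging and
binarization, 1999 of 2000 loci are recovered — the single miss is a
background draw that straddled the threshold in one stage, demoting a
planted class to COMPLEX.

The same flow runs from the shell:

```sh
pluroadmap run --seed 7 --out-dir demo/
```

which simulates fixtures, calibrates and classifies chromatin dynamics,
scores signatures, selects markers, QC-filters and assigns lineages,
clusters temporal profiles, and writes a `manifest.json` of output digests.

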
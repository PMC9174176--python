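import numpy as np
import pandas as pd
import pytest

from pluroadmap import GenomeModel, StageMap, ValueMatrix


@pytest.fixture
def genome() -> GenomeModel:
    return GenomeModel((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture
def five_stages() -> StageMap:
    names = ("pESC", "day6", "day8", "day10", "naive")
    return StageMap(names, {s: s for s in names})


@pytest.fixture
def small_fpkm() -> ValueMatrix:
    """Three samples; gene g1 spans (0, 5, 10), the worked scaling example."""
    data = pd.DataFrame(
        {
            "s1": [0.0, 10.0, 7.0],
            "s2": [5.0, 20.0, 7.0],
            "s3": [10.0, 40.0, 7.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ValueMatrix(data, "FPKM")


def brute_force_threshold(peak: np.ndarray, bg: np.ndarray, alpha: float):
    """Exhaustive sweep over all candidate thresholds (independent oracle)."""
    peak = np.ravel(peak)
    bg = np.ravel(bg)
    for t in np.unique(np.concatenate([peak, bg])):
        n_peak = int((peak >= t).sum())
        if n_peak == 0:
            continue
        efdr = int((bg >= t).sum()) * (peak.size / bg.size) / n_peak
        if efdr <= alpha:
            return float(t), float(efdr)
    return None


def brute_force_qc(counts, qc):
    """Independent per-cell / per-gene QC rule scan (oracle)."""
    genes = counts.feature_ids
    mito = [g for g in genes if g.startswith(qc.mito_prefix)]
    kept_cells = []
    for cell in counts.sample_ids:
        col = counts.data[cell]
        n_count = col.sum()
        n_feature = int((col > 0).sum())
        pct_mt = col[mito].sum() / n_count * 100 if n_count > 0 else 0.0
        if (n_feature > qc.min_features
                and qc.min_count < n_count < qc.max_count
                and pct_mt < qc.max_pct_mt):
            kept_cells.append(cell)
    kept_genes = []
    for g in genes:
        if g.startswith(tuple(qc.ribo_prefixes)):
            continue
        if int((counts.data.loc[g, kept_cells] >= 1).sum()) >= qc.min_cells_per_gene:
            kept_genes.append(g)
    return kept_cells, kept_genes


def brute_force_overlaps(regions_a, regions_b) -> int:
    """All-pairs interval intersection count (independent oracle)."""
    n = 0
    for a in regions_a:
        for b in regions_b:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                n += 1
    return n
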
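"""Gene-signature scoring and marker selection.

Bulk samples are scored against a gene set by min-max scaling each
retained gene across the sample panel — s_gj = (x_gj - min_g)/(max_g -
min_g) — and averaging the scaled values per sample, giving a score in
[0, 1] that is relative to the panel passed in.  Genes must clear an
FPKM >= tau floor in at least one panel sample to be retained, and genes
with a degenerate range (max = min) are dropped from the mean.

Single cells are scored with a control-set module score: the mean
log-normalized expression of the set genes minus the mean of size-matched
control genes drawn from the same average-expression bins, so a null set
scores near zero regardless of expression magnitude.

Trophoblast-stem-cell (TSC) markers are selected from a five-condition
FPKM panel (nTSC, hES, pTSC, EVT, ST) by four strict log2-ratio cutoffs
requiring enrichment in nTSC over hES and pTSC and depletion relative to
the differentiated EVT/ST derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import MarkerThresholds
from .io import GeneSet, ValueMatrix, logger

MARKER_PANEL_CONDITIONS = ("nTSC", "hES", "pTSC", "EVT", "ST")


@dataclass(frozen=True)
class ScaledExpression:
    """Per-gene min-max scaled expression over a sample panel, values in [0,1]."""

    scaled: pd.DataFrame          # retained genes x samples
    retained_genes: tuple[str, ...]
    dropped_low: tuple[str, ...]      # failed the FPKM floor
    dropped_constant: tuple[str, ...]  # max == min
    missing: tuple[str, ...]          # set genes absent from the matrix


def minmax_scale_genes(
    matrix: ValueMatrix, gene_set: GeneSet, tau: float = 5.0
) -> ScaledExpression:
    """Min-max scale a signature's genes across the sample panel.

    Genes absent from the matrix are ignored with a warning; genes with
    no sample at or above ``tau`` and genes with max = min are dropped.
    Raises if no gene survives.
    """
    if matrix.shape[1] < 2:
        raise ValueError("min-max scaling needs a panel of >= 2 samples")
    present = [g for g in gene_set.genes if g in matrix.data.index]
    missing = tuple(g for g in gene_set.genes if g not in matrix.data.index)
    if missing:
        logger.warning("signature %r: %d gene(s) absent from matrix: %s",
                       gene_set.name, len(missing), list(missing[:5]))
    sub = matrix.data.loc[present]
    gene_max = sub.max(axis=1)
    gene_min = sub.min(axis=1)
    low = gene_max < tau
    constant = (~low) & (gene_max == gene_min)
    keep = ~(low | constant)
    dropped_constant = tuple(sub.index[constant])
    if dropped_constant:
        logger.info("signature %r: dropped %d constant gene(s)",
                    gene_set.name, len(dropped_constant))
    if not keep.any():
        raise ValueError(
            f"signature {gene_set.name!r}: no genes retained "
            f"(floor tau={tau}, panel of {matrix.shape[1]} samples)"
        )
    kept = sub.loc[keep]
    rng = (gene_max - gene_min).loc[keep]
    scaled = kept.sub(gene_min.loc[keep], axis=0).div(rng, axis=0)
    return ScaledExpression(
        scaled=scaled,
        retained_genes=tuple(kept.index),
        dropped_low=tuple(sub.index[low]),
        dropped_constant=dropped_constant,
        missing=missing,
    )


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Score bulk samples against gene signatures by panel-relative min-max.

    Parameters
    ----------
    gene_sets : list of GeneSet
        Signatures to score.
    tau : float, default 5.0
        FPKM floor: a gene is retained if >= tau in at least one panel sample.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        samples x signatures score table, entries in [0, 1].
    retained_ : dict
        signature name -> tuple of retained gene symbols.
    """

    def __init__(self, gene_sets: list[GeneSet] | None = None, tau: float = 5.0):
        self.gene_sets = gene_sets
        self.tau = tau

    def fit(self, matrix: ValueMatrix, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be a nonempty list")
        scores: dict[str, pd.Series] = {}
        retained: dict[str, tuple[str, ...]] = {}
        for gs in self.gene_sets:
            scaled = minmax_scale_genes(matrix, gs, self.tau)
            scores[gs.name] = scaled.scaled.mean(axis=0)
            retained[gs.name] = scaled.retained_genes
        self.scores_ = pd.DataFrame(scores)
        self.retained_ = retained
        return self

    def transform(self, matrix: ValueMatrix) -> pd.DataFrame:
        return self.fit(matrix).scores_


def bulk_signature_score(
    matrix: ValueMatrix, gene_sets: list[GeneSet], tau: float = 5.0
) -> pd.DataFrame:
    """samples x signatures score table; see :class:`SignatureScorer`."""
    return SignatureScorer(gene_sets=gene_sets, tau=tau).fit(matrix).scores_


# ---------------------------------------------------------------------------
# Single-cell module score
# ---------------------------------------------------------------------------

def log_normalize_counts(counts: ValueMatrix, scale_factor: float = 1e4) -> pd.DataFrame:
    """log(1 + count / cell_total * scale_factor), genes x cells."""
    if counts.scale != "COUNT":
        raise ValueError("log normalization expects a COUNT matrix")
    totals = counts.data.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    return np.log1p(counts.data / totals * scale_factor)


class CellModuleScorer(BaseEstimator):
    """Control-set module score for single cells.

    Genes are binned by their mean log-normalized expression over cells
    (rank-based, ``n_bins`` bins); for each set gene, ``n_ctrl`` control
    genes are drawn from its bin, and the score is the per-cell mean over
    set genes minus the per-cell mean over the pooled controls.

    Parameters
    ----------
    n_bins : int, default 24
    n_ctrl : int, default 100
    random_state : int, default 0
    """

    def __init__(self, n_bins: int = 24, n_ctrl: int = 100, random_state: int = 0):
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.random_state = random_state

    def score(self, counts: ValueMatrix, gene_set: GeneSet) -> pd.Series:
        """Per-cell score; deterministic under ``random_state``."""
        lognorm = log_normalize_counts(counts)
        set_genes = [g for g in gene_set.genes if g in lognorm.index]
        if not set_genes:
            raise ValueError(
                f"gene set {gene_set.name!r} has no genes in the matrix"
            )
        rng = np.random.default_rng(self.random_state)
        gene_means = lognorm.mean(axis=1)
        n_bins = min(self.n_bins, len(gene_means))
        # rank-based equal-count bins; ties broken by index order (deterministic)
        bins = pd.qcut(gene_means.rank(method="first"), q=n_bins, labels=False)
        bin_members: dict[int, np.ndarray] = {
            int(b): np.asarray(idx)
            for b, idx in gene_means.groupby(bins).groups.items()
        }
        controls: list[str] = []
        for g in set_genes:
            members = bin_members[int(bins.loc[g])]
            take = min(self.n_ctrl, len(members))
            controls.extend(rng.choice(members, size=take, replace=False))
        control_genes = pd.unique(np.asarray(controls))
        score = lognorm.loc[set_genes].mean(axis=0) - lognorm.loc[control_genes].mean(axis=0)
        score.name = gene_set.name
        return score


def cell_module_score(
    counts: ValueMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Functional wrapper around :class:`CellModuleScorer`."""
    return CellModuleScorer(n_bins=n_bins, n_ctrl=n_ctrl, random_state=seed).score(
        counts, gene_set
    )


# ---------------------------------------------------------------------------
# TSC marker selection
# ---------------------------------------------------------------------------

def marker_log_ratios(
    panel: ValueMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """The four log2 ratios per gene on an (nTSC, hES, pTSC, EVT, ST) panel."""
    missing = [c for c in MARKER_PANEL_CONDITIONS if c not in panel.sample_ids]
    if missing:
        raise ValueError(f"marker panel is missing condition(s): {missing}")
    d = panel.data
    n = d["nTSC"] + pseudocount
    return pd.DataFrame(
        {
            "log2_nTSC_vs_hES": np.log2(n / (d["hES"] + pseudocount)),
            "log2_nTSC_vs_pTSC": np.log2(n / (d["pTSC"] + pseudocount)),
            "log2_EVT_vs_nTSC": np.log2((d["EVT"] + pseudocount) / n),
            "log2_ST_vs_nTSC": np.log2((d["ST"] + pseudocount) / n),
        }
    )


def select_tsc_markers(
    panel: ValueMatrix,
    thresholds: MarkerThresholds = MarkerThresholds(),
    pseudocount: float = 1.0,
) -> GeneSet:
    """Keep genes passing all four strict log2-ratio cutoffs.

    A gene is a TSC marker iff log2((nTSC+1)/(hES+1)) > r1,
    log2((nTSC+1)/(pTSC+1)) > r2, log2((EVT+1)/(nTSC+1)) < r3 and
    log2((ST+1)/(nTSC+1)) < r4 — all strict, so a ratio exactly at a
    cutoff is excluded.
    """
    ratios = marker_log_ratios(panel, pseudocount)
    keep = (
        (ratios["log2_nTSC_vs_hES"] > thresholds.r1)
        & (ratios["log2_nTSC_vs_pTSC"] > thresholds.r2)
        & (ratios["log2_EVT_vs_nTSC"] < thresholds.r3)
        & (ratios["log2_ST_vs_nTSC"] < thresholds.r4)
    )
    return GeneSet("TSC_markers", tuple(ratios.index[keep]))
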
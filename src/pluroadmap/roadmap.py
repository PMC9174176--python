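"""Single-cell QC, lineage assignment and per-stage proportion tracking.

Cells pass QC when all three strict gates hold: nFeature > 2500 detected
genes, 1000 < nCount < 100,000 total counts, and pctMT < 10 percent of
counts on mitochondrial (``MT-``-prefixed) genes.  Genes are then kept
when detected (>= 1 count) in at least 10 surviving cells, and ribosomal
(``RPL``/``RPS``-prefixed) genes are removed.  Lineages (naive, primed,
TE, PrE) are assigned per cell as the argmax over the four signature
scores, with ties or sub-margin calls left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import QCConfig
from .io import StageMap, ValueMatrix

LINEAGES = ("naive", "primed", "TE", "PrE")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CellQCReport:
    """Per-cell QC metrics and flags plus per-gene detection counts."""

    cell_metrics: pd.DataFrame   # nFeature, nCount, pctMT, pass flags per cell
    gene_detection: pd.Series    # gene -> n surviving cells with count >= 1
    n_cells_in: int
    n_cells_kept: int
    n_genes_in: int
    n_genes_kept: int


class CellQC(BaseEstimator):
    """Quality filter for a genes x cells count matrix.

    Order of operations is fixed: cell gates first, then the gene
    detection filter (computed on the surviving cells), then ribosomal
    gene removal.

    Attributes
    ----------
    report_ : CellQCReport
    filtered_ : ValueMatrix
    """

    def __init__(self, qc: QCConfig | None = None):
        self.qc = qc

    def fit_transform(self, counts: ValueMatrix, y=None) -> ValueMatrix:
        qc = self.qc or QCConfig()
        if counts.scale != "COUNT":
            raise ValueError("QC expects a COUNT matrix")
        values = counts.values
        if not np.allclose(values, np.round(values)):
            raise ValueError("QC expects integer counts")
        genes = pd.Index(counts.feature_ids)
        is_mt = genes.str.startswith(qc.mito_prefix)
        is_ribo = genes.str.startswith(tuple(qc.ribo_prefixes))

        n_count = values.sum(axis=0)
        n_feature = (values > 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_mt = np.where(
                n_count > 0, values[is_mt].sum(axis=0) / n_count * 100.0, 0.0
            )
        pass_feat = n_feature > qc.min_features
        pass_count = (n_count > qc.min_count) & (n_count < qc.max_count)
        pass_mt = pct_mt < qc.max_pct_mt
        keep_cell = pass_feat & pass_count & pass_mt

        kept_cells = [c for c, k in zip(counts.sample_ids, keep_cell) if k]
        detection = pd.Series(
            (values[:, keep_cell] >= 1).sum(axis=1), index=genes, name="n_cells_detected"
        )
        keep_gene = (detection >= qc.min_cells_per_gene).to_numpy() & ~is_ribo
        kept_genes = genes[keep_gene]

        metrics = pd.DataFrame(
            {
                "nFeature": n_feature,
                "nCount": n_count,
                "pctMT": pct_mt,
                "pass_nFeature": pass_feat,
                "pass_nCount": pass_count,
                "pass_pctMT": pass_mt,
                "pass": keep_cell,
            },
            index=list(counts.sample_ids),
        )
        self.report_ = CellQCReport(
            cell_metrics=metrics,
            gene_detection=detection,
            n_cells_in=counts.shape[1],
            n_cells_kept=len(kept_cells),
            n_genes_in=counts.shape[0],
            n_genes_kept=int(keep_gene.sum()),
        )
        self.filtered_ = ValueMatrix(
            counts.data.loc[kept_genes, kept_cells], "COUNT"
        )
        return self.filtered_


def qc_filter_cells(
    counts: ValueMatrix, qc: QCConfig | None = None
) -> tuple[ValueMatrix, CellQCReport]:
    """Functional wrapper around :class:`CellQC`."""
    est = CellQC(qc=qc)
    filtered = est.fit_transform(counts)
    return filtered, est.report_


def cell_scores_table(
    counts: ValueMatrix,
    marker_sets,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """cells x lineages module-score table from one marker GeneSet per lineage."""
    from .signatures import CellModuleScorer

    by_name = {gs.name: gs for gs in marker_sets}
    missing = [l for l in LINEAGES if l not in by_name]
    if missing:
        raise ValueError(f"missing marker set(s) for lineage(s): {missing}")
    scorer = CellModuleScorer(n_bins=n_bins, n_ctrl=n_ctrl, random_state=seed)
    return pd.DataFrame({lin: scorer.score(counts, by_name[lin]) for lin in LINEAGES})


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageAssignment:
    """Per-cell lineage labels, score vectors, and argmax margins."""

    labels: pd.Series     # cell -> label (lineage or "unassigned")
    scores: pd.DataFrame  # cells x lineages
    margins: pd.Series    # best - second-best score per cell


class LineageAssigner(BaseEstimator):
    """Assign each cell the lineage with the highest signature score.

    Exact ties and margins below ``min_margin`` are left unassigned.
    """

    def __init__(self, min_margin: float = 0.0):
        self.min_margin = min_margin

    def predict(self, scores: pd.DataFrame) -> LineageAssignment:
        missing = [l for l in LINEAGES if l not in scores.columns]
        if missing:
            raise ValueError(f"score table is missing lineage(s): {missing}")
        s = scores[list(LINEAGES)]
        if s.isna().any().any():
            raise ValueError("score table contains missing values")
        arr = s.to_numpy()
        order = np.sort(arr, axis=1)
        best, second = order[:, -1], order[:, -2]
        margins = pd.Series(best - second, index=s.index, name="margin")
        labels = pd.Series(
            np.asarray(LINEAGES)[np.argmax(arr, axis=1)], index=s.index, name="lineage"
        )
        tie = best == second
        below = margins < self.min_margin
        labels[tie | below] = UNASSIGNED
        return LineageAssignment(labels=labels, scores=s, margins=margins)


def assign_lineage(scores: pd.DataFrame, min_margin: float = 0.0) -> LineageAssignment:
    """Functional wrapper around :class:`LineageAssigner`."""
    return LineageAssigner(min_margin=min_margin).predict(scores)


def lineage_proportions(
    assignment: LineageAssignment,
    stage_map: StageMap,
    drop_unassigned: bool = False,
) -> pd.DataFrame:
    """Stage x label proportion table; rows sum to 1.

    With ``drop_unassigned`` the unassigned cells are removed per stage and
    the remaining proportions renormalized (explicitly, never silently).
    """
    unstaged = set(assignment.labels.index) - set(stage_map.assignment)
    if unstaged:
        raise ValueError(f"cells without a stage: {sorted(unstaged)[:5]}")
    columns = list(LINEAGES) + [UNASSIGNED]
    rows = {}
    for stage in stage_map.stages:
        cells = [c for c in assignment.labels.index
                 if stage_map.assignment[c] == stage]
        labels = assignment.labels.loc[cells]
        if drop_unassigned:
            labels = labels[labels != UNASSIGNED]
        if len(labels) == 0:
            raise ValueError(f"stage {stage!r} has no cells to tally")
        counts = labels.value_counts().reindex(columns, fill_value=0)
        rows[stage] = counts / counts.sum()
    table = pd.DataFrame(rows).T[columns]
    table.index.name = "stage"
    return table
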
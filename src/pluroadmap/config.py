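"""Pipeline configuration: every tunable threshold in one place.

Defaults are the constants used throughout the analysis: 1% empirical FDR
for the open/closed threshold, an FPKM >= 5 expressed-gene floor, k = 6
temporal clusters, TSS +/- 3 kb promoter windows, top-2000-variance feature
selection, the four TSC-marker log2-ratio cutoffs (3, 2.5, -1.5, -1.5), and
the single-cell QC gates (nFeature > 2500, 1000 < nCount < 100,000,
pctMT < 10, genes detected in >= 10 cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class MarkerThresholds:
    """log2-ratio cutoffs for TSC-marker selection (strict inequalities)."""

    r1: float = 3.0     # log2((nTSC+1)/(hES+1)) > r1
    r2: float = 2.5     # log2((nTSC+1)/(pTSC+1)) > r2
    r3: float = -1.5    # log2((EVT+1)/(nTSC+1)) < r3
    r4: float = -1.5    # log2((ST+1)/(nTSC+1)) < r4


@dataclass(frozen=True)
class QCConfig:
    """Per-cell and per-gene quality gates for droplet scRNA-seq counts."""

    min_features: int = 2500       # cells kept need nFeature strictly above this
    min_count: int = 1000          # strict lower bound on nCount
    max_count: int = 100_000       # strict upper bound on nCount
    max_pct_mt: float = 10.0       # strict upper bound on % mitochondrial counts
    min_cells_per_gene: int = 10   # genes kept need >= 1 count in >= this many cells
    mito_prefix: str = "MT-"
    ribo_prefixes: tuple[str, ...] = ("RPL", "RPS")


@dataclass(frozen=True)
class PipelineConfig:
    fdr_alpha: float = 0.01
    expression_floor: float = 5.0          # FPKM floor tau
    kmeans_k: int = 6
    promoter_halfwidth: int = 3000         # bp
    top_variance_k: int = 2000
    marker_thresholds: MarkerThresholds = field(default_factory=MarkerThresholds)
    pseudocount: float = 1.0
    qc: QCConfig = field(default_factory=QCConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError(f"fdr_alpha must lie in (0, 1), got {self.fdr_alpha}")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML mapping of PipelineConfig fields; omitted fields default."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    kwargs = dict(raw)
    if "marker_thresholds" in kwargs:
        kwargs["marker_thresholds"] = MarkerThresholds(**kwargs["marker_thresholds"])
    if "qc" in kwargs:
        qc = dict(kwargs["qc"])
        if "ribo_prefixes" in qc:
            qc["ribo_prefixes"] = tuple(qc["ribo_prefixes"])
        kwargs["qc"] = QCConfig(**qc)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
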
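"""Chromatin accessibility dynamics (CAD) charting.

The central question this module answers is: at which RPKM value does an
ATAC signal over a candidate locus stop looking like background?  The
answer is calibrated empirically: shuffled background regions (same
lengths, same chromosomes, excluded from the peak set) provide a null
RPKM distribution, and the open/closed threshold ``t*`` is the smallest
observed value at which the scaled fraction of background entries at or
above ``t`` — an empirical false discovery rate — drops to the requested
``alpha``.  Binarized stage-wise calls are then classified into the four
canonical dynamics groups: CO (closed-to-open), OC (open-to-closed),
PO (permanently open) and PC (permanently closed), with non-monotone
patterns set aside as COMPLEX.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GenomeModel, Region, RegionSet, StageMap, ValueMatrix, logger


class DynamicsLabel(str, enum.Enum):
    """Stage-wise accessibility dynamics class of a locus."""

    CO = "CO"            # closed-to-open: one closed->open switch
    OC = "OC"            # open-to-closed: one open->closed switch
    PO = "PO"            # permanently open
    PC = "PC"            # permanently closed
    COMPLEX = "COMPLEX"  # any multi-switch pattern


@dataclass(frozen=True)
class OpenThreshold:
    """A calibrated open/closed RPKM threshold and its achieved empirical FDR."""

    t_star: float
    alpha: float
    efdr_at_t: float
    n_peak_entries: int
    n_background_entries: int

    def __post_init__(self) -> None:
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")
        if self.efdr_at_t > self.alpha:
            raise ValueError("achieved eFDR exceeds alpha")


@dataclass(frozen=True)
class AccessibilityCalls:
    """Boolean open/closed calls, regions x ordered stages (True = open)."""

    region_ids: tuple[str, ...]
    stages: tuple[str, ...]
    calls: np.ndarray  # bool, shape (n_regions, n_stages)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.region_ids), len(self.stages)):
            raise ValueError("calls shape does not match ids/stages")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=list(self.region_ids),
                            columns=list(self.stages))


@dataclass(frozen=True)
class PromoterAssignment:
    """region id -> gene symbols whose TSS +/- w window overlaps the region."""

    assignment: Mapping[str, tuple[str, ...]]
    halfwidth: int


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def compute_rpkm(
    read_counts: ValueMatrix,
    region_lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
) -> ValueMatrix:
    """Reads-per-kilobase-per-million: count * 1e9 / (length_bp * library_size)."""
    if read_counts.scale != "COUNT":
        raise ValueError("compute_rpkm expects a COUNT matrix")
    lengths = np.array([region_lengths[f] for f in read_counts.feature_ids], float)
    libs = np.array([library_sizes[s] for s in read_counts.sample_ids], float)
    if (lengths <= 0).any():
        raise ValueError("region lengths must be positive")
    if (libs <= 0).any():
        bad = read_counts.sample_ids[int(np.argmin(libs))]
        raise ValueError(f"library size for sample {bad!r} must be positive")
    rpkm = read_counts.values * 1e9 / (lengths[:, None] * libs[None, :])
    return ValueMatrix(
        pd.DataFrame(rpkm, index=read_counts.feature_ids, columns=read_counts.sample_ids),
        "RPKM",
    )


# ---------------------------------------------------------------------------
# Background shuffling
# ---------------------------------------------------------------------------

def shuffle_background(
    peaks: RegionSet,
    genome: GenomeModel,
    seed: int,
    max_attempts: int = 1000,
    same_chromosome: bool = True,
) -> RegionSet:
    """Place one length-matched background region per peak by rejection sampling.

    Backgrounds avoid every peak and every previously placed background.
    With ``same_chromosome`` (default) each background stays on its peak's
    chromosome, mirroring an exclusion-based bedtools-style shuffle.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    # per-chromosome sorted exclusion intervals (peaks + placed backgrounds)
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for p in peaks:
        excl[p.chrom].append((p.start, p.end))
    for c in excl:
        excl[c].sort()

    def _overlaps(chrom: str, start: int, end: int) -> bool:
        ivs = excl[chrom]
        lo, hi = 0, len(ivs)
        while lo < hi:  # first interval with end > start
            mid = (lo + hi) // 2
            if ivs[mid][1] <= start:
                lo = mid + 1
            else:
                hi = mid
        return lo < len(ivs) and ivs[lo][0] < end

    chrom_names = [c for c, _ in genome.chromosomes]
    placed: list[Region] = []
    for p in peaks:
        ok = False
        for _ in range(max_attempts):
            chrom = p.chrom if same_chromosome else chrom_names[rng.integers(len(chrom_names))]
            span = lengths[chrom] - p.length
            if span < 0:
                continue
            start = int(rng.integers(0, span + 1))
            end = start + p.length
            if not _overlaps(chrom, start, end):
                ivs = excl[chrom]
                lo, hi = 0, len(ivs)
                while lo < hi:
                    mid = (lo + hi) // 2
                    if ivs[mid] < (start, end):
                        lo = mid + 1
                    else:
                        hi = mid
                ivs.insert(lo, (start, end))
                placed.append(Region(chrom, start, end, f"bg_{p.id}"))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place background for region {p.id!r} "
                f"after {max_attempts} attempts"
            )
    return RegionSet(placed, genome)


# ---------------------------------------------------------------------------
# Threshold calibration / binarization (estimator)
# ---------------------------------------------------------------------------

class OpenThresholdCalibrator(TransformerMixin, BaseEstimator):
    """Calibrate an open/closed RPKM threshold at a target empirical FDR.

    Pooling every entry of the peak matrix and of the background matrix,
    the empirical FDR at a candidate threshold ``t`` is

        eFDR(t) = (#{background >= t} * N_peak / N_bg) / #{peak >= t}

    i.e. the background exceedance count rescaled to the peak matrix size,
    divided by the peak exceedance count.  ``t*`` is the smallest observed
    value (candidates are the sorted distinct values of both matrices)
    with a nonzero peak exceedance and eFDR <= alpha.  Equality at the
    threshold counts as open.

    Parameters
    ----------
    alpha : float, default 0.01
        Target empirical FDR in (0, 1).

    Attributes
    ----------
    threshold_ : OpenThreshold
        Calibrated threshold with achieved eFDR and pool sizes.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, peak_matrix: ValueMatrix, background_matrix: ValueMatrix):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        peak = np.sort(peak_matrix.values.ravel())
        bg = np.sort(background_matrix.values.ravel())
        if peak.size == 0 or bg.size == 0:
            raise ValueError("peak and background matrices must be nonempty")
        candidates = np.unique(np.concatenate([peak, bg]))
        # exceedance counts via searchsorted on the sorted pools
        n_peak_ge = peak.size - np.searchsorted(peak, candidates, side="left")
        n_bg_ge = bg.size - np.searchsorted(bg, candidates, side="left")
        scale = peak.size / bg.size
        with np.errstate(divide="ignore", invalid="ignore"):
            efdr = np.where(n_peak_ge > 0, n_bg_ge * scale / n_peak_ge, np.inf)
        passing = (n_peak_ge > 0) & (efdr <= self.alpha)
        if not passing.any():
            raise ValueError(
                "no candidate threshold achieves the target eFDR; "
                "increase alpha or the peak/background separation"
            )
        i = int(np.argmax(passing))  # smallest candidate, candidates sorted
        self.threshold_ = OpenThreshold(
            t_star=float(candidates[i]),
            alpha=self.alpha,
            efdr_at_t=float(efdr[i]),
            n_peak_entries=int(peak.size),
            n_background_entries=int(bg.size),
        )
        return self

    def transform(self, stage_matrix: ValueMatrix) -> AccessibilityCalls:
        """Binarize a stage-merged RPKM matrix: open iff value >= t*."""
        if not hasattr(self, "threshold_"):
            raise AttributeError("calibrator is not fitted")
        return binarize_accessibility(stage_matrix, self.threshold_)


def calibrate_open_threshold(
    peak_matrix: ValueMatrix, background_matrix: ValueMatrix, alpha: float = 0.01
) -> OpenThreshold:
    """Functional wrapper around :class:`OpenThresholdCalibrator`."""
    return OpenThresholdCalibrator(alpha=alpha).fit(peak_matrix, background_matrix).threshold_


def merge_replicates(matrix: ValueMatrix, stage_map: StageMap) -> ValueMatrix:
    """Average replicate columns into one column per stage (stage order kept)."""
    stage_map.validate_against(matrix)
    unassigned = set(matrix.sample_ids) - set(stage_map.assignment)
    if unassigned:
        raise ValueError(f"samples without a stage: {sorted(unassigned)}")
    cols = {
        stage: matrix.data[stage_map.samples_for(stage)].mean(axis=1)
        for stage in stage_map.stages
    }
    merged = pd.DataFrame(cols)[list(stage_map.stages)]
    return ValueMatrix(merged, matrix.scale)


def binarize_accessibility(
    stage_matrix: ValueMatrix, threshold: OpenThreshold
) -> AccessibilityCalls:
    """Open iff RPKM >= t*; equality at the threshold counts as open."""
    return AccessibilityCalls(
        region_ids=tuple(stage_matrix.feature_ids),
        stages=tuple(stage_matrix.sample_ids),
        calls=stage_matrix.values >= threshold.t_star,
    )


# ---------------------------------------------------------------------------
# Dynamics classification
# ---------------------------------------------------------------------------

def _classify_pattern(pattern: np.ndarray) -> DynamicsLabel:
    if pattern.all():
        return DynamicsLabel.PO
    if not pattern.any():
        return DynamicsLabel.PC
    switches = int(np.sum(pattern[1:] != pattern[:-1]))
    if switches == 1:
        return DynamicsLabel.CO if pattern[-1] else DynamicsLabel.OC
    return DynamicsLabel.COMPLEX


def classify_dynamics(calls: AccessibilityCalls) -> dict[str, DynamicsLabel]:
    """Map each region's open/closed pattern to CO/OC/PO/PC/COMPLEX.

    CO and OC require exactly one switch (so CO is closed at the first
    stage and open at the last, OC the mirror image); any pattern with
    two or more switches is COMPLEX.
    """
    if len(calls.stages) < 2:
        raise ValueError("dynamics classification needs >= 2 stages")
    return {
        rid: _classify_pattern(calls.calls[i])
        for i, rid in enumerate(calls.region_ids)
    }


# ---------------------------------------------------------------------------
# Promoter assignment
# ---------------------------------------------------------------------------

def assign_promoters(
    regions: RegionSet,
    tss_table: Sequence[tuple[str, str, int, str]],
    halfwidth: int = 3000,
    genome: GenomeModel | None = None,
) -> PromoterAssignment:
    """Assign each region the genes whose promoter window overlaps it.

    The promoter window is ``[tss - w, tss + w)`` clipped to the
    chromosome.  ``tss_table`` rows are (gene, chrom, tss, strand); for
    minus-strand genes the caller supplies the annotated transcript end
    coordinate as the TSS.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    lengths = genome.lengths if genome is not None else None
    # promoter windows per chromosome
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for gene, chrom, tss, _strand in tss_table:
        if lengths is not None:
            if chrom not in lengths:
                raise ValueError(f"gene {gene!r}: unknown chromosome {chrom!r}")
            if not 0 <= tss <= lengths[chrom]:
                raise ValueError(f"gene {gene!r}: TSS {tss} outside {chrom}")
        lo = max(0, tss - halfwidth)
        hi = tss + halfwidth if halfwidth > 0 else tss + 1
        if lengths is not None:
            hi = min(hi, lengths[chrom])
        if lo < hi:
            windows.setdefault(chrom, []).append((lo, hi, gene))
    assignment: dict[str, tuple[str, ...]] = {}
    for r in regions:
        hits = [
            gene
            for lo, hi, gene in windows.get(r.chrom, [])
            if r.start < hi and lo < r.end
        ]
        assignment[r.id] = tuple(hits)
    return PromoterAssignment(assignment=assignment, halfwidth=halfwidth)
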
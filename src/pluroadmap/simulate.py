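"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and a seed, and
returns truth objects sufficient to predict the expected output of each
downstream stage:

* :func:`simulate_cad_dataset` — stage-wise region accessibility with
  planted CO/OC/PO/PC dynamics over an exponential null background,
  emulating an RPKM peak matrix paired with a shuffled-background matrix.
* :func:`simulate_bulk_signatures` — lognormal bulk FPKM with planted
  per-stage signature effect multipliers.
* :func:`simulate_marker_panel` — a five-condition (nTSC, hES, pTSC,
  EVT, ST) FPKM panel where true markers pass all four log2-ratio
  cutoffs with >= 0.5 log2 units of margin and non-markers fail at
  least one by the same margin.
* :func:`simulate_cell_matrix` — negative-binomial single-cell counts
  with planted lineage labels, library-size variation, mitochondrial and
  ribosomal genes, and an optional fraction of planted QC-failing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, GenomeModel, Region, RegionSet, StageMap, ValueMatrix

CAD_LABELS = ("CO", "OC", "PO", "PC")
LINEAGES = ("naive", "primed", "TE", "PrE")


def largest_remainder_allocation(
    n: int, proportions: Mapping[str, float], order: Sequence[str]
) -> dict[str, int]:
    """Integer counts summing to n, proportional by largest remainder.

    Remainder ties are broken by position in ``order`` so the allocation
    is deterministic.
    """
    total = sum(proportions.get(k, 0.0) for k in order)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, expected 1")
    quotas = {k: n * proportions.get(k, 0.0) for k in order}
    counts = {k: int(np.floor(quotas[k])) for k in order}
    short = n - sum(counts.values())
    by_rem = sorted(order, key=lambda k: (-(quotas[k] - counts[k]), order.index(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def toy_genome(n_chromosomes: int = 3, length: int = 10_000_000) -> GenomeModel:
    """A small uniform stand-in genome for synthetic runs."""
    return GenomeModel(tuple((f"chr{i + 1}", length) for i in range(n_chromosomes)))


def replicate_stage_map(stage_names: Sequence[str], n_replicates: int = 3) -> StageMap:
    """A stage map with ``n_replicates`` samples per stage (<stage>_rep<i>).

    Three replicates per stage is the default ATAC design emulated here;
    replicate averaging before binarization suppresses the background
    tail that single samples leave above a calibrated threshold.
    """
    assignment = {
        f"{st}_rep{r + 1}": st for st in stage_names for r in range(n_replicates)
    }
    return StageMap(tuple(stage_names), assignment)


# ---------------------------------------------------------------------------
# CAD dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CadParams:
    """Signal/null model for synthetic accessibility.

    Open entries ~ Normal(mu_open, sigma_open) truncated at 0; closed and
    background entries ~ Exponential(bg_scale).  Defaults put the open
    mean far above the background 99th percentile (~4.6 at scale 1), so
    calibration at alpha = 0.01 separates the two cleanly.
    """

    mu_open: float = 50.0
    sigma_open: float = 5.0
    bg_scale: float = 1.0
    region_length: int = 500

    def __post_init__(self) -> None:
        if self.mu_open <= 0 or self.bg_scale <= 0:
            raise ValueError("mu_open and bg_scale must be positive")
        if self.sigma_open < 0:
            raise ValueError("sigma_open must be >= 0")


@dataclass(frozen=True)
class CadTruth:
    """Planted dynamics labels and switch stages for a CAD simulation."""

    labels: dict[str, str]            # region id -> CO/OC/PO/PC
    switch_stage: dict[str, int]      # CO/OC region id -> first stage after switch
    params: CadParams
    label_counts: dict[str, int]


def _open_pattern(label: str, switch: int, n_stages: int) -> np.ndarray:
    stages = np.arange(n_stages)
    if label == "PO":
        return np.ones(n_stages, bool)
    if label == "PC":
        return np.zeros(n_stages, bool)
    if label == "CO":
        return stages >= switch
    if label == "OC":
        return stages < switch
    raise ValueError(f"unknown label {label!r}")


def simulate_cad_dataset(
    genome: GenomeModel,
    n_regions: int,
    label_proportions: Mapping[str, float],
    stages: StageMap,
    params: CadParams = CadParams(),
    seed: int = 0,
) -> tuple[RegionSet, ValueMatrix, ValueMatrix, CadTruth]:
    """Regions, per-sample peak RPKM, matched background RPKM, and truth.

    Label counts follow largest-remainder allocation over (CO, OC, PO,
    PC).  Each CO/OC region gets a planted switch stage drawn uniformly
    from the interior stage boundaries.  One matrix column is emitted per
    assigned sample (one per stage when the stage map carries no sample
    assignment), so replicate merging can be exercised upstream.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    counts = largest_remainder_allocation(n_regions, label_proportions, CAD_LABELS)
    labels = [lab for lab in CAD_LABELS for _ in range(counts[lab])]

    # lay regions along chromosomes with random gaps (never overlapping)
    chroms = list(genome.chromosomes)
    regions: list[Region] = []
    ci, cursor = 0, 0
    for i in range(n_regions):
        gap = int(rng.integers(200, 2000))
        while cursor + gap + params.region_length > chroms[ci][1]:
            ci += 1
            cursor = 0
            if ci >= len(chroms):
                raise ValueError("genome too small for requested regions")
        start = cursor + gap
        regions.append(
            Region(chroms[ci][0], start, start + params.region_length, f"region_{i + 1:05d}")
        )
        cursor = start + params.region_length
    region_set = RegionSet(regions, genome)

    n_stages = len(stages.stages)
    if n_stages < 2:
        raise ValueError("need >= 2 stages")
    assignment = dict(stages.assignment) or {s: s for s in stages.stages}
    samples = [s for st in stages.stages for s in assignment if assignment[s] == st]
    stage_idx = np.array([stages.stages.index(assignment[s]) for s in samples])

    switch: dict[str, int] = {}
    truth_labels: dict[str, str] = {}
    open_grid = np.zeros((n_regions, n_stages), bool)
    for i, (r, lab) in enumerate(zip(regions, labels)):
        truth_labels[r.id] = lab
        sw = int(rng.integers(1, n_stages)) if lab in ("CO", "OC") else 0
        if lab in ("CO", "OC"):
            switch[r.id] = sw
        open_grid[i] = _open_pattern(lab, sw, n_stages)

    open_cells = open_grid[:, stage_idx]  # regions x samples
    bg_draw = rng.exponential(params.bg_scale, size=(n_regions, len(samples)))
    open_draw = np.maximum(
        rng.normal(params.mu_open, params.sigma_open, size=(n_regions, len(samples))),
        0.0,
    )
    peak_values = np.where(open_cells, open_draw, bg_draw)
    background = rng.exponential(params.bg_scale, size=(n_regions, len(samples)))

    ids = [r.id for r in regions]
    peaks_vm = ValueMatrix(pd.DataFrame(peak_values, index=ids, columns=samples), "RPKM")
    bg_vm = ValueMatrix(
        pd.DataFrame(background, index=[f"bg_{i}" for i in ids], columns=samples), "RPKM"
    )
    truth = CadTruth(labels=truth_labels, switch_stage=switch, params=params,
                     label_counts=counts)
    return region_set, peaks_vm, bg_vm, truth


# ---------------------------------------------------------------------------
# Bulk signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureTruth:
    """Planted signature memberships and per-stage effect multipliers."""

    signatures: dict[str, tuple[tuple[str, ...], dict[str, float]]]
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0

    def __post_init__(self) -> None:
        for name, (_genes, effects) in self.signatures.items():
            for stage, mult in effects.items():
                if not np.isfinite(mult) or mult < 1:
                    raise ValueError(
                        f"signature {name!r}: effect multiplier for {stage!r} "
                        f"must be finite and >= 1"
                    )


def simulate_bulk_signatures(
    n_genes: int,
    samples_per_stage: int,
    stages: StageMap,
    truth: SignatureTruth,
    seed: int = 0,
) -> tuple[ValueMatrix, SignatureTruth]:
    """Lognormal baseline FPKM with signature genes multiplied per stage."""
    universe = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    uni_set = set(universe)
    for name, (genes, _effects) in truth.signatures.items():
        outside = [g for g in genes if g not in uni_set]
        if outside:
            raise ValueError(
                f"signature {name!r} members outside the gene universe: {outside[:5]}"
            )
    rng = np.random.default_rng(seed)
    samples = [f"{st}_rep{r + 1}" for st in stages.stages for r in range(samples_per_stage)]
    sample_stage = [st for st in stages.stages for _ in range(samples_per_stage)]
    base = np.exp(
        rng.normal(truth.baseline_log_mean, truth.baseline_log_sd,
                   size=(n_genes, len(samples)))
    )
    idx = {g: i for i, g in enumerate(universe)}
    for _name, (genes, effects) in truth.signatures.items():
        rows = [idx[g] for g in genes]
        mult = np.array([effects.get(st, 1.0) for st in sample_stage])
        base[np.ix_(rows, range(len(samples)))] *= mult[None, :]
    vm = ValueMatrix(pd.DataFrame(base, index=universe, columns=samples), "FPKM")
    return vm, truth


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

def simulate_marker_panel(
    n_genes: int, n_true_markers: int, seed: int = 0, margin: float = 0.5
) -> tuple[ValueMatrix, tuple[str, ...]]:
    """A five-condition FPKM panel with constructed true/false TSC markers.

    True markers satisfy all four log2-ratio cutoffs (3, 2.5, -1.5, -1.5,
    with the +1 pseudocount) by at least ``margin`` log2 units; every
    non-marker fails at least one cutoff by at least ``margin``.
    """
    if n_true_markers > n_genes:
        raise ValueError("n_true_markers cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    marker_pos = set(rng.choice(n_genes, size=n_true_markers, replace=False).tolist())

    rows = np.zeros((n_genes, 5))
    for i in range(n_genes):
        n = rng.uniform(100.0, 400.0)
        if i in marker_pos:
            r1 = rng.uniform(3.0 + margin, 6.0)
            r2 = rng.uniform(2.5 + margin, 5.0)
            r3 = rng.uniform(-5.0, -1.5 - margin)
            r4 = rng.uniform(-5.0, -1.5 - margin)
        else:
            # choose >= 1 cutoff to violate by >= margin; others pass
            viol = rng.random(4) < 0.5
            if not viol.any():
                viol[rng.integers(4)] = True
            r1 = rng.uniform(0.0, 3.0 - margin) if viol[0] else rng.uniform(3.0 + margin, 6.0)
            r2 = rng.uniform(0.0, 2.5 - margin) if viol[1] else rng.uniform(2.5 + margin, 5.0)
            r3 = rng.uniform(-1.5 + margin, 1.0) if viol[2] else rng.uniform(-5.0, -1.5 - margin)
            r4 = rng.uniform(-1.5 + margin, 1.0) if viol[3] else rng.uniform(-5.0, -1.5 - margin)
        hes = (n + 1) / 2 ** r1 - 1
        ptsc = (n + 1) / 2 ** r2 - 1
        evt = (n + 1) * 2 ** r3 - 1
        st = (n + 1) * 2 ** r4 - 1
        rows[i] = (n, hes, ptsc, evt, st)
    vm = ValueMatrix(
        pd.DataFrame(rows, index=ids, columns=["nTSC", "hES", "pTSC", "EVT", "ST"]),
        "FPKM",
    )
    markers = tuple(ids[i] for i in sorted(marker_pos))
    return vm, markers


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageParams:
    """Generative model for synthetic droplet counts.

    Counts are negative binomial (gamma-Poisson, size ``dispersion``)
    around gene means ~ base_mean x lognormal gene factor, scaled by a
    lognormal per-cell library factor; each cell's own lineage markers
    are elevated by ``elevation``.  Planted QC failures shrink the
    library factor (low-feature/low-count mode) or inflate mitochondrial
    means (high-pctMT mode).
    """

    proportions: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.25, "primed": 0.25, "TE": 0.25, "PrE": 0.25}
    )
    elevation: float = 8.0
    base_mean: float = 5.0
    gene_factor_sd: float = 0.3
    library_log_sd: float = 0.15
    dispersion: float = 10.0
    qc_fail_fraction: float = 0.0
    n_mito_genes: int = 13
    n_ribo_genes: int = 20

    def __post_init__(self) -> None:
        if self.elevation <= 1:
            raise ValueError("elevation factor must exceed 1")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class LineageTruth:
    """Planted per-cell lineage labels and QC-failure flags."""

    lineage: dict[str, str]           # cell id -> lineage
    qc_fail: dict[str, str]           # failing cell id -> mode (low_library|high_mito)
    marker_sets: tuple[GeneSet, ...]
    params: LineageParams


def default_lineage_marker_sets(n_per_set: int = 40) -> tuple[GeneSet, ...]:
    """Disjoint synthetic marker sets, one per lineage."""
    return tuple(
        GeneSet(lin, tuple(f"{lin.upper()}_M{j + 1:03d}" for j in range(n_per_set)))
        for lin in LINEAGES
    )


def simulate_cell_matrix(
    n_cells: int,
    n_genes: int = 3000,
    params: LineageParams = LineageParams(),
    marker_sets: Sequence[GeneSet] | None = None,
    seed: int = 0,
) -> tuple[ValueMatrix, LineageTruth]:
    """Negative-binomial counts with planted lineages and QC structure.

    The gene universe is: the four disjoint lineage marker sets, then
    ``MT-``-prefixed mitochondrial genes, ``RPL``/``RPS``-prefixed
    ribosomal genes, and background genes up to ``n_genes``.
    """
    if marker_sets is None:
        marker_sets = default_lineage_marker_sets()
    names = [gs.name for gs in marker_sets]
    if sorted(names) != sorted(LINEAGES):
        raise ValueError(f"need one marker set per lineage {LINEAGES}, got {names}")
    all_markers = [g for gs in marker_sets for g in gs.genes]
    if len(set(all_markers)) != len(all_markers):
        raise ValueError("marker sets must be pairwise disjoint")

    mito = [f"MT-SIM{j + 1}" for j in range(params.n_mito_genes)]
    half = params.n_ribo_genes // 2
    ribo = [f"RPL{j + 1}SIM" for j in range(half)] + [
        f"RPS{j + 1}SIM" for j in range(params.n_ribo_genes - half)
    ]
    n_bg = n_genes - len(all_markers) - len(mito) - len(ribo)
    if n_bg < 0:
        raise ValueError("n_genes too small for marker/mito/ribo genes")
    genes = all_markers + mito + ribo + [f"BG_{j + 1:05d}" for j in range(n_bg)]

    rng = np.random.default_rng(seed)
    counts_per_lineage = largest_remainder_allocation(n_cells, params.proportions, LINEAGES)
    cell_ids = [f"cell_{i + 1:05d}" for i in range(n_cells)]
    lineage_of = {}
    i = 0
    for lin in LINEAGES:
        for _ in range(counts_per_lineage[lin]):
            lineage_of[cell_ids[i]] = lin
            i += 1

    n_fail = int(round(params.qc_fail_fraction * n_cells))
    fail_cells = rng.choice(n_cells, size=n_fail, replace=False)
    qc_fail = {
        cell_ids[c]: ("low_library" if j % 2 == 0 else "high_mito")
        for j, c in enumerate(sorted(fail_cells))
    }

    gene_factor = np.exp(rng.normal(0.0, params.gene_factor_sd, size=len(genes)))
    base = params.base_mean * gene_factor  # per-gene mean
    lib = np.exp(rng.normal(0.0, params.library_log_sd, size=n_cells))

    marker_rows = {gs.name: np.array([genes.index(g) for g in gs.genes]) for gs in marker_sets}
    mito_rows = np.arange(len(all_markers), len(all_markers) + len(mito))

    means = np.repeat(base[:, None], n_cells, axis=1)
    for ci, cell in enumerate(cell_ids):
        means[marker_rows[lineage_of[cell]], ci] *= params.elevation
        mode = qc_fail.get(cell)
        if mode == "low_library":
            means[:, ci] *= 0.02
        elif mode == "high_mito":
            means[mito_rows, ci] *= 100.0
    means *= lib[None, :]

    # gamma-Poisson negative binomial with size = dispersion
    shape = params.dispersion
    lam = rng.gamma(shape, means / shape)
    counts = rng.poisson(lam).astype(float)

    vm = ValueMatrix(pd.DataFrame(counts, index=genes, columns=cell_ids), "COUNT")
    truth = LineageTruth(
        lineage=lineage_of, qc_fail=qc_fail,
        marker_sets=tuple(marker_sets), params=params,
    )
    return vm, truth
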
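"""Domain containers and plain-text readers/writers shared by every pipeline stage.

All genomic coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Quantification matrices are features x samples, complete
(no missing entries) and nonnegative, with a scale tag recording whether the
values are RPKM, FPKM or raw counts.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pluroadmap")
if not logger.handlers:  # structured lines to stderr, once
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VALID_SCALES = ("RPKM", "FPKM", "COUNT")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genome / regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome model")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"region {self.id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class RegionSet:
    """An ordered collection of uniquely identified regions."""

    def __init__(self, regions: Iterable[Region], genome: GenomeModel | None = None):
        self.regions: list[Region] = list(regions)
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids: {dupes[:5]}")
        if genome is not None:
            lengths = genome.lengths
            for r in self.regions:
                if r.chrom not in lengths:
                    raise ValueError(f"region {r.id!r}: unknown chromosome {r.chrom!r}")
                if r.end > lengths[r.chrom]:
                    raise ValueError(
                        f"region {r.id!r} ends at {r.end} beyond {r.chrom} "
                        f"length {lengths[r.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "id": [r.id for r in self.regions],
            }
        )


# ---------------------------------------------------------------------------
# Value matrices
# ---------------------------------------------------------------------------

class ValueMatrix:
    """A features x samples nonnegative quantification matrix.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
    scale
        One of ``RPKM``, ``FPKM`` or ``COUNT``.
    """

    def __init__(self, data: pd.DataFrame, scale: str):
        if scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {scale!r}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)
        self.scale = scale

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_features(self, ids: Sequence[str]) -> "ValueMatrix":
        return ValueMatrix(self.data.loc[list(ids)], self.scale)

    def subset_samples(self, ids: Sequence[str]) -> "ValueMatrix":
        return ValueMatrix(self.data[list(ids)], self.scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValueMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# Stage maps / gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageMap:
    """Ordered stage names plus a sample -> stage assignment."""

    stages: tuple[str, ...]
    assignment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage names")
        unknown = {s for s in self.assignment.values() if s not in self.stages}
        if unknown:
            raise ValueError(f"assignment uses undeclared stages: {sorted(unknown)}")

    def samples_for(self, stage: str) -> list[str]:
        return [s for s, st in self.assignment.items() if st == stage]

    def validate_against(self, matrix: ValueMatrix) -> None:
        missing = set(self.assignment) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"assigned samples absent from matrix: {sorted(missing)}")
        for stage in self.stages:
            if not self.samples_for(stage):
                raise ValueError(f"stage {stage!r} has no samples")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_value_matrix(path: str | Path, scale: str) -> ValueMatrix:
    """Read a TSV matrix (header = sample ids, first column = feature ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed file structure
        raise ParseError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dupes[:5]}")
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        ) from exc
    try:
        return ValueMatrix(numeric, scale)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_value_matrix(matrix: ValueMatrix, path: str | Path) -> None:
    matrix.data.to_csv(Path(path), sep="\t", index_label="feature_id")


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a two-column chrom-sizes TSV into a GenomeModel."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
        chroms.append((fields[0], length))
    try:
        return GenomeModel(tuple(chroms))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_bed_regions(path: str | Path, genome: GenomeModel) -> RegionSet:
    """Read BED3/BED4 regions, validating against genome bounds.

    Ids come from column 4 when present, else ``region_<n>`` (1-based line
    order among region lines).
    """
    path = Path(path)
    lengths = genome.lengths
    regions: list[Region] = []
    n = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if chrom not in lengths:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if end > lengths[chrom]:
            raise ParseError(
                f"{path}:{lineno}: end {end} beyond {chrom} length {lengths[chrom]}"
            )
        n += 1
        rid = fields[3] if len(fields) >= 4 and fields[3] else f"region_{n}"
        regions.append(Region(chrom, start, end, rid))
    try:
        return RegionSet(regions, genome)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def read_gmt_genesets(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets (name, description, symbols...), one set per line.

    Duplicate symbols within a line are dropped with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
        name = fields[0]
        seen: dict[str, None] = {}
        for sym in fields[2:]:
            if not sym:
                continue
            if sym in seen:
                logger.warning("%s:%d: duplicate symbol %r in set %r dropped",
                               path, lineno, sym, name)
            seen[sym] = None
        sets.append(GeneSet(name, tuple(seen)))
    return sets


def write_gmt_genesets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def read_stage_map(path: str | Path) -> StageMap:
    """Read a two-column sample -> stage TSV; stage order = first appearance."""
    path = Path(path)
    assignment: dict[str, str] = {}
    stages: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        sample, stage = fields[0], fields[1]
        if sample in assignment:
            raise ParseError(f"{path}:{lineno}: duplicate sample {sample!r}")
        assignment[sample] = stage
        if stage not in stages:
            stages.append(stage)
    return StageMap(tuple(stages), assignment)


def write_stage_map(stage_map: StageMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for stage in stage_map.stages:
            for sample in stage_map.samples_for(stage):
                fh.write(f"{sample}\t{stage}\n")
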
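"""Interval algebra and positional annotation on a two-subgenome genome.

All coordinates are 0-based half-open (BED convention). Chromosome names
carry the subgenome as their leading letter (``A01``, ``C03``); a mapping
table can override this for nonstandard naming.

Accessible regions, methylation bins and sRNA clusters are classified
relative to gene bodies as *genic* (any overlap), *proximal* (within a
flanking window, 2 kb by default) or *distal* (farther than the window
from every gene), with precedence genic > proximal > distal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class PositionalClass(enum.Enum):
    """Location of a region relative to annotated gene bodies."""

    GENIC = "genic"
    PROXIMAL = "proximal"
    DISTAL = "distal"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def subgenome(self) -> str:
        return subgenome_of(self.chrom)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """bp gap between intervals; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


# Chromosome -> subgenome override table (module-level, set by config loading).
_SUBGENOME_OVERRIDES: dict[str, str] = {}


def set_subgenome_overrides(mapping: dict[str, str]) -> None:
    """Register explicit chromosome->subgenome assignments for nonstandard names."""
    for chrom, sg in mapping.items():
        if sg not in ("A", "C"):
            raise ValueError(f"subgenome must be A or C, got {sg!r} for {chrom!r}")
    _SUBGENOME_OVERRIDES.clear()
    _SUBGENOME_OVERRIDES.update(mapping)


def subgenome_of(chrom: str) -> str:
    """Subgenome (A or C) of a chromosome, from override table or name prefix."""
    if chrom in _SUBGENOME_OVERRIDES:
        return _SUBGENOME_OVERRIDES[chrom]
    prefix = chrom[0].upper()
    if prefix in ("A", "C"):
        return prefix
    raise ValueError(
        f"cannot derive subgenome from chromosome {chrom!r}; "
        "register it with set_subgenome_overrides()"
    )


@dataclass
class GeneModel:
    """A gene body with optional cross-subgenome homolog partner."""

    gene_id: str
    interval: GenomicInterval
    subgenome: str = ""
    homolog_partner: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.subgenome:
            self.subgenome = self.interval.subgenome
        if self.subgenome not in ("A", "C"):
            raise ValueError(f"subgenome must be A or C, got {self.subgenome!r}")


@dataclass(frozen=True)
class TEFeature:
    """A transposable-element annotation."""

    interval: GenomicInterval
    te_class: str = "unknown"


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of (start, end) pairs on one chromosome as sorted disjoint runs."""
    runs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def overlap_fraction(region: GenomicInterval, features: Iterable[TEFeature]) -> float:
    """Fraction of ``region`` covered by the union of feature intervals.

    Overlapping features are unioned before measuring so no base is counted
    twice; a region more than half covered by transposons is TE-driven under
    the downstream (strict >) threshold rule.
    """
    clipped = []
    for f in features:
        iv = f.interval
        if iv.chrom != region.chrom:
            continue
        s, e = max(iv.start, region.start), min(iv.end, region.end)
        if e > s:
            clipped.append((s, e))
    if not clipped:
        return 0.0
    covered = sum(e - s for s, e in merge_intervals(clipped))
    return covered / region.length


def classify_position(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    window_bp: int = 2000,
) -> PositionalClass:
    """Classify a region as genic, proximal or distal relative to gene bodies.

    genic: overlaps any gene body by >=1 bp; proximal: within ``window_bp``
    of a gene-body boundary (strand-agnostic, upstream or downstream);
    distal: otherwise. Precedence genic > proximal > distal.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    proximal = False
    for g in genes:
        d = region.distance_to(g.interval)
        if d is None:
            continue
        if d == 0:
            return PositionalClass.GENIC
        if d <= window_bp:
            proximal = True
    return PositionalClass.PROXIMAL if proximal else PositionalClass.DISTAL


def nearest_gene(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> Optional[tuple[str, int]]:
    """Closest gene on the region's chromosome and its bp gap (0 if overlapping).

    Ties break by smaller gene start, then lexicographic gene_id. Returns
    None ("unassignable") when the chromosome carries no gene.
    """
    best: Optional[tuple[int, int, str]] = None  # (distance, start, gene_id)
    for g in genes:
        d = region.distance_to(g.interval)
        if d is None:
            continue
        key = (d, g.interval.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


@dataclass
class GeneIndex:
    """Per-chromosome sorted gene lookup used by the pipeline stages."""

    genes: Sequence[GeneModel]
    by_chrom: dict[str, list[GeneModel]] = field(init=False)

    def __post_init__(self) -> None:
        self.by_chrom = {}
        for g in self.genes:
            self.by_chrom.setdefault(g.interval.chrom, []).append(g)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda g: (g.interval.start, g.gene_id))

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return self.by_chrom.get(chrom, [])

    def classify(self, region: GenomicInterval, window_bp: int = 2000) -> PositionalClass:
        return classify_position(region, self.on_chrom(region.chrom), window_bp)

    def nearest(self, region: GenomicInterval) -> Optional[tuple[str, int]]:
        return nearest_gene(region, self.on_chrom(region.chrom))
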
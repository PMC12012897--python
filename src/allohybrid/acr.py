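"""Accessible chromatin region (ACR) construction and categorization.

Replicate ATAC peaks are merged into consensus ACRs when peaks from enough
replicates mutually overlap by strictly more than 50 bp. Consensus regions
are then categorized across samples:

* novel / silent — present (reads >= 5 in every replicate) on one side of
  the cross and exactly zero on the other; novel means hybrid-only, silent
  means parent-only. Zeros are structural (raw counts), so a normalized
  near-zero never qualifies.
* SPA-M / SPA-P — single-parent activation: detected in one parent plus the
  hybrid, absent in the other parent. Only defined on the A subgenome since
  the paternal line (AA) carries no C subgenome.
* TE-driven — more than half of the region covered by transposon
  annotation (strict > 0.5 by default).
* DE-up / DE-down — differential accessibility by the NB count test with
  BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneIndex,
    GenomicInterval,
    PositionalClass,
    TEFeature,
    merge_intervals,
    overlap_fraction,
    subgenome_of,
)
from .stats import bh_adjust, nb_test_matrix, spearman

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Peaks of one ATAC replicate: (interval, read count) pairs.

    Overlapping peaks within a replicate are unioned (counts summed) at
    construction so downstream merging sees disjoint intervals.
    """

    sample: str
    replicate_id: str
    peaks: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = self._validated(self.peaks)

    @staticmethod
    def _validated(
        peaks: Sequence[tuple[GenomicInterval, float]]
    ) -> list[tuple[GenomicInterval, float]]:
        by_chrom: dict[str, list[tuple[GenomicInterval, float]]] = {}
        for iv, count in peaks:
            by_chrom.setdefault(iv.chrom, []).append((iv, count))
        out: list[tuple[GenomicInterval, float]] = []
        for chrom, items in sorted(by_chrom.items()):
            items.sort(key=lambda t: t[0].start)
            cur_s, cur_e, cur_c = None, None, 0.0
            for iv, count in items:
                if cur_s is None or iv.start >= cur_e:
                    if cur_s is not None:
                        out.append((GenomicInterval(chrom, cur_s, cur_e), cur_c))
                    cur_s, cur_e, cur_c = iv.start, iv.end, count
                else:  # overlap within replicate: union and pool reads
                    cur_e = max(cur_e, iv.end)
                    cur_c += count
            if cur_s is not None:
                out.append((GenomicInterval(chrom, cur_s, cur_e), cur_c))
        return out


@dataclass
class ACRRecord:
    """A consensus accessible region with per-replicate read support."""

    interval: GenomicInterval
    sample: str
    replicate_reads: np.ndarray
    mean_reads: float = 0.0
    positional: Optional[PositionalClass] = None
    te_fraction: float = 0.0
    labels: set[str] = field(default_factory=set)
    target_gene: Optional[str] = None
    gene_linked: bool = False

    def __post_init__(self) -> None:
        self.replicate_reads = np.asarray(self.replicate_reads, dtype=float)
        if self.mean_reads == 0.0:
            self.mean_reads = float(self.replicate_reads.mean()) if self.replicate_reads.size else 0.0


def _mutual_clique_exists(
    peaks: list[tuple[int, GenomicInterval]],
    n_replicates_needed: int,
    min_overlap_bp: int,
) -> bool:
    """True if one peak per replicate from >= n replicates pairwise overlap
    by strictly more than min_overlap_bp."""
    by_rep: dict[int, list[GenomicInterval]] = {}
    for rep, iv in peaks:
        by_rep.setdefault(rep, []).append(iv)
    reps = sorted(by_rep)
    if len(reps) < n_replicates_needed:
        return False
    from itertools import combinations, product

    for combo in combinations(reps, n_replicates_needed):
        for choice in product(*(by_rep[r] for r in combo)):
            ok = all(
                a.overlap_len(b) > min_overlap_bp
                for i, a in enumerate(choice)
                for b in choice[i + 1 :]
            )
            if ok:
                return True
    return False


def merge_replicate_peaks(
    replicates: Sequence[PeakSet],
    min_overlap_bp: int = 50,
    min_replicates: int = 2,
) -> list[ACRRecord]:
    """Merge one sample's replicate peaks into consensus ACRs.

    A location becomes an ACR when peaks from at least ``min_replicates``
    replicates mutually overlap with pairwise overlaps strictly greater
    than ``min_overlap_bp``; the ACR interval is the union of the connected
    peaks and per-replicate read counts are attached (0 for a replicate
    without a supporting peak).
    """
    if len(replicates) < 2:
        raise ValueError(
            "need >= 2 replicates; for single-replicate data use the peaks directly"
        )
    sample = replicates[0].sample
    n_rep = len(replicates)
    # Pool peaks tagged by replicate index, per chromosome.
    by_chrom: dict[str, list[tuple[int, GenomicInterval, float]]] = {}
    for ri, ps in enumerate(replicates):
        for iv, count in ps.peaks:
            by_chrom.setdefault(iv.chrom, []).append((ri, iv, count))

    out: list[ACRRecord] = []
    for chrom, items in sorted(by_chrom.items()):
        items.sort(key=lambda t: (t[1].start, t[1].end))
        n = len(items)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # connect peaks overlapping by strictly more than min_overlap_bp
        for i in range(n):
            for j in range(i + 1, n):
                if items[j][1].start >= items[i][1].end:
                    break
                if items[i][1].overlap_len(items[j][1]) > min_overlap_bp:
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            peaks = [(items[i][0], items[i][1]) for i in members]
            if not _mutual_clique_exists(peaks, min_replicates, min_overlap_bp):
                continue
            start = min(items[i][1].start for i in members)
            end = max(items[i][1].end for i in members)
            reads = np.zeros(n_rep)
            for i in members:
                reads[items[i][0]] += items[i][2]
            out.append(ACRRecord(GenomicInterval(chrom, start, end), sample, reads))
    out.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    return out


def quantify_peaks_in_region(
    region: GenomicInterval, peakset: PeakSet
) -> float:
    """Total read count of a replicate's peaks overlapping a region."""
    return sum(
        count for iv, count in peakset.peaks if iv.overlaps(region)
    )


def consensus_regions(
    acrs_by_sample: dict[str, list[ACRRecord]]
) -> list[GenomicInterval]:
    """Cross-sample master ACR list: union-merge of all samples' ACRs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for acrs in acrs_by_sample.values():
        for a in acrs:
            by_chrom.setdefault(a.interval.chrom, []).append(
                (a.interval.start, a.interval.end)
            )
    out = [
        GenomicInterval(chrom, s, e)
        for chrom, runs in sorted(by_chrom.items())
        for s, e in merge_intervals(runs)
    ]
    return out


def call_novel_silent(
    acr_reads_hybrid: Sequence[float],
    acr_reads_parents: Sequence[Sequence[float]],
    min_reads: float = 5,
) -> str:
    """'novel' (hybrid-only), 'silent' (parent-only) or 'neither'.

    Presence requires every replicate at or above ``min_reads``; absence
    requires exact zeros in every replicate of the other side.
    """
    if not acr_reads_parents:
        raise ValueError("at least one parent sample is required")
    h = np.asarray(acr_reads_hybrid, dtype=float)
    parents = [np.asarray(p, dtype=float) for p in acr_reads_parents]
    parents_all = np.concatenate(parents)
    if np.all(h >= min_reads) and np.all(parents_all == 0):
        return "novel"
    if np.all(h == 0) and np.all(parents_all >= min_reads):
        return "silent"
    return "neither"


def call_spa(
    maternal_reads: Sequence[float],
    paternal_reads: Sequence[float],
    hybrid_reads: Sequence[float],
    subgenome: str,
    min_reads: float = 5,
) -> str:
    """Single-parent-activation call for one A-subgenome region.

    'SPA-M': present in maternal and hybrid, absent in paternal;
    'SPA-P': the mirror; 'shared': present in both parents;
    'absent-informative': anything else. C-subgenome input is rejected —
    the paternal AA line has no C subgenome, so absence there carries no
    information.
    """
    if subgenome == "C":
        raise ValueError(
            "SPA calls are undefined on the C subgenome: the paternal AA parent "
            "is structurally missing it; restrict the analysis to A-subgenome peaks"
        )
    m = np.asarray(maternal_reads, dtype=float)
    p = np.asarray(paternal_reads, dtype=float)
    h = np.asarray(hybrid_reads, dtype=float)

    def present(x: np.ndarray) -> bool:
        return bool(np.all(x >= min_reads))

    def absent(x: np.ndarray) -> bool:
        return bool(np.all(x == 0))

    if present(m) and present(p):
        return "shared"
    if present(m) and absent(p) and present(h):
        return "SPA-M"
    if absent(m) and present(p) and present(h):
        return "SPA-P"
    return "absent-informative"


def label_te_driven(
    acr: ACRRecord, tes: Iterable[TEFeature], threshold: float = 0.5
) -> bool:
    """True when strictly more than ``threshold`` of the ACR overlaps TEs."""
    acr.te_fraction = overlap_fraction(acr.interval, tes)
    driven = acr.te_fraction > threshold
    if driven:
        acr.labels.add("TE-driven")
    else:
        acr.labels.discard("TE-driven")
    return driven


def differential_accessibility(
    region_ids: Sequence[str],
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    size_factors_a: Optional[np.ndarray] = None,
    size_factors_b: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-ACR NB test with BH adjustment and DE-up / DE-down labels.

    The fold change is sample B over sample A; DE-up means more accessible
    in B. Regions with zero counts everywhere are excluded (logged).
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    ids = np.asarray(region_ids)
    nonzero = (A.sum(axis=1) + B.sum(axis=1)) > 0
    if (~nonzero).any():
        logger.info("excluding %d zero-count region(s)", int((~nonzero).sum()))
    lfc, p = nb_test_matrix(A[nonzero], B[nonzero], size_factors_a, size_factors_b)
    padj = bh_adjust(p)
    label = np.where(
        (padj < alpha) & (np.abs(lfc) >= lfc_threshold),
        np.where(lfc > 0, "DE-up", "DE-down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "region": ids[nonzero],
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": padj,
            "label": label,
        }
    ).set_index("region")


def link_acr_to_genes(
    acrs: Sequence[ACRRecord], gene_index: GeneIndex, window_bp: int = 2000
) -> None:
    """Attach positional class and target gene to each ACR in place.

    genic -> the overlapped gene; proximal -> nearest gene (within the
    window by construction); distal -> nearest gene recorded but flagged
    unlinked.
    """
    for acr in acrs:
        acr.positional = gene_index.classify(acr.interval, window_bp)
        hit = gene_index.nearest(acr.interval)
        if hit is None:
            acr.target_gene, acr.gene_linked = None, False
            continue
        gene_id, dist = hit
        acr.target_gene = gene_id
        acr.gene_linked = acr.positional in (
            PositionalClass.GENIC,
            PositionalClass.PROXIMAL,
        )


def tss_window_accessibility(
    acrs: Sequence[ACRRecord],
    gene_index: GeneIndex,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> pd.DataFrame:
    """Per-gene summed ACR read support and nearest-ACR distance at the TSS.

    The TSS window runs ``upstream_bp`` before to ``downstream_bp`` after
    the transcription start (strand-aware; strandless genes use the left
    boundary).
    """
    acr_by_chrom: dict[str, list[ACRRecord]] = {}
    for a in acrs:
        acr_by_chrom.setdefault(a.interval.chrom, []).append(a)
    rows = []
    for chrom, genes in gene_index.by_chrom.items():
        chrom_acrs = acr_by_chrom.get(chrom, [])
        for g in genes:
            if g.interval.strand == "-":
                tss = g.interval.end
                win = GenomicInterval(chrom, max(0, tss - downstream_bp), tss + upstream_bp)
            else:
                tss = g.interval.start
                win = GenomicInterval(chrom, max(0, tss - upstream_bp), tss + downstream_bp)
            intensity = 0.0
            tss_point = GenomicInterval(chrom, max(0, tss), max(0, tss) + 1)
            dist = None
            for a in chrom_acrs:
                if a.interval.overlaps(win):
                    intensity += a.mean_reads
                d = a.interval.distance_to(tss_point)
                if d is not None and (dist is None or d < dist):
                    dist = d
            rows.append((g.gene_id, intensity, dist))
    return pd.DataFrame(rows, columns=["gene_id", "tss_intensity", "tss_distance"]).set_index(
        "gene_id"
    )


def accessibility_expression_correlation(
    tss_intensity: Sequence[float],
    tss_distance: Sequence[float],
    expression: Sequence[float],
):
    """Spearman correlations of TSS accessibility and TSS distance against
    log-scaled expression. Returns (intensity_result, distance_result)."""
    expr = np.log1p(np.asarray(expression, dtype=float))
    if expr.size < 10:
        raise ValueError("need >= 10 genes with both measurements")
    return (
        spearman(np.asarray(tss_intensity, dtype=float), expr),
        spearman(np.asarray(tss_distance, dtype=float), expr),
    )


def region_subgenome(region: GenomicInterval) -> str:
    return subgenome_of(region.chrom)
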
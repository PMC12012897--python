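"""WGBS methylation and small-RNA layer.

Methylation calls arrive as per-cytosine counts (chrom, pos, strand,
context, methylated, unmethylated) in the three plant contexts CG, CHG and
CHH. Levels are always *weighted*: pooled methylated reads over pooled
total reads, never a mean of per-site ratios. Differential methylation is
tested in fixed 200-bp bins (Fisher's exact test on pooled counts, BH per
context) and a bin is a DMR only when its level difference also clears the
context threshold — 0.3 (CG), 0.2 (CHG), 0.1 (CHH).

The in-silico hybrid methylome mixes the parents 1:1 after scaling both to
equal coverage; C-subgenome positions carry maternal counts only because
the paternal AA line has no C subgenome.

sRNA reads (18-30 nt) are grouped into clusters by positional proximity
and quantified as reads per million total clean reads (RPM); hyper-/hypo-
DMR bins are tested for sRNA accumulation shifts between the hybrid and
the in-silico mixture with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneIndex, GenomicInterval, PositionalClass, subgenome_of
from .stats import bh_adjust, fisher_exact_many, rank_tests

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
DMR_DELTA = {"CG": 0.3, "CHG": 0.2, "CHH": 0.1}
ACR_METH_THRESHOLDS = {"CG": 0.1, "CHG": 0.1, "CHH": 0.05}


def weighted_methylation(
    calls: pd.DataFrame,
    region: Optional[GenomicInterval] = None,
    context: Optional[str] = None,
    min_coverage: int = 5,
) -> Optional[float]:
    """Weighted methylation level over qualifying sites, or None if none.

    Pooled counts: sum(methylated) / sum(total) across sites of ``context``
    inside ``region`` whose coverage is at least ``min_coverage``.
    """
    sub = calls
    if region is not None:
        sub = sub[
            (sub["chrom"] == region.chrom)
            & (sub["pos"] >= region.start)
            & (sub["pos"] < region.end)
        ]
    if context is not None:
        sub = sub[sub["context"] == context]
    total = sub["meth"] + sub["unmeth"]
    sub = sub[total >= min_coverage]
    if sub.empty:
        return None
    pooled_total = float((sub["meth"] + sub["unmeth"]).sum())
    return float(sub["meth"].sum()) / pooled_total


def build_insilico_methylome(
    maternal_calls: pd.DataFrame, paternal_calls: pd.DataFrame
) -> pd.DataFrame:
    """1:1 in-silico hybrid methylome from the two parents.

    At positions shared by both parents each parent is scaled to their mean
    coverage before summing, so neither parent dominates by depth.
    Positions seen in only one parent (all C-subgenome positions in
    particular) pass through unchanged. Counts are rounded back to
    integers.
    """
    keys = ["chrom", "pos", "strand", "context"]
    merged = maternal_calls.merge(
        paternal_calls, on=keys, how="outer", suffixes=("_m", "_p")
    )
    tm = merged["meth_m"].fillna(0) + merged["unmeth_m"].fillna(0)
    tp = merged["meth_p"].fillna(0) + merged["unmeth_p"].fillna(0)
    shared = merged["meth_m"].notna() & merged["meth_p"].notna() & (tm > 0) & (tp > 0)
    target = (tm + tp) / 2.0
    meth = np.where(
        shared,
        merged["meth_m"].fillna(0) * target / tm.replace(0, np.nan)
        + merged["meth_p"].fillna(0) * target / tp.replace(0, np.nan),
        merged["meth_m"].fillna(merged["meth_p"]),
    )
    unmeth = np.where(
        shared,
        merged["unmeth_m"].fillna(0) * target / tm.replace(0, np.nan)
        + merged["unmeth_p"].fillna(0) * target / tp.replace(0, np.nan),
        merged["unmeth_m"].fillna(merged["unmeth_p"]),
    )
    out = merged[keys].copy()
    out["meth"] = np.rint(np.nan_to_num(meth)).astype(np.int64)
    out["unmeth"] = np.rint(np.nan_to_num(unmeth)).astype(np.int64)
    return out.sort_values(["chrom", "pos", "context"]).reset_index(drop=True)


def bin_methylation(
    calls: pd.DataFrame,
    bin_size: int = 200,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Pool per-cytosine counts into fixed non-overlapping bins per context.

    Sites under ``min_coverage`` are dropped before pooling. Returns one
    row per (chrom, bin_start, context) with pooled counts, the number of
    qualifying sites and the weighted level.
    """
    total = calls["meth"] + calls["unmeth"]
    sub = calls[total >= min_coverage].copy()
    sub["bin_start"] = (sub["pos"] // bin_size) * bin_size
    grouped = (
        sub.groupby(["chrom", "bin_start", "context"], sort=True)
        .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"), n_sites=("pos", "size"))
        .reset_index()
    )
    grouped["level"] = grouped["meth"] / (grouped["meth"] + grouped["unmeth"])
    grouped["bin_end"] = grouped["bin_start"] + bin_size
    return grouped


def call_dmrs(
    bins1: pd.DataFrame,
    bins2: pd.DataFrame,
    context: Optional[str] = None,
    delta_thresholds: Optional[dict[str, float]] = None,
    alpha: float = 0.05,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Differential methylation over shared bins of two samples.

    Tests every bin covered by >= ``min_sites`` qualifying cytosines in
    both samples with a two-sided Fisher exact test on pooled counts; BH
    adjustment runs separately per context. A bin is a DMR when the
    adjusted p is below ``alpha`` *and* |level1 - level2| strictly exceeds
    the context delta (0.3/0.2/0.1 for CG/CHG/CHH). Direction 'hyper'
    means sample 1 above sample 2, so swapping the samples flips every
    direction.
    """
    deltas = dict(DMR_DELTA if delta_thresholds is None else delta_thresholds)
    keys = ["chrom", "bin_start", "context"]
    merged = bins1.merge(bins2, on=keys, suffixes=("_1", "_2"))
    if "bin_end_1" in merged.columns:
        merged["bin_end"] = merged["bin_end_1"]
        merged = merged.drop(columns=["bin_end_1", "bin_end_2"])
    if context is not None:
        merged = merged[merged["context"] == context]
    unknown = set(merged["context"].unique()) - set(deltas)
    if unknown:
        raise ValueError(f"no delta threshold for context(s) {sorted(unknown)}")
    merged = merged[
        (merged["n_sites_1"] >= min_sites) & (merged["n_sites_2"] >= min_sites)
    ].reset_index(drop=True)
    if merged.empty:
        return merged.assign(
            delta=[], p_value=[], adjusted_p=[], is_dmr=[], direction=[]
        )
    merged["delta"] = merged["level_1"] - merged["level_2"]
    merged["p_value"] = fisher_exact_many(
        merged["meth_1"].values,
        merged["unmeth_1"].values,
        merged["meth_2"].values,
        merged["unmeth_2"].values,
    )
    merged["adjusted_p"] = 1.0
    for ctx, idx in merged.groupby("context").groups.items():
        merged.loc[idx, "adjusted_p"] = bh_adjust(merged.loc[idx, "p_value"].values)
    thr = merged["context"].map(deltas)
    merged["is_dmr"] = (merged["adjusted_p"] < alpha) & (merged["delta"].abs() > thr)
    merged["direction"] = np.where(merged["delta"] > 0, "hyper", "hypo")
    merged.loc[~merged["is_dmr"], "direction"] = ""
    return merged


def call_dmls(
    calls1: pd.DataFrame,
    calls2: pd.DataFrame,
    alpha: float = 0.05,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Per-cytosine differential methylation (DMLs).

    Only sites covered >= ``min_coverage`` in both samples are tested;
    Fisher exact + BH per context; significant sites are labeled hyper
    (sample 1 higher) or hypo.
    """
    keys = ["chrom", "pos", "strand", "context"]
    merged = calls1.merge(calls2, on=keys, suffixes=("_1", "_2"))
    t1 = merged["meth_1"] + merged["unmeth_1"]
    t2 = merged["meth_2"] + merged["unmeth_2"]
    merged = merged[(t1 >= min_coverage) & (t2 >= min_coverage)].reset_index(drop=True)
    if merged.empty:
        return merged.assign(p_value=[], adjusted_p=[], is_dml=[], direction=[])
    merged["level_1"] = merged["meth_1"] / (merged["meth_1"] + merged["unmeth_1"])
    merged["level_2"] = merged["meth_2"] / (merged["meth_2"] + merged["unmeth_2"])
    merged["p_value"] = fisher_exact_many(
        merged["meth_1"].values,
        merged["unmeth_1"].values,
        merged["meth_2"].values,
        merged["unmeth_2"].values,
    )
    merged["adjusted_p"] = 1.0
    for ctx, idx in merged.groupby("context").groups.items():
        merged.loc[idx, "adjusted_p"] = bh_adjust(merged.loc[idx, "p_value"].values)
    merged["is_dml"] = merged["adjusted_p"] < alpha
    merged["direction"] = np.where(merged["level_1"] > merged["level_2"], "hyper", "hypo")
    merged.loc[~merged["is_dml"], "direction"] = ""
    return merged


def classify_dmr_targets(
    dmrs: pd.DataFrame, gene_index: GeneIndex, window_bp: int = 2000
) -> pd.DataFrame:
    """Positional class and differentially methylated gene (DMG) per DMR.

    genic DMRs target the overlapped gene, proximal ones the nearest gene;
    distal DMRs get no DMG.
    """
    positions, targets = [], []
    for _, row in dmrs.iterrows():
        iv = GenomicInterval(row["chrom"], int(row["bin_start"]), int(row["bin_end"]))
        pos = gene_index.classify(iv, window_bp)
        positions.append(str(pos))
        if pos in (PositionalClass.GENIC, PositionalClass.PROXIMAL):
            hit = gene_index.nearest(iv)
            targets.append(hit[0] if hit else "")
        else:
            targets.append("")
    out = dmrs.copy()
    out["positional"] = positions
    out["target_gene"] = targets
    return out


def acr_methylation_status(
    region: GenomicInterval,
    calls: pd.DataFrame,
    thresholds: Optional[dict[str, float]] = None,
    min_coverage: int = 5,
) -> str:
    """'unmethylated' when every covered context sits below its threshold,
    'methylated' when any reaches it, 'undefined' with no covered site."""
    thr = dict(ACR_METH_THRESHOLDS if thresholds is None else thresholds)
    levels = {
        ctx: weighted_methylation(calls, region, ctx, min_coverage) for ctx in CONTEXTS
    }
    defined = {ctx: lv for ctx, lv in levels.items() if lv is not None}
    if not defined:
        return "undefined"
    if any(lv >= thr[ctx] for ctx, lv in defined.items()):
        return "methylated"
    return "unmethylated"


def cluster_srna(
    reads: pd.DataFrame,
    min_len: int = 18,
    max_len: int = 30,
    max_gap: int = 75,
    min_reads: int = 5,
    total_reads: Optional[int] = None,
) -> pd.DataFrame:
    """Group length-filtered sRNA reads into positional clusters.

    Reads outside [min_len, max_len] nt are discarded; remaining reads less
    than ``max_gap`` bp apart merge into maximal clusters; clusters with
    fewer than ``min_reads`` members are dropped. RPM is relative to
    ``total_reads`` (the sample's total clean reads; defaults to the input
    read count).
    """
    if total_reads is None:
        total_reads = len(reads)
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    kept = reads[(reads["length"] >= min_len) & (reads["length"] <= max_len)]
    kept = kept.sort_values(["chrom", "start", "end"])
    rows = []
    cur = None  # [chrom, start, end, count, lengths]
    for chrom, start, end, length in kept[["chrom", "start", "end", "length"]].itertuples(
        index=False
    ):
        if cur is not None and chrom == cur[0] and start - cur[2] <= max_gap:
            cur[2] = max(cur[2], end)
            cur[3] += 1
            cur[4].append(length)
        else:
            if cur is not None:
                rows.append(cur)
            cur = [chrom, start, end, 1, [length]]
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(
        [
            (c, s, e, n, 1e6 * n / total_reads, int(pd.Series(ls).mode().iloc[0]))
            for c, s, e, n, ls in rows
            if n >= min_reads
        ],
        columns=["chrom", "start", "end", "read_count", "rpm", "dominant_length"],
    )
    return out


def _rpm_per_region(
    regions: pd.DataFrame, clusters: pd.DataFrame
) -> np.ndarray:
    """Summed cluster RPM overlapping each (chrom, bin_start, bin_end) row."""
    rpm = np.zeros(len(regions))
    by_chrom = {c: g for c, g in clusters.groupby("chrom")}
    for i, (_, row) in enumerate(regions.iterrows()):
        g = by_chrom.get(row["chrom"])
        if g is None:
            continue
        hit = (g["start"] < row["bin_end"]) & (g["end"] > row["bin_start"])
        rpm[i] = g.loc[hit, "rpm"].sum()
    return rpm


def dmr_srna_enrichment(
    dmrs: pd.DataFrame,
    clusters_hybrid: pd.DataFrame,
    clusters_insilico: pd.DataFrame,
    min_regions: int = 3,
) -> dict[str, dict]:
    """Wilcoxon rank-sum of per-DMR sRNA RPM, hybrid vs in-silico, by direction.

    Returns for each direction present ('hyper', 'hypo') the p-value, the
    median RPM of both samples, which side is higher, and an underpowered
    flag when fewer than ``min_regions`` DMRs carry that direction.
    """
    results: dict[str, dict] = {}
    for direction in ("hyper", "hypo"):
        sub = dmrs[dmrs["direction"] == direction]
        if len(sub) < min_regions:
            results[direction] = {
                "p_value": float("nan"),
                "n": len(sub),
                "underpowered": True,
                "median_hybrid": float("nan"),
                "median_insilico": float("nan"),
                "higher_in": "",
            }
            continue
        rpm_h = _rpm_per_region(sub, clusters_hybrid)
        rpm_i = _rpm_per_region(sub, clusters_insilico)
        res = rank_tests([rpm_h, rpm_i])
        med_h, med_i = float(np.median(rpm_h)), float(np.median(rpm_i))
        results[direction] = {
            "p_value": res.p_value,
            "n": len(sub),
            "underpowered": False,
            "median_hybrid": med_h,
            "median_insilico": med_i,
            "higher_in": "insilico" if med_i > med_h else ("hybrid" if med_h > med_i else "tie"),
        }
    return results


def methylome_subgenome(calls: pd.DataFrame) -> pd.Series:
    return calls["chrom"].map(subgenome_of)
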
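"""Configuration-driven end-to-end orchestration of all analysis stages.

``run_pipeline`` executes annotation -> ACR -> expression -> methylation ->
sRNA -> integration on an on-disk dataset (real post-alignment summaries or
the output of the synthetic generator), writes TSV/BED/JSON results, and
returns a machine-readable summary. Stages are independently skippable;
reruns on identical inputs are byte-identical.

Every threshold defaults to the published value (2-kb window, >50 bp
overlap, reads >= 5, FPKM > 1, |log2FC| 1.5 / 2, R^2 > 0.64, methylation
deltas 0.3/0.2/0.1 in 200-bp bins, TE fraction 0.5, k = 9 clusters), so a
bare run reproduces the published rule set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import acr as A
from . import expression as E
from . import io as aio
from . import methylation as M
from .intervals import GeneIndex, GenomicInterval
from .stats import fuzzy_cmeans, rank_tests

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the published values."""

    indir: str = "."
    outdir: str = "results"
    seed: int = 0

    window_bp: int = 2000
    min_overlap_bp: int = 50
    min_replicates: int = 2
    min_reads: float = 5.0
    te_threshold: float = 0.5
    lfc_acr: float = 1.0
    cmeans_k: int = 9
    cmeans_m: float = 2.0

    fpkm_expressed: float = 1.0
    spe_silent: float = 0.1
    lfc_additive: float = 1.5
    lfc_deg: float = 2.0
    r2_threshold: float = 0.64
    alpha: float = 0.05
    dosage_per_genotype: bool = False

    meth_min_coverage: int = 5
    meth_bin_size: int = 200
    meth_min_sites: int = 3
    dmr_deltas: dict = field(default_factory=lambda: dict(M.DMR_DELTA))
    acr_meth_thresholds: dict = field(default_factory=lambda: dict(M.ACR_METH_THRESHOLDS))

    srna_min_len: int = 18
    srna_max_len: int = 30
    srna_max_gap: int = 75
    srna_min_reads: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known - {"simulate"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_annotation(indir: Path):
    genes = aio.read_gff3_genes(indir / "genes.gff3")
    tes = aio.read_te_bed(indir / "tes.bed") if (indir / "tes.bed").exists() else []
    pairs_path = indir / "homologs.tsv"
    pairs = aio.read_homolog_pairs(pairs_path) if pairs_path.exists() else []
    return genes, tes, pairs


def _acr_stage(config: PipelineConfig, indir: Path, outdir: Path, genes, tes) -> dict:
    """Consensus ACR construction, categorization and clustering."""
    peak_dir = indir / "peaks"
    peaksets: dict[str, list[A.PeakSet]] = {}
    for sample in ("maternal", "paternal", "hybrid"):
        files = sorted(peak_dir.glob(f"{sample}_rep*.bed"))
        if files:
            peaksets[sample] = [
                A.PeakSet(sample, f.stem.split("_")[-1], aio.read_peak_bed(f)) for f in files
            ]
    if not peaksets:
        return {}
    gene_index = GeneIndex(genes)
    acrs_by_sample = {
        s: A.merge_replicate_peaks(ps, config.min_overlap_bp, config.min_replicates)
        for s, ps in peaksets.items()
    }
    master = A.consensus_regions(acrs_by_sample)

    rows = []
    profiles = []
    for region in master:
        reads = {
            s: np.array([A.quantify_peaks_in_region(region, ps) for ps in peaksets[s]])
            for s in peaksets
        }
        rec = A.ACRRecord(region, "consensus", reads["hybrid"])
        A.link_acr_to_genes([rec], gene_index, config.window_bp)
        A.label_te_driven(rec, tes, config.te_threshold)
        h, m_, p = reads["hybrid"], reads["maternal"], reads["paternal"]
        ns = A.call_novel_silent(h, [m_, p], config.min_reads)
        spa = ""
        if region.subgenome == "A":
            spa_call = A.call_spa(m_, p, h, "A", config.min_reads)
            spa = spa_call if spa_call.startswith("SPA") else ""
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "subgenome": region.subgenome,
                "positional": str(rec.positional),
                "target_gene": rec.target_gene or "",
                "gene_linked": rec.gene_linked,
                "te_fraction": round(rec.te_fraction, 4),
                "te_driven": rec.te_fraction > config.te_threshold,
                "novel_silent": ns if ns != "neither" else "",
                "spa": spa,
                "mean_maternal": m_.mean(),
                "mean_paternal": p.mean(),
                "mean_hybrid": h.mean(),
            }
        )
        profiles.append([m_.mean(), p.mean(), h.mean()])

    acr_df = pd.DataFrame(rows)
    profiles = np.asarray(profiles)
    if len(acr_df) >= config.cmeans_k:
        clustering = fuzzy_cmeans(
            profiles, k=config.cmeans_k, m=config.cmeans_m, seed=config.seed
        )
        labels = np.full(len(acr_df), "", dtype=object)
        labels[clustering.kept_rows] = clustering.labels
        acr_df["cmeans_cluster"] = labels
    else:
        acr_df["cmeans_cluster"] = ""

    # differential accessibility hybrid vs maternal (the AACC reference parent)
    ids = acr_df["chrom"] + ":" + acr_df["start"].astype(str) + "-" + acr_df["end"].astype(str)
    counts_m = np.array(
        [
            [A.quantify_peaks_in_region(GenomicInterval(r.chrom, r.start, r.end), ps) for ps in peaksets["maternal"]]
            for r in acr_df.itertuples()
        ]
    )
    counts_h = np.array(
        [
            [A.quantify_peaks_in_region(GenomicInterval(r.chrom, r.start, r.end), ps) for ps in peaksets["hybrid"]]
            for r in acr_df.itertuples()
        ]
    )
    de = A.differential_accessibility(
        ids.values, counts_m, counts_h, config.lfc_acr, config.alpha
    )
    acr_df.to_csv(outdir / "acrs.tsv", sep="\t", index=False, float_format="%.6g")
    de.to_csv(outdir / "acr_differential.tsv", sep="\t", float_format="%.6g")
    return {
        "acr_df": acr_df,
        "n_acrs": len(acr_df),
        "positional": acr_df["positional"].value_counts().to_dict(),
        "novel": int((acr_df["novel_silent"] == "novel").sum()),
        "silent": int((acr_df["novel_silent"] == "silent").sum()),
        "spa_m": int((acr_df["spa"] == "SPA-M").sum()),
        "spa_p": int((acr_df["spa"] == "SPA-P").sum()),
        "te_driven": int(acr_df["te_driven"].sum()),
        "de_up": int((de["label"] == "DE-up").sum()),
        "de_down": int((de["label"] == "DE-down").sum()),
    }


def _expression_stage(config: PipelineConfig, indir: Path, outdir: Path, genes, pairs) -> dict:
    counts_path = indir / "counts.tsv"
    if not counts_path.exists():
        return {}
    raw = aio.read_counts_tsv(counts_path)
    roles = {}
    for role in ("maternal", "paternal", "hybrid"):
        cols = [c for c in raw.columns if c.startswith(f"{role}_")]
        if not cols:
            raise ValueError(f"counts table is missing replicate columns for role {role!r}")
        roles[role] = cols
    table = E.ExpressionTable(raw.drop(columns="length"), raw["length"], roles)
    sub = pd.Series({g.gene_id: g.subgenome for g in genes}).reindex(raw.index)
    if sub.isna().any():
        missing = sub.index[sub.isna()][:3].tolist()
        raise ValueError(f"genes absent from annotation, e.g. {missing}")
    sf = {r: table.size_factors[roles[r]].values for r in roles}

    insilico = E.build_insilico_hybrid(
        table.raw("maternal"), table.raw("paternal"), sf["maternal"], sf["paternal"]
    )
    additivity = E.classify_additivity(
        table.raw("hybrid"),
        insilico,
        config.lfc_additive,
        config.alpha,
        size_factors_hybrid=sf["hybrid"],
    )
    additivity.index = raw.index
    pattern = E.classify_pattern(
        table.raw("hybrid"),
        table.raw("maternal"),
        table.raw("paternal"),
        additivity["additivity"].values,
        config.lfc_deg,
        config.alpha,
        size_factors=sf,
        subgenome=sub.values,
    )
    pattern.index = raw.index
    fpkm = table.fpkm()
    spe = E.call_spe(
        fpkm[roles["maternal"]].values,
        fpkm[roles["paternal"]].values,
        fpkm[roles["hybrid"]].values,
        sub.values,
        config.fpkm_expressed,
        config.spe_silent,
    )
    spe.index = raw.index
    dosage = E.classify_dosage(
        fpkm[roles["maternal"]].values,
        fpkm[roles["hybrid"]].values,
        fpkm[roles["paternal"]].values,
        sub.values,
        config.r2_threshold,
        config.alpha,
        per_genotype=config.dosage_per_genotype,
    )
    dosage.index = raw.index

    gene_df = pd.DataFrame(
        {
            "subgenome": sub,
            "mean_fpkm_hybrid": fpkm[roles["hybrid"]].mean(axis=1),
            "expressed": fpkm[roles["hybrid"]].mean(axis=1) > config.fpkm_expressed,
            "additivity": additivity["additivity"],
            "additivity_lfc": additivity["log2_fold_change"],
            "pattern": pattern["pattern"],
            "spe": spe["spe"],
            "dosage": dosage["dosage"],
            "dosage_r2": dosage["r_squared"],
        }
    )
    gene_df.index.name = "gene_id"
    gene_df.to_csv(outdir / "gene_classes.tsv", sep="\t", float_format="%.6g")
    homologs = E.homolog_categories(dosage["dosage"], pairs)
    homologs.to_csv(outdir / "homolog_categories.tsv", sep="\t", index=False)
    return {
        "gene_df": gene_df,
        "fpkm_hybrid": fpkm[roles["hybrid"]].mean(axis=1),
        "n_genes": len(gene_df),
        "additivity": gene_df["additivity"].value_counts().to_dict(),
        "pattern": gene_df["pattern"].value_counts().to_dict(),
        "spe": gene_df["spe"].value_counts().to_dict(),
        "dosage": gene_df["dosage"].value_counts().to_dict(),
        "homolog_categories": homologs["category"].value_counts().to_dict()
        if len(homologs)
        else {},
    }


def _methylation_stage(
    config: PipelineConfig, indir: Path, outdir: Path, genes, acr_df: Optional[pd.DataFrame]
) -> dict:
    meth_dir = indir / "meth"
    if not meth_dir.exists():
        return {}
    calls = {
        p.stem.split(".")[0]: aio.read_cx_report(p) for p in sorted(meth_dir.glob("*.cx.tsv"))
    }
    if not {"maternal", "paternal", "hybrid"} <= set(calls):
        raise ValueError("methylation stage needs maternal, paternal and hybrid CX reports")
    insilico = M.build_insilico_methylome(calls["maternal"], calls["paternal"])
    bins_h = M.bin_methylation(calls["hybrid"], config.meth_bin_size, config.meth_min_coverage)
    bins_i = M.bin_methylation(insilico, config.meth_bin_size, config.meth_min_coverage)
    dmrs = M.call_dmrs(
        bins_h,
        bins_i,
        delta_thresholds=config.dmr_deltas,
        alpha=config.alpha,
        min_sites=config.meth_min_sites,
    )
    gene_index = GeneIndex(genes)
    called = M.classify_dmr_targets(
        dmrs[dmrs["is_dmr"]].reset_index(drop=True), gene_index, config.window_bp
    )
    called.to_csv(outdir / "dmrs.tsv", sep="\t", index=False, float_format="%.6g")

    dmls = M.call_dmls(calls["hybrid"], insilico, config.alpha, config.meth_min_coverage)
    dml_called = dmls[dmls["is_dml"]]
    dml_called.to_csv(outdir / "dmls.tsv", sep="\t", index=False, float_format="%.6g")

    acr_status = pd.DataFrame()
    if acr_df is not None and len(acr_df):
        status = [
            M.acr_methylation_status(
                GenomicInterval(r.chrom, r.start, r.end),
                calls["hybrid"],
                config.acr_meth_thresholds,
                config.meth_min_coverage,
            )
            for r in acr_df.itertuples()
        ]
        acr_status = acr_df[["chrom", "start", "end"]].copy()
        acr_status["meth_status"] = status
        acr_status.to_csv(outdir / "acr_methylation.tsv", sep="\t", index=False)

    by_ctx = (
        called.groupby(["context", "direction"]).size().to_dict() if len(called) else {}
    )
    return {
        "dmr_df": called,
        "acr_meth": acr_status,
        "n_dmrs": int(dmrs["is_dmr"].sum()),
        "dmrs_by_context_direction": {f"{c}_{d}": int(n) for (c, d), n in by_ctx.items()},
        "dmr_positional": called["positional"].value_counts().to_dict() if len(called) else {},
        "n_dmls": int(dmls["is_dml"].sum()),
        "n_dmgs": int((called["target_gene"] != "").sum()) if len(called) else 0,
    }


def _srna_stage(config: PipelineConfig, indir: Path, outdir: Path, dmr_df) -> dict:
    srna_dir = indir / "srna"
    if not srna_dir.exists():
        return {}
    reads = {p.stem: aio.read_srna_bed(p) for p in sorted(srna_dir.glob("*.bed"))}
    clusters = {
        s: M.cluster_srna(
            df,
            config.srna_min_len,
            config.srna_max_len,
            config.srna_max_gap,
            config.srna_min_reads,
        )
        for s, df in reads.items()
    }
    for s, cl in clusters.items():
        cl.to_csv(outdir / f"srna_clusters_{s}.tsv", sep="\t", index=False, float_format="%.6g")
    summary = {f"n_clusters_{s}": len(cl) for s, cl in clusters.items()}
    if dmr_df is not None and len(dmr_df) and {"hybrid", "insilico"} <= set(clusters):
        enrich = M.dmr_srna_enrichment(dmr_df, clusters["hybrid"], clusters["insilico"])
        (outdir / "srna_dmr_enrichment.json").write_text(
            json.dumps(enrich, indent=1, sort_keys=True)
        )
        summary["dmr_enrichment"] = enrich
    return summary


def integrate(
    acr_df: Optional[pd.DataFrame],
    gene_df: Optional[pd.DataFrame],
    expression: Optional[pd.Series],
    acr_meth: Optional[pd.DataFrame] = None,
) -> dict:
    """Cross-layer integration tables.

    (a) fraction of gene-linked novel ACRs whose target gene is
    transgressive-up; (b) hybrid expression grouped by ACR positional
    class (Kruskal-Wallis); (c) expression by ACR methylation status
    (Wilcoxon); (d) expression of TE-driven vs non-TE ACR target genes
    (Wilcoxon). Empty inputs yield empty results with a warning.
    """
    out: dict = {}
    if acr_df is None or gene_df is None or expression is None or not len(acr_df):
        logger.warning("integration skipped: missing upstream tables")
        return out

    novel = acr_df[(acr_df["novel_silent"] == "novel") & acr_df["gene_linked"]]
    if len(novel):
        targets = novel["target_gene"]
        known = targets[targets.isin(gene_df.index)]
        frac = (
            float((gene_df.loc[known, "pattern"] == "transgressive-up").mean())
            if len(known)
            else float("nan")
        )
        out["novel_acr_transgressive_up_fraction"] = frac
        out["novel_acr_n_linked"] = int(len(known))

    linked = acr_df[acr_df["gene_linked"] & acr_df["target_gene"].isin(gene_df.index)]
    expr_of = lambda sub: expression.loc[sub["target_gene"]].values  # noqa: E731
    groups = [
        expr_of(linked[linked["positional"] == cls]) for cls in ("genic", "proximal", "distal")
    ]
    groups = [g for g in groups if g.size > 0]
    if len(groups) >= 2:
        res = rank_tests([np.log1p(g) for g in groups])
        out["expression_by_positional_class"] = {
            "p_value": res.p_value,
            "medians": {
                cls: float(np.median(expr_of(linked[linked["positional"] == cls])))
                for cls in ("genic", "proximal", "distal")
                if (linked["positional"] == cls).any()
            },
        }

    if acr_meth is not None and len(acr_meth):
        merged = linked.merge(acr_meth, on=["chrom", "start", "end"])
        meth_g = merged[merged["meth_status"] == "methylated"]
        unmeth_g = merged[merged["meth_status"] == "unmethylated"]
        if len(meth_g) >= 3 and len(unmeth_g) >= 3:
            res = rank_tests(
                [np.log1p(expr_of(meth_g)), np.log1p(expr_of(unmeth_g))]
            )
            out["expression_by_acr_methylation"] = {
                "p_value": res.p_value,
                "median_methylated": float(np.median(expr_of(meth_g))),
                "median_unmethylated": float(np.median(expr_of(unmeth_g))),
            }

    te_g, non_te_g = linked[linked["te_driven"]], linked[~linked["te_driven"]]
    if len(te_g) >= 3 and len(non_te_g) >= 3:
        res = rank_tests([np.log1p(expr_of(te_g)), np.log1p(expr_of(non_te_g))])
        out["expression_te_vs_non_te"] = {
            "p_value": res.p_value,
            "median_te": float(np.median(expr_of(te_g))),
            "median_non_te": float(np.median(expr_of(non_te_g))),
        }
    return out


def run_pipeline(config: PipelineConfig, stages: Optional[list[str]] = None) -> dict:
    """Run the requested stages (default: all) and write ``summary.json``."""
    indir, outdir = Path(config.indir), Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or ["acr", "expression", "methylation", "srna", "integrate"]
    genes, tes, pairs = _load_annotation(indir)
    logger.info("annotation: %d genes, %d TEs, %d homolog pairs", len(genes), len(tes), len(pairs))

    summary: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    acr_res = expr_res = meth_res = {}
    if "acr" in stages:
        acr_res = _acr_stage(config, indir, outdir, genes, tes)
        summary["stages"]["acr"] = {k: v for k, v in acr_res.items() if k != "acr_df"}
    if "expression" in stages:
        expr_res = _expression_stage(config, indir, outdir, genes, pairs)
        summary["stages"]["expression"] = {
            k: v for k, v in expr_res.items() if k not in ("gene_df", "fpkm_hybrid")
        }
    if "methylation" in stages:
        meth_res = _methylation_stage(
            config, indir, outdir, genes, acr_res.get("acr_df")
        )
        summary["stages"]["methylation"] = {
            k: v for k, v in meth_res.items() if k not in ("dmr_df", "acr_meth")
        }
    if "srna" in stages:
        srna_res = _srna_stage(config, indir, outdir, meth_res.get("dmr_df"))
        summary["stages"]["srna"] = srna_res
    if "integrate" in stages:
        summary["stages"]["integration"] = integrate(
            acr_res.get("acr_df"),
            expr_res.get("gene_df"),
            expr_res.get("fpkm_hybrid"),
            meth_res.get("acr_meth"),
        )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
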
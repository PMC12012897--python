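"""Ground-truth multi-omics generator for the allotriploid study design.

The simulated cross mirrors the real one: an allotetraploid maternal line
(AACC), a diploid paternal line (AA) and their allotriploid F1 (AAC). The
genome is a coordinate skeleton of A- and C-subgenome chromosomes carrying
non-overlapping genes (with A-C homolog pairs) and transposable elements.
Four assays are emulated with planted, recoverable ground truth:

* ATAC peaks per replicate, with planted shared / novel / silent / SPA-M /
  SPA-P / TE-driven accessible regions. Absence is structural (no peak at
  all), so the "reads = 0" side of the novel/silent rule is satisfiable;
  replicate peaks are jittered +/-30 bp so consensus merging is exercised.
* NB-distributed expression counts with planted additive, expression-level
  dominance, transgressive, SPE and dosage classes. C-subgenome genes are
  structural zeros in the paternal sample.
* Binomial methylation calls at ~50k cytosines with context baselines,
  TE hypermethylation, and planted DMR bins where the hybrid's rate is
  shifted against both parents.
* sRNA reads in two samples (hybrid, in-silico) with an accumulation shift
  planted at DMR bins.

Everything is driven by one integer seed through per-assay RNG streams, so
outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, TEFeature, merge_intervals
from .acr import PeakSet

SAMPLES = ("maternal", "paternal", "hybrid")

# fixed RNG stream ids, one per assay (draw order is part of the contract)
_STREAM_GENOME, _STREAM_EXPR, _STREAM_ACR, _STREAM_METH, _STREAM_SRNA = range(1, 6)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study-scale settings."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"A01": 1_000_000, "A02": 1_000_000, "C01": 1_000_000, "C02": 1_000_000}
    )
    n_genes: int = 800
    gene_length_range: tuple = (1000, 3000)
    n_tes_per_chrom: int = 100
    te_length_range: tuple = (500, 2500)
    homolog_fraction: float = 0.7
    n_replicates: int = 3

    # expression
    nb_dispersion: float = 0.1
    base_mean_log: float = 5.3  # lognormal location of baseline expression
    base_mean_sigma: float = 0.7
    eld_fold: float = 8.0  # parental divergence for ELD genes
    transgressive_fold: float = 8.0  # hybrid beyond the extreme parent
    spe_mean: float = 800.0
    dosage_scale_log: float = 8.0  # lognormal location of dosage-gene scale
    dosage_dispersion: float = 0.002  # low dispersion: replicate noise ~5% of scale
    # additive-dominated mix, as reported for real allotriploid hybrids
    # (~83-90% additive); keeps the majority-unchanged assumption of
    # median-of-ratios normalization realistic
    class_proportions: dict = field(
        default_factory=lambda: {
            "additive": 0.75,
            "eld_m": 0.03,
            "eld_p": 0.03,
            "transgressive_up": 0.025,
            "transgressive_down": 0.025,
            "spe_m": 0.02,
            "spe_p": 0.02,
            "dosage_dependent": 0.05,
            "dosage_independent": 0.05,
        }
    )

    # ACRs
    n_acrs: int = 600
    acr_width_range: tuple = (200, 400)
    acr_jitter_bp: int = 30
    acr_read_mean: float = 25.0  # per-replicate reads = 5 + Poisson(mean)
    acr_min_reads: int = 5
    acr_proportions: dict = field(
        default_factory=lambda: {
            "shared": 0.55,
            "novel": 0.10,
            "silent": 0.05,
            "spa_m": 0.10,
            "spa_p": 0.10,
            "te_driven": 0.10,
        }
    )
    novel_to_transgressive_fraction: float = 0.6
    n_noise_peaks: int = 40  # singleton-replicate peaks that must not survive merging

    # methylation
    n_cytosines: int = 50_000
    meth_coverage: float = 30.0
    context_proportions: dict = field(
        default_factory=lambda: {"CG": 0.3, "CHG": 0.3, "CHH": 0.4}
    )
    context_baselines: dict = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.3, "CHH": 0.1}
    )
    te_meth_boost: float = 0.25
    proximal_meth_factor: float = 0.5
    n_dmrs: int = 200
    dmr_bin_size: int = 200
    dmr_context: str = "CG"
    dmr_delta: float = 0.4
    dmr_sites_per_bin: int = 8

    # sRNA
    n_srna_background: int = 300
    srna_cluster_reads: float = 15.0  # per-cluster reads = 5 + Poisson(mean)
    srna_shift: float = 2.0  # fold accumulation shift at DMR bins

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(getattr(cls(), f.name), tuple) else v
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted labels: one row per simulated feature, exactly once."""

    genes: pd.DataFrame  # index gene_id: subgenome, expr_class
    acrs: pd.DataFrame  # chrom, start, end, category
    dmrs: pd.DataFrame  # chrom, bin_start, context, direction
    srna_shift: float = 1.0

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "acrs": self.acrs.to_dict(orient="list"),
            "dmrs": self.dmrs.to_dict(orient="list"),
            "srna_shift": self.srna_shift,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")
        return cls(
            genes=genes,
            acrs=pd.DataFrame(payload["acrs"]),
            dmrs=pd.DataFrame(payload["dmrs"]),
            srna_shift=payload["srna_shift"],
        )


def make_genome(config: SimConfig) -> tuple[list[GeneModel], list[TEFeature]]:
    """Place non-overlapping genes and intergenic-preferring TEs.

    Genes sit in regular slots with jittered offsets; A genes are paired
    with C homologs for ``homolog_fraction`` of the smaller subgenome. TEs
    are sampled in the gaps between genes.
    """
    rng = config.rng(_STREAM_GENOME)
    chroms = sorted(config.chrom_lengths)
    n_per_chrom = config.n_genes // len(chroms)
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    for chrom in chroms:
        clen = config.chrom_lengths[chrom]
        slot = clen // n_per_chrom
        if slot <= hi:
            raise ValueError(f"gene density infeasible on {chrom}: slot {slot} <= max length {hi}")
        for i in range(n_per_chrom):
            glen = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(0, slot - glen))
            start = i * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}G{i + 1:04d}"
            genes.append(GeneModel(gid, GenomicInterval(chrom, start, start + glen, strand)))

    a_genes = [g for g in genes if g.subgenome == "A"]
    c_genes = [g for g in genes if g.subgenome == "C"]
    n_pairs = int(round(config.homolog_fraction * min(len(a_genes), len(c_genes))))
    a_paired = rng.choice(len(a_genes), size=n_pairs, replace=False)
    c_paired = rng.choice(len(c_genes), size=n_pairs, replace=False)
    for ai, ci in zip(a_paired, c_paired):
        a_genes[ai].homolog_partner = c_genes[ci].gene_id
        c_genes[ci].homolog_partner = a_genes[ai].gene_id

    tes: list[TEFeature] = []
    te_lo, te_hi = config.te_length_range
    classes = np.array(["LTR/Gypsy", "LTR/Copia", "LINE", "DNA/MuDR"])
    for chrom in chroms:
        gaps = _intergenic_gaps(chrom, config.chrom_lengths[chrom], genes)
        gaps = [g for g in gaps if g[1] - g[0] > te_lo + 10]
        weights = np.array([g[1] - g[0] for g in gaps], dtype=float)
        weights /= weights.sum()
        for _ in range(config.n_tes_per_chrom):
            gs, ge = gaps[rng.choice(len(gaps), p=weights)]
            tlen = int(rng.integers(te_lo, min(te_hi, ge - gs - 1) + 1))
            start = int(rng.integers(gs, ge - tlen))
            tes.append(
                TEFeature(GenomicInterval(chrom, start, start + tlen), str(rng.choice(classes)))
            )
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return genes, tes


def _intergenic_gaps(chrom: str, clen: int, genes: list[GeneModel]) -> list[tuple[int, int]]:
    spans = merge_intervals(
        [(g.interval.start, g.interval.end) for g in genes if g.interval.chrom == chrom]
    )
    gaps, prev = [], 0
    for s, e in spans:
        if s > prev:
            gaps.append((prev, s))
        prev = e
    if prev < clen:
        gaps.append((prev, clen))
    return gaps


def _assign_classes(config: SimConfig, genes: list[GeneModel], rng: np.random.Generator) -> pd.Series:
    """Planted expression class per gene; parent-contrast classes (ELD,
    transgressive, SPE, dosage-independent) go to the A subgenome only."""
    a_ids = [g.gene_id for g in genes if g.subgenome == "A"]
    c_ids = [g.gene_id for g in genes if g.subgenome == "C"]
    rng.shuffle(a_ids)
    rng.shuffle(c_ids)
    n = len(genes)
    a_only = ("eld_m", "eld_p", "transgressive_up", "transgressive_down", "spe_m", "spe_p", "dosage_independent")
    labels: dict[str, str] = {}
    # A-restricted classes claim genes first, then shared classes from the
    # smallest up, so the bulk additive class cannot starve the others
    ordered = sorted(
        config.class_proportions.items(), key=lambda kv: (kv[0] not in a_only, kv[1])
    )
    for cls_name, prop in ordered:
        k = int(round(prop * n))
        for j in range(k):
            if cls_name in a_only:
                if not a_ids:
                    break
                labels[a_ids.pop()] = cls_name
            else:
                # shared classes alternate subgenomes so each gets members
                pool = a_ids if (j % 2 == 0 and a_ids) or not c_ids else c_ids
                if not pool:
                    break
                labels[pool.pop()] = cls_name
    for gid in a_ids + c_ids:
        labels[gid] = "background"
    return pd.Series({g.gene_id: labels[g.gene_id] for g in genes}, name="expr_class")


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float, size: tuple) -> np.ndarray:
    """NB counts with mean mu and dispersion alpha; mu == 0 stays exactly 0."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    out = np.zeros(size, dtype=np.int64)
    pos = mu > 0
    if alpha <= 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu[pos])
    out[pos] = rng.negative_binomial(n_param, p_param)
    return out


def simulate_expression(
    config: SimConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts table (gene x sample replicates, plus lengths) and true labels.

    Genotype means follow each gene's planted class; C-subgenome genes are
    structural zeros in the paternal sample whatever their class.
    """
    rng = config.rng(_STREAM_EXPR)
    labels = _assign_classes(config, genes, rng)
    nrep = config.n_replicates
    gene_ids = [g.gene_id for g in genes]
    sub = pd.Series({g.gene_id: g.subgenome for g in genes})
    n = len(genes)
    base = rng.lognormal(config.base_mean_log, config.base_mean_sigma, size=n)
    # parental divergence of unconstrained genes: log-symmetric around 1 so
    # neither parent is systematically richer (median-of-ratios assumption)
    u = 2.0 ** rng.normal(0.0, 0.5, size=n)

    mu = pd.DataFrame(0.0, index=gene_ids, columns=["maternal", "hybrid", "paternal"])
    alpha = pd.Series(config.nb_dispersion, index=gene_ids)
    fold_e, fold_t = config.eld_fold, config.transgressive_fold
    for i, gid in enumerate(gene_ids):
        cls_name = labels[gid]
        b = base[i]
        if cls_name == "additive":
            m, p = b * u[i], b
        elif cls_name == "eld_m":
            m, p = b * fold_e, b
        elif cls_name == "eld_p":
            m, p = b, b * fold_e
        elif cls_name in ("transgressive_up", "transgressive_down"):
            m, p = b, b * u[i]
        elif cls_name == "spe_m":
            m, p = config.spe_mean, 0.0
        elif cls_name == "spe_p":
            m, p = 0.0, config.spe_mean
        elif cls_name == "dosage_dependent":
            s = rng.lognormal(config.dosage_scale_log, 0.3)
            dose = (0.5, 2 / 3, 1.0) if sub[gid] == "A" else (0.5, 1 / 3, 0.0)
            mu.loc[gid] = [s * dose[0], s * dose[1], s * dose[2]]
            alpha[gid] = config.dosage_dispersion
            continue
        elif cls_name == "dosage_independent":
            m = p = b * 2
        else:  # background
            m, p = b * 2.0 ** rng.uniform(-1, 1), b * 2.0 ** rng.uniform(-1, 1)

        # the AA paternal line cannot express C-subgenome genes; zero its
        # mean before deriving the hybrid so planted classes stay coherent
        if sub[gid] == "C":
            p = 0.0

        if cls_name == "eld_m":
            h = m
        elif cls_name == "eld_p":
            h = p
        elif cls_name == "transgressive_up":
            h = max(m, p) * fold_t
        elif cls_name == "transgressive_down":
            h = min(m, p) / fold_t
        elif cls_name in ("spe_m", "spe_p"):
            h = config.spe_mean
        elif cls_name == "dosage_independent":
            h = m
        elif cls_name == "background":
            h = rng.uniform(min(m, p), max(m, p) + 1e-9)
        else:  # additive
            h = 0.5 * (m + p)
        mu.loc[gid] = [m, h, p]

    # paternal AA line carries no C subgenome
    mu.loc[sub == "C", "paternal"] = 0.0

    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=gene_ids,
        name="length",
    )
    data = {"length": lengths}
    for role in ("maternal", "paternal", "hybrid"):
        for r in range(nrep):
            col = np.zeros(n, dtype=np.int64)
            for a_val in np.unique(alpha.values):
                mask = alpha.values == a_val
                col[mask] = _nb_draws(
                    rng, mu[role].values[mask], float(a_val), (int(mask.sum()),)
                )
            data[f"{role}_{r + 1}"] = col
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return counts, labels


def _place_loci(
    rng: np.random.Generator,
    config: SimConfig,
    n: int,
    chrom_pool: list[str],
    width_range: tuple[int, int],
    occupied: dict[str, list[tuple[int, int]]],
    min_sep: int = 1000,
) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        for _attempt in range(200):
            chrom = chrom_pool[int(rng.integers(0, len(chrom_pool)))]
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            start = int(rng.integers(0, config.chrom_lengths[chrom] - w))
            if all(
                start >= e + min_sep or start + w <= s - min_sep
                for s, e in occupied.get(chrom, [])
            ):
                occupied.setdefault(chrom, []).append((start, start + w))
                out.append(GenomicInterval(chrom, start, start + w))
                break
        else:
            raise RuntimeError("could not place locus; genome too crowded")
    return out


def simulate_acrs(
    config: SimConfig,
    genes: list[GeneModel],
    tes: list[TEFeature],
    expr_labels: Optional[pd.Series] = None,
) -> tuple[dict[str, list[PeakSet]], pd.DataFrame]:
    """Per-sample replicate PeakSets plus the planted category table.

    Presence follows the category definitions (structural absence
    elsewhere); per-replicate peaks are jittered +/-``acr_jitter_bp`` and
    carry 5 + Poisson reads so presence thresholds always hold. A fraction
    of novel ACRs is placed in the promoters of planted transgressive-up
    genes to create the novel-ACR/transgressive linkage.
    """
    rng = config.rng(_STREAM_ACR)
    props = config.acr_proportions
    if props.get("te_driven", 0) > 0 and not tes:
        raise ValueError("cannot plant TE-driven ACRs with zero TE density")
    a_chroms = [c for c in config.chrom_lengths if c.startswith("A")]
    all_chroms = sorted(config.chrom_lengths)
    counts = {k: int(round(v * config.n_acrs)) for k, v in props.items()}

    occupied: dict[str, list[tuple[int, int]]] = {}
    records: list[tuple[str, int, int, str]] = []

    # TE-driven: >50% of the region inside one TE
    te_pool = [t for t in tes if t.interval.length >= config.acr_width_range[0]]
    for idx in rng.choice(len(te_pool), size=counts.get("te_driven", 0), replace=False):
        te = te_pool[idx].interval
        w = min(int(rng.integers(*config.acr_width_range)), te.length)
        inside = int(np.ceil(w * 0.6))
        start = int(rng.integers(te.start, max(te.start + 1, te.end - inside)))
        occupied.setdefault(te.chrom, []).append((start, start + w))
        records.append((te.chrom, start, start + w, "te_driven"))

    # novel ACRs: part linked to transgressive-up promoters
    n_novel = counts.get("novel", 0)
    linked = 0
    if expr_labels is not None and config.novel_to_transgressive_fraction > 0:
        tg = [
            g
            for g in genes
            if expr_labels.get(g.gene_id) == "transgressive_up" and g.subgenome == "A"
        ]
        rng.shuffle(tg)
        linked = int(round(n_novel * config.novel_to_transgressive_fraction)) if tg else 0
        for i in range(linked):
            # promoters may host several novel regions: cycle the gene list
            g = tg[i % len(tg)]
            iv = g.interval
            w = int(rng.integers(*config.acr_width_range))
            for _attempt in range(50):
                off = int(rng.integers(100, 800))
                if iv.strand == "-":
                    start = iv.end + off
                else:
                    start = max(0, iv.start - off - w)
                if all(
                    start >= e or start + w <= s
                    for s, e in occupied.get(iv.chrom, [])
                ):
                    break
            occupied.setdefault(iv.chrom, []).append((start, start + w))
            records.append((iv.chrom, start, start + w, "novel"))
    for iv in _place_loci(
        rng, config, n_novel - linked, a_chroms, config.acr_width_range, occupied
    ):
        records.append((iv.chrom, iv.start, iv.end, "novel"))

    for cat, pool in (
        ("silent", a_chroms),
        ("spa_m", a_chroms),
        ("spa_p", a_chroms),
        ("shared", all_chroms),
    ):
        for iv in _place_loci(
            rng, config, counts.get(cat, 0), pool, config.acr_width_range, occupied
        ):
            records.append((iv.chrom, iv.start, iv.end, cat))

    presence = {
        "shared": ("maternal", "paternal", "hybrid"),
        "te_driven": ("maternal", "paternal", "hybrid"),
        "novel": ("hybrid",),
        "silent": ("maternal", "paternal"),
        "spa_m": ("maternal", "hybrid"),
        "spa_p": ("paternal", "hybrid"),
    }
    peaks: dict[str, list[list[tuple[GenomicInterval, float]]]] = {
        s: [[] for _ in range(config.n_replicates)] for s in SAMPLES
    }
    for chrom, start, end, cat in records:
        sg = chrom[0].upper()
        for sample in presence[cat]:
            if sample == "paternal" and sg == "C":
                continue  # AA line: no C subgenome at all
            for r in range(config.n_replicates):
                j1 = int(rng.integers(-config.acr_jitter_bp, config.acr_jitter_bp + 1))
                j2 = int(rng.integers(-config.acr_jitter_bp, config.acr_jitter_bp + 1))
                s_, e_ = max(0, start + j1), end + j2
                reads = config.acr_min_reads + int(rng.poisson(config.acr_read_mean))
                peaks[sample][r].append((GenomicInterval(chrom, s_, e_), float(reads)))

    # singleton noise peaks: one replicate of one sample, must not merge
    for iv in _place_loci(
        rng, config, config.n_noise_peaks, all_chroms, config.acr_width_range, occupied
    ):
        sample = SAMPLES[int(rng.integers(0, 3))]
        if sample == "paternal" and iv.subgenome == "C":
            sample = "hybrid"
        r = int(rng.integers(0, config.n_replicates))
        reads = config.acr_min_reads + int(rng.poisson(config.acr_read_mean))
        peaks[sample][r].append((iv, float(reads)))

    peaksets = {
        s: [PeakSet(s, f"rep{r + 1}", plist) for r, plist in enumerate(peaks[s])]
        for s in SAMPLES
    }
    truth = pd.DataFrame(records, columns=["chrom", "start", "end", "category"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    return peaksets, truth


def simulate_methylome(
    config: SimConfig, genes: list[GeneModel], tes: list[TEFeature]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample cytosine call tables and the planted DMR bin table.

    Context baselines (CG 0.6, CHG 0.3, CHH 0.1) are raised inside TEs and
    halved near genes. In planted bins both parents share a baseline and
    the hybrid's rate is shifted by +/-``dmr_delta``; the paternal sample
    has no C-subgenome rows.
    """
    rng = config.rng(_STREAM_METH)
    chroms = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    ctxs = np.array(list(config.context_proportions))
    ctx_p = np.array([config.context_proportions[c] for c in ctxs])

    # planted DMR bins, kept clear of each other
    bin_size = config.dmr_bin_size
    dmr_rows = []
    used_bins: set[tuple[str, int]] = set()
    n_per_chrom = int(np.ceil(config.n_dmrs / len(chroms)))
    for chrom in chroms:
        n_bins_chrom = config.chrom_lengths[chrom] // bin_size
        while sum(1 for c, _ in used_bins if c == chrom) < n_per_chrom and len(dmr_rows) < config.n_dmrs:
            b = int(rng.integers(0, n_bins_chrom)) * bin_size
            if (chrom, b) in used_bins:
                continue
            used_bins.add((chrom, b))
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            dmr_rows.append((chrom, b, config.dmr_context, direction))
    dmr_truth = pd.DataFrame(dmr_rows, columns=["chrom", "bin_start", "context", "direction"])

    frames = {}
    chrom_arr, pos_arr, strand_arr, ctx_arr, rate_parent, rate_hybrid = [], [], [], [], [], []
    for chrom in chroms:
        clen = config.chrom_lengths[chrom]
        n_c = int(round(config.n_cytosines * clen / total_len))
        pos = np.sort(rng.choice(clen, size=n_c, replace=False))
        ctx = rng.choice(ctxs, size=n_c, p=ctx_p)
        strand = rng.choice(np.array(["+", "-"]), size=n_c)
        base_rate = np.array([config.context_baselines[c] for c in ctx])

        te_runs = merge_intervals(
            [(t.interval.start, t.interval.end) for t in tes if t.interval.chrom == chrom]
        )
        prox_runs = merge_intervals(
            [
                (max(0, g.interval.start - 2000), g.interval.end + 2000)
                for g in genes
                if g.interval.chrom == chrom
            ]
        )
        in_te = _in_runs(pos, te_runs)
        in_prox = _in_runs(pos, prox_runs) & ~in_te
        rate = base_rate.copy()
        rate[in_te] = np.minimum(rate[in_te] + config.te_meth_boost, 0.95)
        rate[in_prox] = rate[in_prox] * config.proximal_meth_factor
        r_par, r_hyb = rate.copy(), rate.copy()

        chrom_dmrs = dmr_truth[dmr_truth["chrom"] == chrom]
        for _, row in chrom_dmrs.iterrows():
            b = row["bin_start"]
            # clear the bin of background sites, then plant dedicated ones
            keep = (pos < b) | (pos >= b + bin_size)
            pos, ctx, strand = pos[keep], ctx[keep], strand[keep]
            r_par, r_hyb = r_par[keep], r_hyb[keep]
            k = config.dmr_sites_per_bin
            new_pos = np.sort(rng.choice(np.arange(b, b + bin_size), size=k, replace=False))
            new_ctx = np.full(k, row["context"])
            new_strand = rng.choice(np.array(["+", "-"]), size=k)
            if row["direction"] == "hyper":
                base, shifted = 0.4, 0.4 + config.dmr_delta
            else:
                base, shifted = 0.8, 0.8 - config.dmr_delta
            pos = np.concatenate([pos, new_pos])
            ctx = np.concatenate([ctx, new_ctx])
            strand = np.concatenate([strand, new_strand])
            r_par = np.concatenate([r_par, np.full(k, base)])
            r_hyb = np.concatenate([r_hyb, np.full(k, shifted)])

        order = np.argsort(pos, kind="stable")
        chrom_arr.append(np.full(pos.size, chrom))
        pos_arr.append(pos[order])
        ctx_arr.append(ctx[order])
        strand_arr.append(strand[order])
        rate_parent.append(r_par[order])
        rate_hybrid.append(r_hyb[order])

    base_df = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_arr),
            "pos": np.concatenate(pos_arr),
            "strand": np.concatenate(strand_arr),
            "context": np.concatenate(ctx_arr),
        }
    )
    r_par = np.concatenate(rate_parent)
    r_hyb = np.concatenate(rate_hybrid)
    for sample in SAMPLES:
        rate = r_hyb if sample == "hybrid" else r_par
        df = base_df.copy()
        if sample == "paternal":
            keep = ~df["chrom"].str.startswith("C")
            df = df[keep].reset_index(drop=True)
            rate = rate[keep.values]
        cov = rng.poisson(config.meth_coverage, size=len(df))
        meth = rng.binomial(cov, rate)
        df["meth"] = meth
        df["unmeth"] = cov - meth
        frames[sample] = df
    return frames, dmr_truth


def _in_runs(pos: np.ndarray, runs: list[tuple[int, int]]) -> np.ndarray:
    if not runs:
        return np.zeros(pos.size, dtype=bool)
    starts = np.array([s for s, _ in runs])
    ends = np.array([e for _, e in runs])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


_SRNA_LENGTHS = np.arange(18, 31)
_SRNA_LENGTH_P = np.array([1, 1, 2, 10, 3, 2, 8, 2, 1, 1, 1, 1, 1], dtype=float)
_SRNA_LENGTH_P /= _SRNA_LENGTH_P.sum()  # modes at 21 and 24 nt


def simulate_srna(
    config: SimConfig, dmr_truth: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """sRNA reads for the hybrid and the in-silico mixture.

    Background cluster loci have equal expected reads in both samples; at
    hyper-DMR bins the in-silico sample accumulates ``srna_shift`` times
    more reads, at hypo-DMR bins the hybrid does (shift 1 plants nothing).
    """
    rng = config.rng(_STREAM_SRNA)
    chroms = sorted(config.chrom_lengths)
    loci: list[tuple[str, int, float, float]] = []  # chrom, center, mult_hybrid, mult_insilico
    for _ in range(config.n_srna_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        center = int(rng.integers(200, config.chrom_lengths[chrom] - 200))
        loci.append((chrom, center, 1.0, 1.0))
    for _, row in dmr_truth.iterrows():
        center = int(row["bin_start"]) + config.dmr_bin_size // 2
        if row["direction"] == "hyper":
            loci.append((row["chrom"], center, 1.0, config.srna_shift))
        else:
            loci.append((row["chrom"], center, config.srna_shift, 1.0))

    reads: dict[str, list[tuple[str, int, int, int]]] = {"hybrid": [], "insilico": []}
    for chrom, center, mult_h, mult_i in loci:
        base = 5 + int(rng.poisson(config.srna_cluster_reads))
        for sample, mult in (("hybrid", mult_h), ("insilico", mult_i)):
            n_reads = int(round(base * mult))
            offs = rng.integers(-config.dmr_bin_size // 2 + 5, config.dmr_bin_size // 2 - 5, size=n_reads)
            lens = rng.choice(_SRNA_LENGTHS, size=n_reads, p=_SRNA_LENGTH_P)
            for off, ln in zip(offs, lens):
                start = max(0, center + int(off))
                reads[sample].append((chrom, start, start + int(ln), int(ln)))
    out = {}
    for sample, rows in reads.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])
        out[sample] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def simulate_all(config: SimConfig, outdir) -> GroundTruth:
    """Run every generator and write the on-disk dataset.

    Layout: genes.gff3, tes.bed, homologs.tsv, counts.tsv,
    peaks/<sample>_rep<k>.bed, meth/<sample>.cx.tsv, srna/<sample>.bed,
    truth.json.
    """
    from . import io as aio

    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "meth").mkdir(exist_ok=True)
    (outdir / "srna").mkdir(exist_ok=True)

    genes, tes = make_genome(config)
    counts, labels = simulate_expression(config, genes)
    peaksets, acr_truth = simulate_acrs(config, genes, tes, labels)
    meth, dmr_truth = simulate_methylome(config, genes, tes)
    srna = simulate_srna(config, dmr_truth)

    aio.write_gff3_genes(genes, outdir / "genes.gff3")
    aio.write_te_bed(tes, outdir / "tes.bed")
    pairs = [
        (g.gene_id, g.homolog_partner)
        for g in genes
        if g.subgenome == "A" and g.homolog_partner
    ]
    aio.write_homolog_pairs(pairs, outdir / "homologs.tsv")
    aio.write_counts_tsv(counts, outdir / "counts.tsv")
    for sample, psets in peaksets.items():
        for r, ps in enumerate(psets):
            aio.write_peak_bed(ps.peaks, outdir / "peaks" / f"{sample}_rep{r + 1}.bed")
    for sample, df in meth.items():
        aio.write_cx_report(df, outdir / "meth" / f"{sample}.cx.tsv")
    for sample, df in srna.items():
        aio.write_srna_bed(df, outdir / "srna" / f"{sample}.bed")

    gene_truth = pd.DataFrame(
        {
            "subgenome": pd.Series({g.gene_id: g.subgenome for g in genes}),
            "expr_class": labels,
        }
    )
    gene_truth.index.name = "gene_id"
    truth = GroundTruth(
        genes=gene_truth, acrs=acr_truth, dmrs=dmr_truth, srna_shift=config.srna_shift
    )
    truth.to_json(outdir / "truth.json")
    return truth
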
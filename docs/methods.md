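# Methods

`allohybrid` analyses post-alignment multi-omics summaries from an
interspecific *Brassica* cross: an allotetraploid maternal parent (genome
AACC), a diploid paternal parent (AA) and their allotriploid F1 hybrid
(AAC). The asymmetry of that design — the paternal line structurally lacks
the whole C subgenome — runs through every stage and is treated explicitly
rather than averaged away.

## Coordinate model

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read so BED files round-trip byte-exactly. Chromosome names
carry the subgenome as their leading letter (`A01`, `C02`); an override
table handles nonstandard names. Regions are classified against gene
bodies as **genic** (≥1 bp overlap), **proximal** (within a 2,000 bp
flank, measured strand-agnostically from the gene-body boundaries) or
**distal**, with precedence genic > proximal > distal. The 2 kb window is
the published convention for compact plant genomes; it is a parameter
(`window_bp`). "Within 2 kb" is read against gene-body boundaries rather
than TSS/TTS points only — the two readings differ only for regions beyond
an annotated UTR, and the gene-body reading keeps the rule monotone in the
window size.

## Accessible chromatin regions (ACRs)

Per-replicate ATAC peaks become a consensus ACR when peaks from at least
`min_replicates` (default 2 of 3) replicates mutually overlap by strictly
more than 50 bp; the consensus interval is the union of the connected
peaks. The strict reading of "over 50 bp" makes a 50-bp overlap
insufficient. Union intervals (rather than intersections) follow
consensus-peak practice in differential-binding tools.

Cross-sample categories are threshold rules on per-replicate read support
at consensus regions:

* **novel** — every hybrid replicate ≥ 5 reads and every replicate of both
  parents exactly 0; **silent** is the mirror image. The "reads = 0" side
  is applied to raw counts: a normalized near-zero never qualifies, only a
  structural absence does.
* **SPA-M / SPA-P** (single-parent activation) — present (≥5 reads in all
  replicates) in one parent plus the hybrid, absent (0) in the other
  parent. Restricted to the A subgenome: absence of a C-subgenome peak in
  the AA paternal line carries no information, so C input raises an error
  instead of a spurious call.
* **TE-driven** — strictly more than 50% of the region covered by the
  union of TE annotations (never double-counting overlapping TEs).
* **DE-up / DE-down** — the negative-binomial test below, BH-adjusted
  p < 0.05 and |log2FC| ≥ 1 (the fold threshold is not fixed by
  convention; 1 is the package default and configurable).

Whether "reads ≥ 5" applies per replicate or to pooled replicates is not
fixed by convention either; the per-replicate reading is used because it
is the stricter one and matches the replicate-consistency spirit of the
merge rule.

Accessibility profiles (mean reads per sample) are soft-clustered with
fuzzy c-means (k = 9, fuzzifier m = 2, tolerance 1e-5, max 300 iterations,
seeded) on row-z-scored profiles; constant rows are dropped with a logged
warning. k = 9 mirrors the cluster count used for this kind of
accessibility partition; m, tol and the iteration cap are the conventional
Bezdek defaults.

## Negative-binomial two-group test

A deliberately simple stand-in for a full GLM framework, used for
differential accessibility and all expression contrasts:

1. median-of-ratios size factors (geometric-mean reference per gene;
   total-count fallback with a warning when no gene is positive
   everywhere);
2. per-gene method-of-moments dispersion from the pooled within-group
   variance of normalized counts, **moderated** by a least-squares
   mean–dispersion trend `a0 + a1/μ`: the estimate is floored at the trend
   and capped at 4× the trend, so a single outlier variance from 3
   replicates can neither fake precision nor destroy power;
3. a Wald z test on `log2((μ_B + 0.5)/(μ_A + 0.5))` with delta-method
   standard errors from `Var(K/s) = μ/s + αμ²`.

Genes with zero counts in both groups return (log2FC 0, p 1). The
moderation and the plain normal reference were chosen by Monte-Carlo
calibration on NB null data (mean 100, dispersion 0.1, 3 vs 3): the raw
p < 0.05 fraction is 0.031–0.045 across seeds with at most ~1
BH-significant gene in 2,000 — slightly conservative, never
anticonservative. A t reference with n−2 df was rejected as
over-conservative (~0.004); un-moderated moment dispersion as
anticonservative (~0.11). Agreement with any external differential tool
is explicitly not a goal; calibration is.

## Expression genetics

FPKM is `count / (length_kb × library_millions)`; a gene is *expressed*
when FPKM strictly exceeds 1. For every cross-sample comparison the
library size is **effective** (median-of-ratios size factor × median raw
depth) rather than the raw total: the paternal AA library contains no
C-subgenome reads, so raw-total FPKM systematically inflates paternal
A-gene values and would manufacture a dosage gradient in every constant
gene. `raw_library=True` restores plain FPKM.

The **in-silico hybrid** (mid-parent) mixes normalized parental counts 1:1
per replicate pair, rounded to integers for count testing. The 1:1 ratio
is the stated construction for this design; a maternal-weight parameter
exists purely for sensitivity analysis. A gene is **nonadditive** (up or
down) when the hybrid differs from the in-silico sample at BH-adjusted
p < 0.05 and |log2FC| ≥ 1.5, otherwise additive.

**Patterns** come from the three pairwise contrasts (hybrid–maternal,
hybrid–paternal, maternal–paternal) under the stricter DEG rule
(|log2FC| ≥ 2, adjusted p < 0.05), following the standard dominance
framework:

| pattern | rule |
|---|---|
| transgressive-up | hybrid significantly above both parents |
| transgressive-down | hybrid significantly below both parents |
| ELD-M | hybrid ≈ maternal, ≠ paternal, parents differ |
| ELD-P | hybrid ≈ paternal, ≠ maternal, parents differ |
| additive | none of the above and the MPV test is non-differential |
| other | remaining combinations |

Contrast-derived patterns take precedence over the additive fill: a hybrid
expressed exactly at one parent's level has `H/MPV ≤ 2` and so can never
clear the 1.5 log2 MPV rule, yet is the textbook dominance case. Paternal
contrasts are suppressed for C-subgenome genes (they would all read as
spurious maternal dominance), so C genes can only be additive or other —
the same restriction the SPA/SPE definitions impose.

**SPE** (single parental expression): expressed (FPKM > 1, every
replicate) in one parent and the hybrid, silent in the other parent. The
silence bound — FPKM < 0.1 in all replicates — is a package decision (no
numeric bound is fixed by the definition) and is configurable. A-subgenome
only; C genes return `none` with reason `C-subgenome-uninformative`.

**Dosage dependence.** Relative subgenome dosage across (maternal, hybrid,
paternal) is (1/2, 2/3, 1) for A and (1/2, 1/3, 0) for C. Each gene's
expression is Pearson-correlated with its dosage vector; BH adjustment
runs genome-wide; *dependent* requires r² strictly above 0.64 **and**
adjusted p < 0.05. Zero-variance expression is independent; negative
correlations with r² > 0.64 are labeled dependent with the sign reported.
By default every replicate contributes one point at its genotype's dosage
(n = 9). The 3-point per-genotype-mean mode is kept (`per_genotype=True`)
but is nearly powerless: with n = 3 the p-value has 1 df
(`p = 1 − (2/π)·asin|r|`), so FDR < 0.05 needs |r| > 0.997 — the worked
example (expression 1.72/1.96/2.54, r = 0.9990, p = 0.029) passes, but a
gene with 5% noise typically does not. Homolog pairs cross the A- and
C-member labels into AdCd / AdCi / AiCd / AiCi; unpaired genes are
reported as genome-unique.

## Methylation and sRNA

Methylation levels are always weighted (pooled methylated / pooled total),
over sites with read coverage ≥ 5 — the standard validity filter; "covers
five or more cytosine sites" is read as per-cytosine coverage, the
conventional interpretation, and is configurable. The in-silico methylome
mixes parents 1:1 after scaling both to their mean coverage at each shared
position (so depth differences cannot tilt the mixture), with C-subgenome
positions carried from the maternal parent alone.

**DMRs** are called in fixed 200-bp bins per context. A bin is tested when
≥ 3 qualifying cytosines of the context are covered in both samples (the
per-bin site minimum is a package decision); the test is a two-sided
Fisher exact on pooled counts — chosen as standard WGBS practice since no
specific statistic is dictated — BH-adjusted per context. A DMR requires
adjusted p < 0.05 **and** |Δlevel| strictly above 0.3 / 0.2 / 0.1 for
CG / CHG / CHH. Direction `hyper` means sample 1 above sample 2, so
swapping samples flips all directions. **DMLs** apply the same test per
cytosine. The bulk Fisher path enumerates the hypergeometric support
vectorized (tie tolerance 1 + 1e-7, matching scipy to < 1e-12; verified
against a brute-force enumeration oracle). DMRs are positioned and
assigned to genes (DMGs) with the same genic/proximal rules as ACRs.

ACR methylation status: *unmethylated* iff every covered context sits
below (mCG 0.1, mCHG 0.1, mCHH 0.05); *methylated* if any reaches its
bound; *undefined* without covered cytosines. These bounds are package
decisions, exposed in configuration and echoed in outputs.

**sRNA**: reads of 18–30 nt are grouped into clusters by merging reads
less than 75 bp apart and keeping clusters with ≥ 5 reads (gap and minimum
are simplified stand-ins for a dedicated clustering tool; exact parity is
a non-goal). RPM is reads per million total clean reads. DMR–sRNA
association is a Wilcoxon rank-sum of per-DMR summed cluster RPM between
the hybrid and the in-silico sample, separately for hyper- and hypo-DMRs;
fewer than 3 DMRs in a direction flags the result underpowered.

Rank tests use exact enumeration for tie-free samples of ≤ 25 per group
and the tie/continuity-corrected normal approximation otherwise; a
statistic exactly at its null center reports p = 1. Kruskal–Wallis serves
3+ groups.

## Synthetic data generator

The generator emulates the study design so every pipeline rule is
exercisable with known truth: 2 A + 2 C chromosomes of 1 Mb, 800
non-overlapping genes (70% of the smaller subgenome in A–C homolog pairs),
~100 TEs per chromosome in intergenic space, 3 replicates per assay,
one integer seed feeding fixed per-assay RNG streams (bit-reproducible).

*Expression.* NB counts (dispersion 0.1) around per-genotype means set by
each gene's planted class. The class mix is additive-dominated (75%
additive; 3% ELD each way; 2.5% transgressive each way; 2% SPE each way;
5% dosage-dependent; 5% dosage-independent) — real allotriploid
transcriptomes are reported at 83–90% additive, and an additive-dominated
mixture is also what keeps median-of-ratios normalization valid.
Parental divergence of unconstrained genes is log-symmetric
(2^N(0, 0.5)), so neither parent is systematically richer. ELD and
transgressive effects use fold 8: the DEG rule needs *observed*
|log2FC| ≥ 2 in two contrasts jointly, and with 3 replicates at
dispersion 0.1 the fold-change estimate has SD ≈ 0.38, so a true fold of
8 (log2 = 3) leaves a ~2.6 SD margin per contrast (expected per-gene
recovery ≥ 97%); at fold 4 the truth sits exactly on the decision
boundary and no classifier could recover 90% of it. SPE silence and the
paternal C subgenome are structural zeros, not sampled zeros.
Dosage-dependent genes scale a lognormal baseline (~3,000 counts) by the
dosage vector at dispersion 0.002, i.e. replicate noise ≈ 5% of scale —
the regime in which dosage classification is claimed to be calibrated;
dosage-independent genes are constant-mean A-subgenome genes at the
ordinary dispersion (planting them on C would be meaningless: the
structural paternal zero makes any expressed C gene genuinely
dosage-tracking).

*ACRs.* 600 loci (55% shared, 10% novel, 5% silent, 10% SPA-M, 10% SPA-P,
10% TE-driven placed ≥60% inside a TE), widths 200–400 bp, replicate
peaks jittered ±30 bp so the >50 bp merge rule is genuinely exercised,
reads 5 + Poisson(25) where present and structurally absent elsewhere;
40 singleton-replicate noise peaks that must not survive merging. 60% of
novel loci are planted in transgressive-up promoters (cycling through the
gene list) to realize the novel-ACR/transgressive linkage.

*Methylome.* ~50,000 cytosines (CG/CHG/CHH at 30/30/40%), baselines
0.6/0.3/0.1, +0.25 inside TEs (capped 0.95), ×0.5 within 2 kb of genes;
coverage Poisson(30); binomial counts. 200 planted DMR bins (CG, half
hyper / half hypo) each carry 8 dedicated CG sites with both parents at a
common level and the hybrid shifted ±0.4.

*sRNA.* 300 background cluster loci with equal expected reads in the
hybrid and in-silico samples; at hyper-DMR bins the in-silico sample gets
2× the reads, at hypo-DMR bins the hybrid does; lengths 18–30 nt with
modes at 21 and 24.

What the generator does **not** emulate: read-level sequencing noise and
mapping bias (counts are drawn directly), homoeologous cross-mapping,
genome sequence (coordinates only, so no motif or conversion-rate
effects), biological correlation between layers beyond the explicitly
planted links, and replicate-level batch structure. Passing recovery
tests therefore demonstrates that the decision rules implement their
definitions and are calibrated under their stated noise models — not that
the thresholds are optimal for any particular real dataset.

## Problem sizes and runtime

The default simulation (800 genes, 600 ACR loci, ~50k cytosines, 200 DMR
bins, ~12k sRNA reads per sample) runs the full pipeline in well under a
minute on a single CPU; these sizes were chosen so the complete
generate-analyse-verify cycle stays interactive while every class retains
enough members (≥16) for stable recovery rates.

## Known limitations

* The NB test is intentionally minimal: no GLM covariates, no fold-change
  shrinkage, moment dispersion only; it is calibrated against its own null
  model, not guaranteed to match any full GLM framework gene-for-gene.
* Pearson p-values at n = 3 carry 1 df and are reported as computed; the
  per-genotype dosage mode inherits that near-zero power.
* One correlation-with-rank-test pairing in the source material
  ("R = 0.32, Kruskal–Wallis test") is ambiguous; the package reports
  Spearman rho with its own p-value for accessibility–expression links.
* DMR calling tests pooled counts per bin and ignores within-bin site
  heterogeneity; a beta-binomial model would be stricter under biological
  replication (pooled replicates are this design's input).
* sRNA clustering is positional only (no strandedness, no phasing, no
  miRNA annotation).
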
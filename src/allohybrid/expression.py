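"""Expression genetics of the allotriploid hybrid.

The hybrid (AAC) is compared against an *in-silico* mid-parent sample built
by mixing maternal (AACC) and paternal (AA) RNA-seq 1:1. Genes are then
classified on several axes:

* additivity — nonadditive when hybrid differs from the in-silico
  mid-parent (adjusted p < 0.05 and |log2FC| >= 1.5), additive otherwise;
* pattern — transgressive-up/down (hybrid significantly above/below both
  parents), expression-level dominance ELD-M / ELD-P (hybrid matches one
  parent while the parents differ), or other; parent contrasts use the
  stricter DEG rule (adjusted p < 0.05, |log2FC| >= 2);
* SPE — single parental expression: expressed (FPKM > 1) in exactly one
  parent and the hybrid, silent (FPKM < 0.1) in the other; A subgenome
  only, since the paternal AA line cannot express C-subgenome genes;
* dosage — expression tracking relative subgenome copy number across
  (maternal, hybrid, paternal) = (1/2, 2/3, 1) for A and (1/2, 1/3, 0) for
  C; dosage-dependent when r^2 > 0.64 with BH-adjusted Pearson p < 0.05.

Homolog pairs combine the A- and C-member dosage labels into the four
categories AdCd, AdCi, AiCd, AiCi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import (
    CorrelationResult,
    bh_adjust,
    median_of_ratios_size_factors,
    nb_test_matrix,
    pearson,
)

logger = logging.getLogger(__name__)

DOSAGE_A = (0.5, 2.0 / 3.0, 1.0)  # (maternal, hybrid, paternal), A subgenome
DOSAGE_C = (0.5, 1.0 / 3.0, 0.0)  # C subgenome: absent from the AA paternal line

ROLES = ("maternal", "paternal", "hybrid", "insilico")


@dataclass
class ExpressionTable:
    """Gene x sample raw counts with lengths and sample-role assignment."""

    counts: pd.DataFrame  # genes x sample columns, raw integer counts
    lengths: pd.Series  # bp per gene
    roles: dict[str, list[str]]  # role -> ordered replicate column names
    size_factors: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(sum(self.roles.values(), [])) - set(self.counts.columns)
        if missing:
            raise ValueError(f"role columns absent from counts: {sorted(missing)}")
        self.size_factors = pd.Series(
            median_of_ratios_size_factors(self.counts.values),
            index=self.counts.columns,
        )

    def columns(self, role: str) -> list[str]:
        if role not in self.roles:
            raise ValueError(f"missing sample role {role!r}")
        return self.roles[role]

    def raw(self, role: str) -> np.ndarray:
        return self.counts[self.columns(role)].values.astype(float)

    def normalized(self, role: str) -> np.ndarray:
        cols = self.columns(role)
        return self.counts[cols].values / self.size_factors[cols].values

    def fpkm(self, role: Optional[str] = None, raw_library: bool = False) -> pd.DataFrame:
        """FPKM per sample; by default on *effective* library sizes.

        The paternal AA line contributes no C-subgenome reads, so its raw
        library is compositionally smaller and naive per-total FPKM
        inflates every paternal A-gene value. Effective libraries
        (median-of-ratios size factor x the median raw depth) remove that
        bias; ``raw_library=True`` restores plain per-total FPKM.
        """
        cols = self.columns(role) if role else list(self.counts.columns)
        sub = self.counts[cols]
        if raw_library:
            return compute_fpkm(sub, self.lengths, sub.sum(axis=0))
        median_depth = float(self.counts.sum(axis=0).median())
        eff = self.size_factors[cols] * median_depth
        return compute_fpkm(sub, self.lengths, eff)


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM = count / (length in kb x library size in millions)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths.values / 1e3, lib / 1e6)
    return pd.DataFrame(
        counts.values / denom, index=counts.index, columns=counts.columns
    )


def expressed_mask(fpkm: pd.DataFrame) -> pd.Series:
    """Expressed gene rule: mean FPKM strictly above 1."""
    return fpkm.mean(axis=1) > 1.0


def build_insilico_hybrid(
    maternal_counts: np.ndarray,
    paternal_counts: np.ndarray,
    size_factors_maternal: Optional[np.ndarray] = None,
    size_factors_paternal: Optional[np.ndarray] = None,
    weight_maternal: float = 0.5,
) -> np.ndarray:
    """Mid-parent in-silico hybrid: per replicate pair, the 1:1 mixture of
    normalized parental counts, rounded to integers for count testing.

    Replicates are paired by index; when counts differ the surplus parent
    replicates are dropped (rank-order pairing) with a warning. The
    ``weight_maternal`` knob exists for sensitivity analysis only; 0.5 is
    the stated mixing rule.
    """
    M = np.atleast_2d(np.asarray(maternal_counts, dtype=float))
    P = np.atleast_2d(np.asarray(paternal_counts, dtype=float))
    if M.shape[0] != P.shape[0]:
        raise ValueError("parents must share the gene axis")
    if size_factors_maternal is not None:
        M = M / np.asarray(size_factors_maternal, dtype=float)
    if size_factors_paternal is not None:
        P = P / np.asarray(size_factors_paternal, dtype=float)
    n = min(M.shape[1], P.shape[1])
    if M.shape[1] != P.shape[1]:
        logger.warning(
            "parental replicate counts differ (%d vs %d); pairing first %d by rank order",
            M.shape[1],
            P.shape[1],
            n,
        )
    mix = weight_maternal * M[:, :n] + (1.0 - weight_maternal) * P[:, :n]
    return np.rint(mix).astype(np.int64)


def classify_additivity(
    hybrid_counts: np.ndarray,
    insilico_counts: np.ndarray,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    size_factors_hybrid: Optional[np.ndarray] = None,
    size_factors_insilico: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Additive vs nonadditive-up/down, hybrid against the in-silico MPV.

    Fold change is hybrid over in-silico, so nonadditive-up means the
    hybrid exceeds the mid-parent expectation.
    """
    lfc, p = nb_test_matrix(
        insilico_counts, hybrid_counts, size_factors_insilico, size_factors_hybrid
    )
    padj = bh_adjust(p)
    label = np.where(
        (padj < alpha) & (np.abs(lfc) >= lfc_threshold),
        np.where(lfc > 0, "nonadditive-up", "nonadditive-down"),
        "additive",
    )
    return pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": p, "adjusted_p": padj, "additivity": label}
    )


def _deg_call(
    counts_ref: np.ndarray,
    counts_alt: np.ndarray,
    lfc_threshold: float,
    alpha: float,
    sf_ref: Optional[np.ndarray] = None,
    sf_alt: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(direction, lfc): +1 alt above ref, -1 below, 0 not differential."""
    lfc, p = nb_test_matrix(counts_ref, counts_alt, sf_ref, sf_alt)
    padj = bh_adjust(p)
    sig = (padj < alpha) & (np.abs(lfc) >= lfc_threshold)
    return np.where(sig, np.sign(lfc), 0).astype(int), lfc


def classify_pattern(
    hybrid_counts: np.ndarray,
    maternal_counts: np.ndarray,
    paternal_counts: np.ndarray,
    additivity: Sequence[str],
    lfc_deg: float = 2.0,
    alpha: float = 0.05,
    size_factors: Optional[dict[str, np.ndarray]] = None,
    subgenome: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Expression pattern of each gene in the hybrid relative to its parents.

    transgressive-up/down: hybrid significantly above/below *both* parents;
    ELD-M: hybrid indistinguishable from the maternal parent, differential
    against the paternal one, with the parents themselves differing; ELD-P
    mirrored. Genes whose additivity label is 'additive' stay additive;
    unresolved combinations are 'other'. Parent contrasts use the DEG rule
    (|log2FC| >= 2, adjusted p < 0.05). ``size_factors`` may carry per-role
    arrays under keys 'hybrid', 'maternal', 'paternal'.

    When ``subgenome`` is given, paternal contrasts of C-subgenome genes
    are suppressed: the AA paternal line carries no C subgenome, so every
    expressed C gene would otherwise read as spurious maternal dominance.
    C genes can therefore only be 'additive' or 'other'.
    """
    sf = size_factors or {}
    hm, lfc_hm = _deg_call(
        maternal_counts, hybrid_counts, lfc_deg, alpha, sf.get("maternal"), sf.get("hybrid")
    )
    hp, lfc_hp = _deg_call(
        paternal_counts, hybrid_counts, lfc_deg, alpha, sf.get("paternal"), sf.get("hybrid")
    )
    mp, _ = _deg_call(
        paternal_counts, maternal_counts, lfc_deg, alpha, sf.get("paternal"), sf.get("maternal")
    )
    additivity = np.asarray(additivity)
    n = additivity.size
    if subgenome is not None:
        is_c = np.asarray(subgenome) == "C"
        hp[is_c] = 0
        mp[is_c] = 0
    pattern = np.full(n, "other", dtype=object)
    trans_up = (hm == 1) & (hp == 1)
    trans_down = (hm == -1) & (hp == -1)
    eld_m = (hm == 0) & (hp != 0) & (mp != 0)
    eld_p = (hp == 0) & (hm != 0) & (mp != 0)
    pattern[eld_m] = "ELD-M"
    pattern[eld_p] = "ELD-P"
    pattern[trans_up] = "transgressive-up"
    pattern[trans_down] = "transgressive-down"
    # contrasts take precedence: a hybrid matching one parent exactly can
    # never clear the MPV fold rule (H/MPV <= 2), yet is a dominance case
    pattern[(pattern == "other") & (additivity == "additive")] = "additive"
    return pd.DataFrame(
        {
            "pattern": pattern,
            "lfc_hybrid_vs_maternal": lfc_hm,
            "lfc_hybrid_vs_paternal": lfc_hp,
        }
    )


def call_spe(
    fpkm_maternal: np.ndarray,
    fpkm_paternal: np.ndarray,
    fpkm_hybrid: np.ndarray,
    subgenome: Sequence[str],
    expressed_threshold: float = 1.0,
    silent_threshold: float = 0.1,
) -> pd.DataFrame:
    """Single-parental-expression labels per gene.

    SPE-M: every maternal and hybrid replicate expressed (FPKM strictly
    above ``expressed_threshold``) while every paternal replicate is silent
    (FPKM below ``silent_threshold``); SPE-P mirrored. Restricted to the A
    subgenome — C-subgenome genes get 'none' with reason
    'C-subgenome-uninformative' because the paternal AA parent cannot
    express them.
    """
    M = np.atleast_2d(np.asarray(fpkm_maternal, dtype=float))
    P = np.atleast_2d(np.asarray(fpkm_paternal, dtype=float))
    H = np.atleast_2d(np.asarray(fpkm_hybrid, dtype=float))
    sg = np.asarray(subgenome)

    def expr(x: np.ndarray) -> np.ndarray:
        return np.all(x > expressed_threshold, axis=1)

    def silent(x: np.ndarray) -> np.ndarray:
        return np.all(x < silent_threshold, axis=1)

    label = np.full(sg.size, "none", dtype=object)
    reason = np.full(sg.size, "", dtype=object)
    is_a = sg == "A"
    spe_m = is_a & expr(M) & silent(P) & expr(H)
    spe_p = is_a & expr(P) & silent(M) & expr(H)
    label[spe_m] = "SPE-M"
    label[spe_p] = "SPE-P"
    reason[~is_a] = "C-subgenome-uninformative"
    return pd.DataFrame({"spe": label, "reason": reason})


def dosage_dependence(
    expression: Sequence[float],
    dosage: Sequence[float],
    r2_threshold: float = 0.64,
    alpha: float = 0.05,
    adjusted_p: Optional[float] = None,
) -> tuple[CorrelationResult, str]:
    """Dosage call for one gene from paired dosage/expression vectors.

    Expression order must match the dosage vector order (maternal, hybrid,
    paternal; replicate-expanded vectors are accepted). The gene is
    'dependent' iff r^2 strictly exceeds ``r2_threshold`` and the
    (BH-adjusted, when supplied) p-value is below ``alpha``. Zero-variance
    expression is 'independent'.
    """
    expr = np.asarray(expression, dtype=float)
    dose = np.asarray(dosage, dtype=float)
    if expr.shape != dose.shape:
        raise ValueError("expression and dosage lengths differ")
    res = pearson(dose, expr)
    if adjusted_p is not None:
        res.adjusted_p = adjusted_p
    if res.undefined:
        return res, "independent"
    p_eff = res.adjusted_p if res.adjusted_p is not None else res.p_value
    dependent = res.r_squared > r2_threshold and p_eff < alpha
    return res, "dependent" if dependent else "independent"


def classify_dosage(
    fpkm_maternal: np.ndarray,
    fpkm_hybrid: np.ndarray,
    fpkm_paternal: np.ndarray,
    subgenome: Sequence[str],
    r2_threshold: float = 0.64,
    alpha: float = 0.05,
    per_genotype: bool = False,
) -> pd.DataFrame:
    """Genome-wide dosage classification with genome-wide BH adjustment.

    Replicate-level values (each replicate contributes one point at its
    genotype's dosage) are the default; ``per_genotype=True`` collapses to
    the three genotype means, which with 1 df makes significance very hard
    to reach and is kept only for comparability.
    """
    M = np.atleast_2d(np.asarray(fpkm_maternal, dtype=float))
    H = np.atleast_2d(np.asarray(fpkm_hybrid, dtype=float))
    P = np.atleast_2d(np.asarray(fpkm_paternal, dtype=float))
    sg = np.asarray(subgenome)
    n_genes = sg.size
    rs = np.full(n_genes, np.nan)
    ps = np.ones(n_genes)
    undefined = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        dose3 = DOSAGE_A if sg[i] == "A" else DOSAGE_C
        if per_genotype:
            x = np.asarray(dose3)
            y = np.array([M[i].mean(), H[i].mean(), P[i].mean()])
        else:
            x = np.concatenate(
                [np.full(M.shape[1], dose3[0]), np.full(H.shape[1], dose3[1]), np.full(P.shape[1], dose3[2])]
            )
            y = np.concatenate([M[i], H[i], P[i]])
        res = pearson(x, y)
        rs[i], undefined[i] = res.r, res.undefined
        ps[i] = 1.0 if res.undefined else res.p_value
    padj = bh_adjust(ps)
    r2 = rs**2
    dependent = (~undefined) & (r2 > r2_threshold) & (padj < alpha)
    return pd.DataFrame(
        {
            "r": rs,
            "r_squared": r2,
            "p_value": ps,
            "adjusted_p": padj,
            "dosage": np.where(dependent, "dependent", "independent"),
            "subgenome": sg,
        }
    )


def homolog_categories(
    dosage_labels: pd.Series, homolog_pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Cross A/C dosage labels per homolog pair: AdCd, AdCi, AiCd, AiCi.

    Pairs naming unknown genes are skipped with a log entry; genes absent
    from any pair are the caller's 'genome-unique' set.
    """
    rows = []
    for a_id, c_id in homolog_pairs:
        if a_id not in dosage_labels.index or c_id not in dosage_labels.index:
            logger.warning("homolog pair (%s, %s) references unknown gene; skipped", a_id, c_id)
            continue
        a_dep = dosage_labels[a_id] == "dependent"
        c_dep = dosage_labels[c_id] == "dependent"
        cat = ("Ad" if a_dep else "Ai") + ("Cd" if c_dep else "Ci")
        rows.append((a_id, c_id, cat))
    return pd.DataFrame(rows, columns=["a_gene", "c_gene", "category"])
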
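"""Statistical kernel shared by all pipeline stages.

The negative-binomial two-group test is a deliberately simple stand-in for
a full GLM-based differential framework: median-of-ratios normalization,
method-of-moments dispersion floored at a fitted mean-dispersion trend, and
and a Wald z test on the log2 ratio of group means (pseudocount 0.5). The
trend floor absorbs the small-sample noise of the moment estimator, which
is what keeps the plain normal reference honest at 3-vs-3. It is validated
by Monte-Carlo calibration on NB null data rather than by agreement with
any external tool.

Everything else delegates to scipy/statsmodels: Fisher's exact test,
Pearson correlation, Wilcoxon rank-sum / Kruskal-Wallis, and the
Benjamini-Hochberg step-up. A vectorized two-sided hypergeometric test
(`fisher_exact_many`) serves the bulk per-bin/per-cytosine methylation
calls where a Python-level loop over scipy would dominate runtime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "CorrelationResult",
    "bh_adjust",
    "pearson",
    "spearman",
    "fisher_exact_2x2",
    "fisher_exact_many",
    "rank_tests",
    "nb_two_group_test",
    "nb_test_matrix",
    "median_of_ratios_size_factors",
    "FuzzyCMeans",
    "fuzzy_cmeans",
]


@dataclass
class TestResult:
    statistic: float
    log2_fold_change: float
    p_value: float
    adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    undefined: bool = False
    adjusted_p: Optional[float] = None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with two-sided t-based p (n-2 df).

    Zero-variance input yields an undefined-flagged result (r = nan, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), 1.0, n, undefined=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p), n)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (used for accessibility-expression links)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), 1.0, n, undefined=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(rho) ** 2, float(p), n)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The statistic is the odds ratio with a Haldane 0.5 correction applied
    when any cell is zero; log2_fold_change is log2 of that odds ratio.
    """
    for cell in (a, b, c, d):
        if cell < 0 or int(cell) != cell:
            raise ValueError("cells must be non-negative integers")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return TestResult(statistic=odds, log2_fold_change=math.log2(odds), p_value=float(p))


def fisher_exact_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for many 2x2 tables.

    Enumerates the hypergeometric support of each table and sums the
    probabilities of tables no more likely than the observed one (relative
    tie tolerance 1+1e-7, as in scipy). Intended for per-bin / per-cytosine
    methylation testing where table counts are modest (<~1000).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(np.stack([a, b, c, d]) < 0):
        raise ValueError("cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n_tot = r1 + r2
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    width = int(np.max(hi - lo + 1)) if a.size else 0
    if width == 0:
        return np.ones_like(a, dtype=float)
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    kk = np.where(valid, k, lo[:, None])
    pmf = sps.hypergeom.pmf(kk, n_tot[:, None], r1[:, None], c1[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = sps.hypergeom.pmf(a, n_tot, r1, c1)
    p = np.sum(np.where(pmf <= obs[:, None] * (1 + 1e-7), pmf, 0.0), axis=1)
    return np.minimum(p, 1.0)


def rank_tests(groups: Sequence[Sequence[float]]) -> TestResult:
    """Wilcoxon rank-sum for two groups, Kruskal-Wallis for three or more.

    The two-group test is exact for small tie-free samples (n <= 25 per
    group) and the tie/continuity-corrected normal approximation otherwise;
    a statistic exactly at its null center reports p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(arr.size == 0 for arr in arrays):
        raise ValueError("all groups must be non-empty")
    if len(arrays) == 2:
        x, y = arrays
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(res.pvalue)
        if abs(u - x.size * y.size / 2) < 1e-12:
            p = 1.0
        return TestResult(statistic=u, log2_fold_change=float("nan"), p_value=p)
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), log2_fold_change=float("nan"), p_value=float(p))


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference per gene).

    Falls back to total-count scaling (normalized to mean 1) with a warning
    when no gene is nonzero in every sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        logger.warning(
            "no gene with nonzero counts in all samples; using total-count scaling"
        )
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("sample with zero total counts")
        return totals / np.exp(np.mean(np.log(totals)))
    sub = counts[allpos]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return factors


def _fit_dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mean on informative genes."""
    keep = (mean > 0) & (alpha_mom > 0)
    if keep.sum() < 20:
        return 0.01, 0.0
    x = 1.0 / mean[keep]
    y = alpha_mom[keep]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def nb_test_matrix(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: Optional[np.ndarray] = None,
    size_factors_b: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB Wald test over a genes x replicates count matrix pair.

    Returns (log2_fold_change, p_value) arrays; the fold change is group B
    over group A. Genes with all-zero counts in both groups get (0, 1).
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("count matrices must have the same number of genes")
    na, nb = A.shape[1], B.shape[1]
    sfa = np.ones(na) if size_factors_a is None else np.asarray(size_factors_a, dtype=float)
    sfb = np.ones(nb) if size_factors_b is None else np.asarray(size_factors_b, dtype=float)
    if np.any(sfa <= 0) or np.any(sfb <= 0):
        raise ValueError("size factors must be positive")
    An, Bn = A / sfa, B / sfb
    mean_a, mean_b = An.mean(axis=1), Bn.mean(axis=1)

    # Pooled within-group moment dispersion, floored at a fitted 1/mean trend.
    var_a = An.var(axis=1, ddof=1) if na > 1 else np.zeros(A.shape[0])
    var_b = Bn.var(axis=1, ddof=1) if nb > 1 else np.zeros(B.shape[0])
    df_pool = max(na - 1, 0) + max(nb - 1, 0)
    pooled_var = (max(na - 1, 0) * var_a + max(nb - 1, 0) * var_b) / max(df_pool, 1)
    grand_mean = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(
            grand_mean > 0, (pooled_var - grand_mean) / grand_mean**2, 0.0
        )
    alpha_mom = np.clip(alpha_mom, 0.0, 10.0)
    a0, a1 = _fit_dispersion_trend(grand_mean, alpha_mom)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(grand_mean > 0, grand_mean, np.inf)
    # moderate the noisy 2x3-replicate moment estimate: floored at the
    # trend, capped at 4x trend so one outlier variance cannot zero power
    alpha = np.clip(alpha_mom, trend, 4.0 * trend)

    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    inv_sf_a, inv_sf_b = np.mean(1.0 / sfa), np.mean(1.0 / sfb)
    var_mean_a = (mean_a * inv_sf_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b * inv_sf_b + alpha * mean_b**2) / nb
    ln2sq = math.log(2) ** 2
    se = np.sqrt(
        var_mean_a / (mean_a + pseudocount) ** 2 / ln2sq
        + var_mean_b / (mean_b + pseudocount) ** 2 / ln2sq
    )
    both_zero = (mean_a == 0) & (mean_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(both_zero, 1.0, np.minimum(p, 1.0))
    lfc = np.where(both_zero, 0.0, lfc)
    return lfc, p


def nb_two_group_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    size_factors: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> TestResult:
    """NB two-group test for one gene (see `nb_test_matrix` for batches)."""
    sfa = sfb = None
    if size_factors is not None:
        sfa, sfb = (np.asarray(s, dtype=float) for s in size_factors)
    lfc, p = nb_test_matrix(
        np.asarray(counts_a, dtype=float)[None, :],
        np.asarray(counts_b, dtype=float)[None, :],
        sfa,
        sfb,
    )
    return TestResult(statistic=float(lfc[0]), log2_fold_change=float(lfc[0]), p_value=float(p[0]))


class FuzzyCMeans:
    """Bezdek fuzzy c-means clustering, sklearn-style.

    Parameters
    ----------
    n_clusters : number of clusters (k >= 2).
    m : fuzzifier (> 1); 2 is the conventional default.
    tol : convergence threshold on the maximum center shift.
    max_iter : iteration cap.
    random_state : seed for the membership initialization.

    Fitted attributes carry the trailing-underscore convention:
    ``cluster_centers_``, ``memberships_``, ``labels_``, ``n_iter_``,
    ``objective_history_`` (non-increasing by construction).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "m": self.m,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "FuzzyCMeans":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _memberships_from_centers(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = np.maximum(
            ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 1e-300
        )
        exponent = 1.0 / (self.m - 1.0)
        inv = d2 ** (-exponent)
        return inv / inv.sum(axis=1, keepdims=True)

    def fit(self, X: np.ndarray) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (items x features)")
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if X.shape[0] < k:
            raise ValueError("need at least n_clusters items")
        rng = np.random.default_rng(self.random_state)
        U = rng.random((X.shape[0], k))
        U /= U.sum(axis=1, keepdims=True)
        history: list[float] = []
        centers = np.zeros((k, X.shape[1]))
        for it in range(1, self.max_iter + 1):
            Um = U**self.m
            centers_new = (Um.T @ X) / Um.sum(axis=0)[:, None]
            U = self._memberships_from_centers(X, centers_new)
            d2 = ((X[:, None, :] - centers_new[None, :, :]) ** 2).sum(axis=2)
            history.append(float((U**self.m * d2).sum()))
            shift = float(np.max(np.abs(centers_new - centers))) if it > 1 else np.inf
            centers = centers_new
            if shift < self.tol:
                break
        self.cluster_centers_ = centers
        self.memberships_ = U
        self.labels_ = np.argmax(U, axis=1)
        self.n_iter_ = it
        self.objective_history_ = history
        return self

    def fit_predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_memberships(X), axis=1)

    def predict_memberships(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("estimator is not fitted")
        return self._memberships_from_centers(np.asarray(X, dtype=float), self.cluster_centers_)


@dataclass
class FuzzyClustering:
    """Result of fuzzy c-means on z-scored signal profiles."""

    k: int
    m: float
    memberships: np.ndarray
    centers: np.ndarray
    labels: np.ndarray  # hard labels "C1".."Ck"
    kept_rows: np.ndarray  # indices of non-constant input rows
    objective_history: list[float] = field(default_factory=list)


def fuzzy_cmeans(
    profiles: np.ndarray,
    k: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> FuzzyClustering:
    """Fuzzy c-means on row-z-scored profiles; clusters are labeled C1..Ck.

    Constant rows carry no shape information and are dropped (with a logged
    warning) before z-scoring.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be 2-D")
    sd = X.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[0]:
        logger.warning("dropping %d constant profile row(s)", X.shape[0] - kept.size)
    Z = (X[kept] - X[kept].mean(axis=1, keepdims=True)) / sd[kept][:, None]
    est = FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter, random_state=seed).fit(Z)
    labels = np.array([f"C{i + 1}" for i in est.labels_])
    return FuzzyClustering(
        k=k,
        m=m,
        memberships=est.memberships_,
        centers=est.cluster_centers_,
        labels=labels,
        kept_rows=kept,
        objective_history=est.objective_history_,
    )
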
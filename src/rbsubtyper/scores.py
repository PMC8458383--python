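"""Association tests, differential-feature calling and per-sample scores.

Contingency-table tests (chi-squared without continuity correction,
two-sided Fisher exact, Kruskal-Wallis), BH correction, hypergeometric
enrichment, and the per-sample signature scores used to characterize the
subtypes: a Spearman-correlation stemness index, single-sample GSEA
(ssGSEA) enrichment scores, standardized pathway meta-scores and the
immunohistochemistry quick score.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import OmicsMatrix


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return arr


def chi2_test(table) -> Tuple[float, int, float]:
    """Pearson chi-squared test without continuity correction."""
    arr = _as_table(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi2_test requires at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def fisher_exact_2x2(table, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is at most ``(1 + rel_tol)`` times the
    probability of the observed table.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    a = arr.astype(int)
    if not np.array_equal(a, arr):
        raise ValueError("counts must be integers")
    r1, r2 = a.sum(axis=1)
    c1, _c2 = a.sum(axis=0)
    n = a.sum()
    if n == 0:
        return 1.0
    kmin = max(0, r1 - (n - c1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a[0, 0], n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def kruskal_wallis(groups: Sequence[Sequence[float]]
                   ) -> Tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction against a chi-squared reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    total = np.concatenate(groups)
    if total.size < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1
    if np.all(total == total[0]):
        warnings.warn("all values identical; H = 0")
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), df, float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(matrix: OmicsMatrix, labels: pd.Series,
                          test: str = "auto",
                          p_adj_threshold: float = 0.05,
                          delta_threshold: float = 0.0,
                          delta_stat: str = "mean") -> pd.DataFrame:
    """Per-feature two-class test with BH correction and effect-size filter.

    ``test='auto'`` uses the Wilcoxon rank-sum test for beta values and
    Welch's t for expression.  A feature is significant when its adjusted
    p-value is below ``p_adj_threshold`` AND \\|delta\\| exceeds
    ``delta_threshold`` (delta = class-2 minus class-1 mean, or median
    with ``delta_stat='median'``).
    """
    labels = labels.reindex(matrix.samples)
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError("differential_features requires exactly 2 classes")
    m1 = (labels == classes[0]).to_numpy()
    m2 = (labels == classes[1]).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    if test == "auto":
        test = "wilcoxon" if matrix.omics == "methylation-beta" else "welch"
    X = matrix.values.to_numpy(dtype=float)
    A, B = X[:, m1], X[:, m2]
    if delta_stat == "mean":
        delta = B.mean(axis=1) - A.mean(axis=1)
    elif delta_stat == "median":
        delta = np.median(B, axis=1) - np.median(A, axis=1)
    else:
        raise ValueError("delta_stat must be 'mean' or 'median'")
    if test == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    elif test == "wilcoxon":
        p = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            if np.all(A[i] == A[i][0]) and np.all(B[i] == A[i][0]):
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(A[i], B[i],
                                          alternative="two-sided").pvalue
    else:
        raise ValueError("test must be 'auto', 'welch' or 'wilcoxon'")
    p_adj = bh_adjust(p)
    out = pd.DataFrame({
        "delta": delta,
        "direction": np.where(delta > 0, "up", np.where(delta < 0, "down", "none")),
        "p": p, "p_adj": p_adj,
        "significant": (p_adj < p_adj_threshold) & (np.abs(delta) > delta_threshold),
    }, index=matrix.features)
    return out


def hypergeometric_enrichment(query: Iterable, annotated: Iterable,
                              universe_size: int) -> float:
    """Upper-tail probability of at least the observed query/set overlap."""
    q, a = set(query), set(annotated)
    if len(q) > universe_size or len(a) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(q & a)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(q)))


def stemness_index(matrix: OmicsMatrix, weights: pd.Series) -> pd.Series:
    """Spearman-correlation stemness index, min-max scaled to [0, 1].

    Genes are mean-centered across samples; each sample's centered
    profile is Spearman-correlated with the signature weight vector over
    shared genes; the correlations are scaled to [0, 1] over the cohort.
    """
    if weights.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in the weight vector")
    shared = [g for g in weights.index if g in matrix.features]
    if len(shared) < 10:
        raise ValueError("need at least 10 signature genes present")
    X = matrix.values.loc[shared]
    Xc = X.sub(X.mean(axis=1), axis=0)
    w = weights.loc[shared].to_numpy(dtype=float)
    corrs = {}
    for s in matrix.samples:
        rho, _ = stats.spearmanr(Xc[s].to_numpy(), w)
        corrs[s] = float(rho)
    raw = pd.Series(corrs, name="stemness")
    if matrix.n_samples < 2:
        warnings.warn("single sample: returning raw correlation, unscaled")
        return raw
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all samples identical; stemness indices set to 0")
        return raw * 0.0
    return (raw - lo) / (hi - lo)


def _ssgsea_single(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    order = np.argsort(-expr, kind="stable")
    hit = in_set[order]
    n = expr.size
    ranks = np.arange(n, 0, -1, dtype=float)  # rank weight, highest first
    w = ranks ** alpha
    hit_w = np.where(hit, w, 0.0)
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        return 0.0
    P_hit = np.cumsum(hit_w) / denom_hit
    miss = ~hit
    P_miss = np.cumsum(miss) / max(int(miss.sum()), 1)
    return float(np.sum(P_hit - P_miss))


def ssgsea_score(matrix: OmicsMatrix, gene_set: Iterable[str],
                 alpha: float = 0.25, normalize: bool = True) -> pd.Series:
    """Single-sample GSEA enrichment scores for one gene set.

    Genes are ranked by expression within each sample; the score is the
    integrated difference between the rank-weighted in-set cumulative
    distribution (weight rank^alpha) and the uniform out-of-set one.
    With ``normalize`` the cohort's scores are divided by their range.
    """
    genes = matrix.features
    in_set = np.asarray(genes.isin(set(gene_set)))
    if int(in_set.sum()) < 5:
        raise ValueError("need at least 5 gene-set genes present")
    X = matrix.values.to_numpy(dtype=float)
    scores = {s: _ssgsea_single(X[:, j], in_set, alpha)
              for j, s in enumerate(matrix.samples)}
    out = pd.Series(scores, name="ssgsea")
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def meta_score(matrix: OmicsMatrix, gene_set: Iterable[str]) -> pd.Series:
    """Mean expression of a gene set per sample, z-scored across the cohort."""
    present = [g for g in gene_set if g in matrix.features]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    raw = matrix.values.loc[present].mean(axis=0)
    sd = raw.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance across samples; meta-scores set to 0")
        return raw * 0.0
    return (raw - raw.mean()) / sd


def quick_score(intensity: Union[int, float],
                percent: Union[int, float]) -> float:
    """Immunohistochemistry quick score QS = I x P, range 0-300."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be one of {0, 1, 2, 3}")
    if not 0 <= percent <= 100:
        raise ValueError("percent positive cells must lie in [0, 100]")
    return float(intensity) * float(percent)


def association_report(clinical: pd.DataFrame, subtype: pd.Series,
                       categorical: Optional[Sequence[str]] = None,
                       continuous: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Chi-squared / Kruskal-Wallis association of covariates with subtype."""
    subtype = subtype.reindex(clinical.index).dropna()
    clin = clinical.loc[subtype.index]
    if categorical is None:
        categorical = [c for c in clin.columns
                       if clin[c].dtype == object and c != "subtype"]
    if continuous is None:
        continuous = [c for c in clin.columns
                      if np.issubdtype(clin[c].dtype, np.number)
                      and c != "subtype"]
    rows = []
    for c in categorical:
        ct = pd.crosstab(clin[c], subtype)
        stat, df, p = chi2_test(ct.to_numpy())
        rows.append({"covariate": c, "test": "chi2", "statistic": stat,
                     "df": df, "p": p})
    for c in continuous:
        groups = [clin.loc[subtype == s, c].dropna().to_numpy()
                  for s in sorted(subtype.unique())]
        H, df, p = kruskal_wallis(groups)
        rows.append({"covariate": c, "test": "kruskal", "statistic": H,
                     "df": df, "p": p})
    return pd.DataFrame(rows).set_index("covariate")
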
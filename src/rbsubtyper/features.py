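"""Feature selection for consensus clustering.

Two filters are combined: a robust coefficient of variation (rCV) ladder
over a decreasing list of percentile thresholds, and a one-sided variance
test against the median feature variance.  An ICA-based stromal filter
removes genes dominated by stromal contamination before clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .matrix import OmicsMatrix

DEFAULT_RCV_PERCENTILES = (99.5, 99.0, 97.5, 95.0, 90.0, 80.0, 70.0, 60.0)
CNA_RCV_PERCENTILES = (80.0, 75.0, 70.0, 65.0, 60.0, 55.0, 52.5, 50.0)


@dataclass
class FeatureSelectConfig:
    rcv_percentiles: Sequence[float] = DEFAULT_RCV_PERCENTILES
    variance_p_threshold: float = 0.01
    rcv_kind: str = "mad"  # "mad" (MAD/|median|) or "iqr" (IQR/|median|)

    def __post_init__(self) -> None:
        ps = list(self.rcv_percentiles)
        if any(not (0 < p < 100) for p in ps):
            raise ValueError("rcv_percentiles must lie in (0, 100)")
        if any(b >= a for a, b in zip(ps, ps[1:])):
            raise ValueError("rcv_percentiles must be strictly decreasing")
        if self.rcv_kind not in ("mad", "iqr"):
            raise ValueError("rcv_kind must be 'mad' or 'iqr'")


@dataclass
class StromalFilterConfig:
    n_components: int = 3
    contribution_threshold: float = 2.5
    stromal_marker_set: Sequence[str] = ()
    enrichment_p_threshold: float = 1e-3
    max_retries: int = 5

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.contribution_threshold <= 0:
            raise ValueError("contribution_threshold must be positive")


def robust_cv(matrix: OmicsMatrix, kind: str = "mad",
              eps: float = 1e-8) -> pd.Series:
    """Robust coefficient of variation per feature: MAD / max(|median|, eps).

    ``kind='iqr'`` substitutes the interquartile range for the MAD.
    """
    if matrix.n_samples < 2:
        raise ValueError("robust_cv requires at least 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    med = np.median(X, axis=1)
    if kind == "mad":
        disp = np.median(np.abs(X - med[:, None]), axis=1)
    elif kind == "iqr":
        q1, q3 = np.percentile(X, [25, 75], axis=1)
        disp = q3 - q1
    else:
        raise ValueError("kind must be 'mad' or 'iqr'")
    score = disp / np.maximum(np.abs(med), eps)
    return pd.Series(score, index=matrix.features, name="rcv")


def variance_test(matrix: OmicsMatrix) -> pd.Series:
    """One-sided chi-squared test of H0: feature variance = median variance.

    Statistic (n-1) s^2 / sigma0^2 with sigma0^2 the median of the
    per-feature sample variances; upper-tail p-value on n-1 df.
    """
    n = matrix.n_samples
    if n < 3:
        raise ValueError("variance_test requires at least 3 samples")
    s2 = matrix.values.var(axis=1, ddof=1).to_numpy()
    sigma0 = float(np.median(s2))
    if sigma0 <= 0:
        # degenerate matrix: every feature at/below the all-zero median
        p = np.where(s2 > 0, 0.0, 1.0)
    else:
        stat = (n - 1) * s2 / sigma0
        p = stats.chi2.sf(stat, df=n - 1)
    return pd.Series(p, index=matrix.features, name="variance_p")


def select_features(matrix: OmicsMatrix,
                    config: FeatureSelectConfig,
                    percentile: float,
                    rcv_scores: Optional[pd.Series] = None,
                    variance_p: Optional[pd.Series] = None) -> List[str]:
    """Features with rCV >= the given percentile AND variance-test p < threshold."""
    if rcv_scores is None:
        rcv_scores = robust_cv(matrix, kind=config.rcv_kind)
    if variance_p is None:
        variance_p = variance_test(matrix)
    thr = np.percentile(rcv_scores.to_numpy(), percentile)
    mask = (rcv_scores >= thr) & (variance_p < config.variance_p_threshold)
    out = list(matrix.features[mask.to_numpy()])
    if not out:
        warnings.warn(f"no feature passed selection at percentile {percentile}")
    return out


def feature_subsets(matrix: OmicsMatrix,
                    config: Optional[FeatureSelectConfig] = None
                    ) -> List[List[str]]:
    """Nested subsets for the rCV percentile ladder (largest last)."""
    config = config or FeatureSelectConfig()
    rcv = robust_cv(matrix, kind=config.rcv_kind)
    vp = variance_test(matrix)
    return [select_features(matrix, config, p, rcv, vp)
            for p in config.rcv_percentiles]


def stromal_filter_ica(matrix: OmicsMatrix,
                       config: StromalFilterConfig,
                       seed: int = 0
                       ) -> Tuple[OmicsMatrix, List[str], pd.DataFrame]:
    """Remove genes dominated by a stromal-contamination independent component.

    Fits a deflation-based ICA in ``n_components`` components on the
    gene x sample matrix; per component, gene loadings are z-scored and
    the two tails beyond ``contribution_threshold`` are tested for
    hypergeometric enrichment of the stromal marker set.  Genes in any
    significantly enriched tail are removed.
    """
    markers = set(config.stromal_marker_set)
    if not markers:
        raise ValueError("stromal_marker_set is empty; enrichment is undefined")
    if matrix.n_samples <= config.n_components:
        raise ValueError("need more samples than ICA components")
    X = matrix.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)

    S = None
    last_err: Optional[Exception] = None
    for attempt in range(config.max_retries):
        ica = FastICA(n_components=config.n_components, algorithm="deflation",
                      random_state=seed + attempt, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(Xc)  # genes x components
                break
            except (ConvergenceWarning, ValueError) as err:
                last_err = err
                S = None
    if S is None:
        raise RuntimeError(f"ICA failed to converge after retries: {last_err}")

    genes = matrix.features
    universe = len(genes)
    marker_mask = np.asarray(genes.isin(markers))
    n_markers = int(marker_mask.sum())
    report_rows = []
    removed: set = set()
    for c in range(S.shape[1]):
        z = (S[:, c] - S[:, c].mean()) / S[:, c].std(ddof=0)
        for sign, tail in (("+", z > config.contribution_threshold),
                           ("-", z < -config.contribution_threshold)):
            k = int((tail & marker_mask).sum())
            n_tail = int(tail.sum())
            if n_tail == 0 or n_markers == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k - 1, universe, n_markers, n_tail))
            enriched = p < config.enrichment_p_threshold
            if enriched:
                removed.update(genes[tail])
            report_rows.append({"component": c + 1, "sign": sign,
                                "n_tail": n_tail, "n_markers_in_tail": k,
                                "p_enrichment": p, "enriched": enriched})
    report = pd.DataFrame(report_rows)
    keep = [g for g in genes if g not in removed]
    return matrix.subset(keep), sorted(removed), report
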
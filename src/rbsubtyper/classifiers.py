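"""Nearest-centroid subtype classifiers.

Transcriptome and methylome centroids are the per-class feature-wise
medians of the most differentially expressed/methylated features (400
genes or 5000 CpGs per direction at the study's scale).  Queries are
assigned by best Pearson correlation, subject to a minimum-correlation
threshold below which a sample is left unclassified.  A two-stage
selection yields a minimal CpG panel for assay-based classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix

UNCLASSIFIED = "unclassified"


@dataclass
class CentroidModel:
    classes: List                       # e.g. [1, 2]
    features: List[str]
    centroids: pd.DataFrame             # features x classes (median profiles)
    threshold: float = 0.1              # minimum Pearson correlation
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (-1, 1)")
        if list(self.centroids.index) != list(self.features):
            raise ValueError("centroid rows must match the feature list")


def _rank_two_sample(X: pd.DataFrame, mask1: np.ndarray, mask2: np.ndarray,
                     ranking: str) -> Tuple[np.ndarray, np.ndarray]:
    """Two-sided p-values and class-2-minus-class-1 mean differences."""
    A = X.to_numpy(dtype=float)[:, mask1]
    B = X.to_numpy(dtype=float)[:, mask2]
    delta = B.mean(axis=1) - A.mean(axis=1)
    if ranking == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    elif ranking == "ranksum":
        p = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            if np.all(A[i] == A[i][0]) and np.all(B[i] == A[i][0]):
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(A[i], B[i],
                                          alternative="two-sided").pvalue
    else:
        raise ValueError("ranking must be 'welch' or 'ranksum'")
    return p, delta


def build_centroids(matrix: OmicsMatrix, labels: pd.Series,
                    n_top_per_side: int = 400, ranking: str = "welch",
                    threshold: float = 0.1) -> CentroidModel:
    """Per-class median centroids over the most differential features.

    Features are ranked by two-sided two-sample p-value separately within
    each direction of change; the top ``n_top_per_side`` per direction are
    retained (ties broken by larger \\|delta\\|, then feature identifier).
    """
    labels = labels.reindex(matrix.samples)
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError("build_centroids requires exactly 2 classes")
    mask1 = (labels == classes[0]).to_numpy()
    mask2 = (labels == classes[1]).to_numpy()
    if mask1.sum() < 3 or mask2.sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    p, delta = _rank_two_sample(matrix.values, mask1, mask2, ranking)
    if np.all(p >= 1.0):
        warnings.warn("no feature separates the classes (zero-signal model)")
    tbl = pd.DataFrame({"p": p, "delta": delta, "absd": np.abs(delta)},
                       index=matrix.features)
    tbl["feature"] = tbl.index
    up2 = tbl[tbl["delta"] > 0].sort_values(
        ["p", "absd", "feature"], ascending=[True, False, True])
    up1 = tbl[tbl["delta"] < 0].sort_values(
        ["p", "absd", "feature"], ascending=[True, False, True])
    chosen = list(up1.index[:n_top_per_side]) + list(up2.index[:n_top_per_side])
    sub = matrix.values.loc[chosen]
    centroids = pd.DataFrame(
        {c: sub.loc[:, (labels == c).to_numpy()].median(axis=1)
         for c in classes})
    return CentroidModel(classes=list(classes), features=chosen,
                         centroids=centroids, threshold=threshold,
                         metadata={"n_top_per_side": n_top_per_side,
                                   "ranking": ranking})


def classify_nearest_centroid(model: CentroidModel,
                              queries: Union[OmicsMatrix, pd.DataFrame],
                              min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Assign each query to the best-correlated centroid or 'unclassified'.

    Missing model features are dropped pairwise per query; at least
    ``min_overlap_frac`` of the model features (and never fewer than 3)
    must be present.
    """
    Q = queries.values if isinstance(queries, OmicsMatrix) else queries
    if isinstance(Q, pd.Series):
        Q = Q.to_frame()
    shared = [f for f in model.features if f in Q.index]
    if len(shared) < max(3, int(np.ceil(min_overlap_frac * len(model.features)))):
        raise ValueError(
            f"query covers only {len(shared)}/{len(model.features)} model features")
    C = model.centroids.loc[shared]
    rows = []
    for s in Q.columns:
        q = Q.loc[shared, s].astype(float)
        ok = q.notna()
        row: Dict = {}
        if ok.sum() < 3 or q[ok].std(ddof=0) == 0:
            for c in model.classes:
                row[f"corr_{c}"] = np.nan
            row["label"] = UNCLASSIFIED
            row["reason"] = "degenerate-query"
        else:
            corrs = {c: float(np.corrcoef(q[ok.to_numpy()],
                                          C.loc[ok.to_numpy(), c])[0, 1])
                     for c in model.classes}
            for c, v in corrs.items():
                row[f"corr_{c}"] = v
            best = max(corrs, key=lambda c: corrs[c])
            if corrs[best] >= model.threshold:
                row["label"] = best
                row["reason"] = ""
            else:
                row["label"] = UNCLASSIFIED
                row["reason"] = "below-threshold"
        rows.append(pd.Series(row, name=s))
    return pd.DataFrame(rows)


def select_cpg_panel(methylation: OmicsMatrix, labels: pd.Series,
                     n_hyper: int = 50, n_hypo: int = 30,
                     n_final_per_side: int = 7) -> List[str]:
    """Two-stage minimal CpG panel selection.

    Stage 1 ranks CpGs by two-sided rank-sum p-value within each direction
    (hyper-/hypomethylated in the second class) and truncates to
    ``n_hyper``/``n_hypo`` candidates.  Stage 2 re-ranks candidates by
    absolute beta difference and keeps ``n_final_per_side`` per direction.
    The panel lists hypermethylated CpGs first.
    """
    labels = labels.reindex(methylation.samples)
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError("select_cpg_panel requires exactly 2 classes")
    mask1 = (labels == classes[0]).to_numpy()
    mask2 = (labels == classes[1]).to_numpy()
    p, delta = _rank_two_sample(methylation.values, mask1, mask2, "ranksum")
    tbl = pd.DataFrame({"p": p, "delta": delta, "absd": np.abs(delta)},
                       index=methylation.features)
    tbl["feature"] = tbl.index

    def stage(direction_mask: pd.Series, n_stage1: int) -> List[str]:
        cand = tbl[direction_mask].sort_values(
            ["p", "absd", "feature"], ascending=[True, False, True])
        if len(cand) < n_stage1:
            warnings.warn(
                f"only {len(cand)} candidate CpGs for a stage-1 cut of {n_stage1}")
        cand = cand.iloc[:n_stage1]
        final = cand.sort_values(["absd", "p", "feature"],
                                 ascending=[False, True, True])
        return list(final.index[:n_final_per_side])

    hyper = stage(tbl["delta"] > 0, n_hyper)
    hypo = stage(tbl["delta"] < 0, n_hypo)
    if len(hyper) < n_final_per_side or len(hypo) < n_final_per_side:
        warnings.warn("fewer panel CpGs than requested were available")
    return hyper + hypo


def build_cpg_panel_centroids(methylation: OmicsMatrix, labels: pd.Series,
                              panel: Sequence[str],
                              threshold: float = 0.3) -> CentroidModel:
    """Per-class median beta centroids on a CpG panel (threshold 0.3)."""
    labels = labels.reindex(methylation.samples)
    classes = sorted(pd.unique(labels.dropna()))
    sub = methylation.values.loc[list(panel)]
    centroids = pd.DataFrame(
        {c: sub.loc[:, (labels == c).to_numpy()].median(axis=1)
         for c in classes})
    return CentroidModel(classes=list(classes), features=list(panel),
                         centroids=centroids, threshold=threshold,
                         metadata={"kind": "cpg-panel"})


def classify_cpg_panel(model: CentroidModel,
                       query: Union[pd.Series, pd.DataFrame, OmicsMatrix]
                       ) -> pd.DataFrame:
    """Nearest-centroid classification on panel beta values (Pearson >= 0.3)."""
    Q = query.values if isinstance(query, OmicsMatrix) else query
    if isinstance(Q, pd.Series):
        Q = Q.to_frame()
    available = [f for f in model.features if f in Q.index]
    if len(available) < 3:
        raise ValueError("query provides fewer than 3 panel CpGs")
    return classify_nearest_centroid(model, Q.loc[available],
                                     min_overlap_frac=0.0)


def rpe_outlier_filter(matrix: OmicsMatrix,
                       rpe_signature_genes: Sequence[str]) -> List[str]:
    """Drop samples whose mean RPE-signature expression is a Tukey outlier.

    Samples outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the per-sample mean
    signature expression are removed (linear-interpolation quartiles).
    """
    present = [g for g in rpe_signature_genes if g in matrix.features]
    if not present:
        raise ValueError("no RPE signature gene present in the matrix")
    if matrix.n_samples < 4:
        raise ValueError("need at least 4 samples for the IQR rule")
    score = matrix.values.loc[present].mean(axis=0)
    q1, q3 = np.percentile(score.to_numpy(), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [s for s in matrix.samples if lo <= score[s] <= hi]
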
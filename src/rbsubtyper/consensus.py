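"""Per-omics consensus clustering with noise-perturbation stability.

An ensemble of hierarchical clusterings (feature subsets x linkage
methods, distance 1 - Pearson correlation between samples) is reduced to
a co-classification matrix; consensus partitions come from
complete-linkage clustering of the dissimilarity ``ensemble_size - count``.
Partition stability is scored as mean pair-retention similarity between
the original partition and partitions of Gaussian-noise-perturbed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .matrix import CoClassificationMatrix, OmicsMatrix, Partition

LINKAGES = ("average", "complete", "ward")


@dataclass
class ConsensusConfig:
    linkages: Sequence[str] = LINKAGES
    k_range: Sequence[int] = tuple(range(2, 9))

    def __post_init__(self) -> None:
        bad = set(self.linkages) - set(LINKAGES)
        if bad:
            raise ValueError(f"unsupported linkages: {sorted(bad)}")


@dataclass
class StabilityConfig:
    n_iterations: int = 200
    noise_sigma_factor: float = 1.5
    sigma_mode: str = "sd"  # "sd": 1.5*sqrt(median var); "literal": 1.5*median var

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.noise_sigma_factor <= 0:
            raise ValueError("noise_sigma_factor must be positive")
        if self.sigma_mode not in ("sd", "literal"):
            raise ValueError("sigma_mode must be 'sd' or 'literal'")


def _pearson_dissimilarity(X: np.ndarray, samples) -> np.ndarray:
    """1 - Pearson correlation between sample columns; rejects flat samples."""
    sd = X.std(axis=0)
    flat = np.where(sd == 0)[0]
    if len(flat):
        names = [str(samples[i]) for i in flat]
        raise ValueError(
            f"zero-variance sample(s) over the feature subset: {names}")
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def hclust_partition(matrix: OmicsMatrix, feature_subset: Sequence[str],
                     linkage: str, k: int,
                     provenance: Optional[dict] = None) -> Partition:
    """Cut a hierarchical clustering of 1 - Pearson sample distance at k."""
    subset = list(feature_subset)
    if len(subset) < 2:
        raise ValueError("feature subset must contain at least 2 features")
    if k > matrix.n_samples:
        raise ValueError("k exceeds the number of samples")
    X = matrix.values.loc[subset].to_numpy(dtype=float)
    D = _pearson_dissimilarity(X, matrix.samples)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust")
    prov = {"omics": matrix.omics, "linkage": linkage, "k": k,
            "n_features": len(subset)}
    if provenance:
        prov.update(provenance)
    return Partition(pd.Series(labels, index=matrix.samples), prov)


def build_partition_ensemble(matrix: OmicsMatrix,
                             subsets: Sequence[Sequence[str]],
                             config: ConsensusConfig, k: int) -> List[Partition]:
    """One partition per (feature subset, linkage); 8 x 3 = 24 at defaults."""
    if not subsets:
        raise ValueError("no feature subsets provided")
    out = []
    for si, subset in enumerate(subsets):
        for lk in config.linkages:
            out.append(hclust_partition(matrix, subset, lk, k,
                                        provenance={"subset": si}))
    return out


def coclassification_matrix(partitions: Sequence[Partition]
                            ) -> CoClassificationMatrix:
    """Counts of partitions in which each sample pair shares a cluster."""
    if not partitions:
        raise ValueError("empty partition ensemble")
    samples = partitions[0].samples
    for p in partitions[1:]:
        if not samples.equals(p.samples) and set(samples) != set(p.samples):
            raise ValueError("partitions cover different sample sets")
    n = len(samples)
    counts = np.zeros((n, n), dtype=float)
    for p in partitions:
        lab = p.labels.reindex(samples).to_numpy()
        counts += (lab[:, None] == lab[None, :])
    df = pd.DataFrame(counts, index=samples, columns=samples)
    return CoClassificationMatrix(df, max_value=float(len(partitions)))


def consensus_partition(partitions: Sequence[Partition], k: int) -> Partition:
    """Complete-linkage clustering of ensemble co-classification dissimilarity."""
    cm = coclassification_matrix(partitions)
    D = cm.dissimilarity().to_numpy()
    Z = scipy_linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    prov = {"kind": "consensus", "k": k, "ensemble_size": len(partitions)}
    return Partition(pd.Series(labels, index=cm.samples), prov)


def perturb_with_noise(matrix: OmicsMatrix, stability_cfg: StabilityConfig,
                       rng: np.random.Generator) -> OmicsMatrix:
    """Add i.i.d. Gaussian noise scaled to the median feature variance."""
    X = matrix.values.to_numpy(dtype=float)
    med_var = float(np.median(X.var(axis=1, ddof=1)))
    if stability_cfg.sigma_mode == "sd":
        sigma = stability_cfg.noise_sigma_factor * np.sqrt(med_var)
    else:
        sigma = stability_cfg.noise_sigma_factor * med_var
    noisy = X + rng.normal(0.0, sigma, size=X.shape)
    return OmicsMatrix(pd.DataFrame(noisy, index=matrix.features,
                                    columns=matrix.samples), matrix.omics)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    """(co-pairs in A, co-pairs in B, co-pairs in both) via contingency table."""
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    def c2(x):
        return float((x * (x - 1) / 2).sum())
    return c2(ct.sum(axis=1)), c2(ct.sum(axis=0)), c2(ct)


def symmetric_difference_similarity(pA: Partition, pB: Partition,
                                    variant: str = "retention") -> float:
    """Pair-retention similarity between two partitions (1 for identical).

    ``retention``: mean of |S_A ∩ S_B|/|S_A| and |S_A ∩ S_B|/|S_B| where
    S_X is the set of sample pairs co-clustered in X; a directional ratio
    with empty denominator counts as 0 unless both sets are empty (then 1).
    ``jaccard``: |S_A ∩ S_B| / |S_A ∪ S_B| with the same empty convention.
    """
    if set(pA.samples) != set(pB.samples):
        raise ValueError("partitions cover different sample sets")
    order = pA.samples
    a = pA.labels.reindex(order).to_numpy()
    b = pB.labels.reindex(order).to_numpy()
    nA, nB, nAB = _pair_counts(a, b)
    if nA == 0 and nB == 0:
        return 1.0
    if variant == "retention":
        rA = nAB / nA if nA > 0 else 0.0
        rB = nAB / nB if nB > 0 else 0.0
        return 0.5 * (rA + rB)
    if variant == "jaccard":
        union = nA + nB - nAB
        return nAB / union if union > 0 else 1.0
    raise ValueError("variant must be 'retention' or 'jaccard'")


def stability_score(matrix: OmicsMatrix,
                    subsets: Sequence[Sequence[str]],
                    consensus_cfg: ConsensusConfig,
                    stability_cfg: StabilityConfig,
                    k: int, seed: int = 0
                    ) -> Tuple[pd.DataFrame, float]:
    """Noise-perturbation stability per (subset, linkage) and its mean.

    For each ensemble member, the original k-partition is compared with
    ``n_iterations`` re-clusterings of noise-perturbed data; the score is
    the mean pair-retention similarity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si, subset in enumerate(subsets):
        sub = matrix.subset(subset)
        for lk in consensus_cfg.linkages:
            p0 = hclust_partition(matrix, subset, lk, k)
            sims = []
            for _ in range(stability_cfg.n_iterations):
                noisy = perturb_with_noise(sub, stability_cfg, rng)
                p = hclust_partition(noisy, list(sub.features), lk, k)
                sims.append(symmetric_difference_similarity(p0, p))
            rows.append({"subset": si, "linkage": lk, "k": k,
                         "stability": float(np.mean(sims))})
    df = pd.DataFrame(rows)
    return df, float(df["stability"].mean())


def stability_by_k(matrix: OmicsMatrix, subsets, consensus_cfg: ConsensusConfig,
                   stability_cfg: StabilityConfig, seed: int = 0
                   ) -> pd.Series:
    """Aggregate stability for every k in the configured range."""
    out = {}
    for k in consensus_cfg.k_range:
        _, agg = stability_score(matrix, subsets, consensus_cfg, stability_cfg,
                                 k, seed=seed)
        out[k] = agg
    return pd.Series(out, name="stability")
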
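"""Cluster-of-clusters integration of per-omics consensus partitions.

One consensus partition per omics platform is combined into a fractional
co-classification matrix (0 = a pair never co-classifies in any shared
platform, 1 = always), which is clustered by complete linkage.  The two
largest clusters-of-clusters become the core subtypes; remaining samples
are flagged ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .matrix import CoClassificationMatrix, Partition


@dataclass
class IntegrationResult:
    coclassification: CoClassificationMatrix
    partition: Partition                     # the k_cc-partition
    core_labels: pd.Series                   # sample -> 1 | 2 (core only)
    ambiguous: List[str] = field(default_factory=list)

    @property
    def subtype_of(self) -> pd.Series:
        """Sample -> 'subtype1' | 'subtype2' | 'ambiguous' over all samples."""
        out = pd.Series("ambiguous", index=self.partition.samples, dtype=object)
        out[self.core_labels.index[self.core_labels == 1]] = "subtype1"
        out[self.core_labels.index[self.core_labels == 2]] = "subtype2"
        return out


def cross_omics_coclassification(partitions_by_omics: Mapping[str, Partition],
                                 min_presence: int = 2
                                 ) -> CoClassificationMatrix:
    """Fraction of shared omics platforms in which each pair co-classifies.

    A sample must be present in at least ``min_presence`` platforms to be
    included; excluded samples are reported in a warning.
    """
    if not partitions_by_omics:
        raise ValueError("no omics partitions supplied")
    min_presence = min(min_presence, len(partitions_by_omics))
    all_samples: List[str] = []
    for p in partitions_by_omics.values():
        for s in p.samples:
            if s not in all_samples:
                all_samples.append(s)
    presence = {s: [om for om, p in partitions_by_omics.items()
                    if s in p.labels.index] for s in all_samples}
    kept = [s for s in all_samples if len(presence[s]) >= min_presence]
    dropped = sorted(set(all_samples) - set(kept))
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} sample(s) below min_presence="
            f"{min_presence}: {dropped}")
    n = len(kept)
    M = np.zeros((n, n))
    labels = {om: p.labels for om, p in partitions_by_omics.items()}
    for i in range(n):
        M[i, i] = 1.0
        for j in range(i + 1, n):
            shared = [om for om in presence[kept[i]] if om in presence[kept[j]]]
            if not shared:
                val = 0.0
            else:
                co = sum(labels[om][kept[i]] == labels[om][kept[j]]
                         for om in shared)
                val = co / len(shared)
            M[i, j] = M[j, i] = val
    df = pd.DataFrame(M, index=kept, columns=kept)
    return CoClassificationMatrix(df, max_value=1.0)


def cluster_of_clusters(coclass: CoClassificationMatrix, k_cc: int = 3,
                        clinical: Optional[pd.DataFrame] = None,
                        age_column: str = "age_months") -> IntegrationResult:
    """Complete-linkage clustering of 1 - co-classification, cut at ``k_cc``.

    The two largest clusters become the core subtypes.  Subtype 1 is the
    cluster with the younger mean age when a clinical table is supplied,
    otherwise the cluster containing the earliest-listed sample.  Ties on
    cluster size are broken toward the cluster with the lower mean
    co-classification dissimilarity to all samples.
    """
    samples = coclass.samples
    n = len(samples)
    if k_cc < 2:
        raise ValueError("k_cc must be at least 2")
    if k_cc > n:
        raise ValueError("k_cc exceeds the number of samples")
    D = coclass.dissimilarity().to_numpy()
    Z = scipy_linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(Z, t=k_cc, criterion="maxclust")
    part = Partition(pd.Series(raw, index=samples),
                     {"kind": "cluster-of-clusters", "k": k_cc})
    lab = part.labels
    sizes = lab.value_counts()
    mean_dissim = {c: float(D[(lab == c).to_numpy()].mean())
                   for c in sizes.index}
    ranked = sorted(sizes.index,
                    key=lambda c: (-sizes[c], mean_dissim[c]))
    core_clusters = ranked[:2]
    cA, cB = core_clusters
    if clinical is not None and age_column in clinical.columns:
        ageA = clinical.reindex(lab.index[lab == cA])[age_column].mean()
        ageB = clinical.reindex(lab.index[lab == cB])[age_column].mean()
        first, second = (cA, cB) if ageA <= ageB else (cB, cA)
    else:
        posA = min(samples.get_loc(s) for s in lab.index[lab == cA])
        posB = min(samples.get_loc(s) for s in lab.index[lab == cB])
        first, second = (cA, cB) if posA <= posB else (cB, cA)
    core = pd.Series(dtype=int)
    core = pd.concat([
        pd.Series(1, index=lab.index[lab == first]),
        pd.Series(2, index=lab.index[lab == second]),
    ])
    ambiguous = [s for s in samples if s not in core.index]
    return IntegrationResult(coclass, part, core.reindex(
        [s for s in samples if s in core.index]), ambiguous)
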
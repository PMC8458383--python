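"""Core in-memory containers shared across the pipeline.

All omics data are features x samples :class:`pandas.DataFrame` objects
wrapped in :class:`OmicsMatrix` to carry the omics tag (``expression``,
``methylation-beta`` or ``cna-region``).  Partitions are integer cluster
labels (contiguous from 1) indexed by sample identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

OMICS_TAGS = ("expression", "methylation-beta", "cna-region")


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with an omics tag.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample
        identifiers as the columns.
    omics
        One of ``expression``, ``methylation-beta`` or ``cna-region``.
    """

    values: pd.DataFrame
    omics: str

    def __post_init__(self) -> None:
        if self.omics not in OMICS_TAGS:
            raise ValueError(
                f"unknown omics tag {self.omics!r}; expected one of {OMICS_TAGS}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, features) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(features)], self.omics)


@dataclass
class Partition:
    """An assignment of samples to clusters ``1..k`` with provenance."""

    labels: pd.Series
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = pd.Series(self.labels).astype(int)
        uniq = np.unique(labels.to_numpy())
        if len(uniq) and (uniq[0] != 1 or uniq[-1] != len(uniq)):
            # relabel to contiguous 1..k in order of first appearance
            remap = {}
            for v in labels:
                if v not in remap:
                    remap[v] = len(remap) + 1
            labels = labels.map(remap)
        self.labels = labels

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def relabeled(self, mapping: Mapping[int, int]) -> "Partition":
        return Partition(self.labels.map(mapping), dict(self.provenance))


@dataclass
class CoClassificationMatrix:
    """Symmetric samples x samples co-classification counts (or fractions).

    ``max_value`` is the ensemble size for integer counts, or 1.0 for
    cross-omics fractions.
    """

    counts: pd.DataFrame
    max_value: float

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("co-classification matrix must be square")
        if not np.allclose(arr, arr.T):
            raise ValueError("co-classification matrix must be symmetric")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    def dissimilarity(self) -> pd.DataFrame:
        """MAX_VALUE - count, the dissimilarity used for consensus clustering."""
        d = self.max_value - self.counts
        np.fill_diagonal(d.to_numpy(), 0.0)
        return d
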
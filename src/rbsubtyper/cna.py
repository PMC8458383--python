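"""Copy-number calling and genomic instability scoring.

Segment tables (SEG-like: sample, chrom, start, end, n_features, value;
1-based inclusive coordinates) carry either absolute copy numbers or
smoothed log ratios.  Per sample, a zero level is estimated (length-
weighted median for absolute values, length-weighted histogram mode for
log ratios), segments are discretized to Gain/Normal/Loss with
amplification and homozygous-deletion flags, and genomic instability is
the mean over chromosomes of the length-weighted aberrant fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_features", "value"]

MODES = ("absolute", "logratio")


@dataclass
class CnaThresholds:
    """Discretization rules for the two segment-value modes.

    Absolute mode: gain strictly above zero + 0.5, loss strictly below
    zero - 0.5; amplification at copy number >= 5, homozygous deletion at
    <= 0.5.  Log-ratio mode: gain/loss at zero +/- 0.15; amplification and
    homozygous-deletion cutoffs at mean +/- 5 SD of the normal segments.
    """

    gain_margin_absolute: float = 0.5
    loss_margin_absolute: float = 0.5
    amp_min_absolute: float = 5.0
    homdel_max_absolute: float = 0.5
    gain_margin_logratio: float = 0.15
    loss_margin_logratio: float = 0.15
    extreme_sd_logratio: float = 5.0


@dataclass
class GnlProfile:
    """Discrete Gain(+1)/Normal(0)/Loss(-1) calls for one sample."""

    table: pd.DataFrame  # chrom, start, end, value, status, amp, homdel, weight

    def __post_init__(self) -> None:
        t = self.table
        if (t.loc[t["amp"], "status"] != 1).any():
            raise ValueError("amplified segments must have status +1")
        if (t.loc[t["homdel"], "status"] != -1).any():
            raise ValueError("homozygously deleted segments must have status -1")


def _weights(segments: pd.DataFrame) -> np.ndarray:
    """Segment weights: marker counts when present, else lengths in bp."""
    if "n_features" in segments.columns and segments["n_features"].notna().all() \
            and (segments["n_features"] > 0).all():
        return segments["n_features"].to_numpy(dtype=float)
    return (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, half))
    if np.isclose(cw[i], half) and i + 1 < len(v):
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def estimate_zero_level(segments: pd.DataFrame, mode: str,
                        bin_width: float = 0.05) -> float:
    """Per-sample neutral copy level.

    Absolute mode: length-weighted median segment value.  Log-ratio mode:
    midpoint of the tallest (length-weighted) histogram bin of segment
    values, ``bin_width`` wide.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if segments.empty:
        raise ValueError("no segments for zero-level estimation")
    vals = segments["value"].to_numpy(dtype=float)
    w = (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)
    if mode == "absolute":
        return weighted_median(vals, w)
    lo = np.floor(vals.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((vals.max() - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    hist, _ = np.histogram(vals, bins=edges, weights=w)
    i = int(np.argmax(hist))  # tie -> lower bin
    return float(edges[i] + 0.5 * bin_width)


def call_gnl(segments: pd.DataFrame, zero: float,
             thresholds: Optional[CnaThresholds] = None,
             mode: str = "absolute") -> GnlProfile:
    """Discretize segments into GNL status plus amp/homdel flags."""
    thr = thresholds or CnaThresholds()
    if not np.isfinite(zero):
        raise ValueError("zero level must be finite")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    t = segments.copy()
    v = t["value"].to_numpy(dtype=float)
    if mode == "absolute":
        gain = v > zero + thr.gain_margin_absolute
        loss = v < zero - thr.loss_margin_absolute
        amp = v >= thr.amp_min_absolute
        homdel = v <= thr.homdel_max_absolute
    else:
        gain = v > zero + thr.gain_margin_logratio
        loss = v < zero - thr.loss_margin_logratio
        normal = ~gain & ~loss
        if normal.any():
            mu, sd = v[normal].mean(), v[normal].std(ddof=0)
        else:
            mu, sd = zero, 0.0
        amp = v >= mu + thr.extreme_sd_logratio * sd
        loss_cut = mu - thr.extreme_sd_logratio * sd
        homdel = v <= loss_cut
        if not normal.any():
            amp = np.zeros_like(gain)
            homdel = np.zeros_like(gain)
    status = np.where(gain | amp, 1, np.where(loss | homdel, -1, 0))
    t["status"] = status
    t["amp"] = amp & (status == 1)
    t["homdel"] = homdel & (status == -1)
    t["weight"] = _weights(segments)
    return GnlProfile(t)


def genomic_instability(profile: GnlProfile) -> float:
    """Mean over chromosomes of the weighted fraction of aberrant features."""
    t = profile.table
    if t.empty:
        raise ValueError("empty GNL profile")
    per_chrom = []
    for _, sub in t.groupby("chrom", sort=False):
        w = sub["weight"].to_numpy(dtype=float)
        ab = (sub["status"] != 0).to_numpy()
        per_chrom.append(float(np.sum(w * ab) / np.sum(w)))
    return float(np.mean(per_chrom))


def instability_scores(segments: pd.DataFrame, mode: str = "absolute",
                       thresholds: Optional[CnaThresholds] = None) -> pd.Series:
    """Genomic instability per sample from a multi-sample segment table."""
    out = {}
    for s, sub in segments.groupby("sample", sort=False):
        zero = estimate_zero_level(sub, mode)
        out[s] = genomic_instability(call_gnl(sub, zero, thresholds, mode))
    return pd.Series(out, name="genomic_instability")


def region_average_cn(segments: pd.DataFrame,
                      regions: pd.DataFrame) -> pd.DataFrame:
    """Samples x regions matrix of length-weighted average segment values.

    ``regions`` needs columns chrom, start, end (1-based inclusive) and an
    index of region names; regions must not overlap within a chromosome.
    Regions with no overlapping segment are missing (NaN).
    """
    if (regions["start"] > regions["end"]).any():
        bad = regions[regions["start"] > regions["end"]].index.tolist()
        raise ValueError(f"malformed region(s) with start > end: {bad}")
    for chrom, sub in regions.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping regions on chromosome {chrom}")
    samples = list(pd.unique(segments["sample"]))
    out = pd.DataFrame(index=samples, columns=regions.index, dtype=float)
    for s in samples:
        seg = segments[segments["sample"] == s]
        for rname, r in regions.iterrows():
            ov = seg[(seg["chrom"].astype(str) == str(r["chrom"]))
                     & (seg["end"] >= r["start"]) & (seg["start"] <= r["end"])]
            if ov.empty:
                continue
            w = (np.minimum(ov["end"], r["end"])
                 - np.maximum(ov["start"], r["start"]) + 1).to_numpy(float)
            out.loc[s, rname] = float(np.average(ov["value"], weights=w))
    return out
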
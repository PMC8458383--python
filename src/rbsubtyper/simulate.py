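"""Synthetic multi-omics cohort generator.

Generates two-subtype retinoblastoma-like cohorts with the structure the
downstream pipeline is designed to detect:

* expression (log2 array-intensity scale) with a cone-marker block
  elevated in subtype 1, a neuronal/ganglion block elevated in subtype 2,
  an early-cone block elevated in both subtypes, and an additive stromal
  contamination component;
* DNA methylation beta values with CpG-island hypermethylation and
  open-sea hypomethylation in subtype 2;
* copy-number segment tables with subtype-2-biased arm-level gains/losses
  (1q+, 2p+, 16q-) and occasional focal high-level amplification
  (14-246 copies, MYCN-like), plus a pre-averaged region matrix;
* clinical covariates statistically associated with subtype;
* a retinal-organoid differentiation time-course for 8 cone markers.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix

# Marker gene names planted into the synthetic expression matrix.  Early
# cone markers are shared by both subtypes (both derive from committed
# cones); late cone markers mark the more differentiated subtype 1.
EARLY_CONE_MARKERS = ["OTX2", "CRX", "THRB", "RXRG"]
LATE_CONE_MARKERS = ["PDE6H", "GNAT2", "ARR3", "GUCA1C", "GUCA1A", "GUCA1B",
                     "GNGT2", "PDE6C", "OPN1SW"]
NEURONAL_MARKERS = ["EBF3", "DCX", "ROBO1", "SOX11", "GAP43", "PCDHB10",
                    "STMN2", "NEFM", "POU4F2", "EBF1"]
STROMAL_MARKERS = ["CD14", "AIF1", "CD3D", "TRAC", "TFF1"]

# Cone differentiation panel used for staging (early -> late order).
CONE_PANEL = ["OTX2", "CRX", "THRB", "RXRG", "PDE6H", "GNAT2", "ARR3", "GUCA1C"]

# Simplified arm model: (chromosome, arm, length in Mb)
_ARMS = [
    ("1", "p", 120), ("1", "q", 125),
    ("2", "p", 90), ("2", "q", 150),
    ("6", "p", 60), ("6", "q", 110),
    ("13", "q", 95),
    ("16", "p", 35), ("16", "q", 55),
    ("17", "p", 25), ("17", "q", 55),
    ("19", "p", 26), ("19", "q", 32),
]

MB = 1_000_000


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


def _default_cna_event_probs() -> Dict[str, Tuple[float, float]]:
    # event -> (P(subtype 1), P(subtype 2)); subtype-2 bias for 1q+/2p+/16q-,
    # 6p gain equally frequent, focal amplification only in subtype 2.
    return {
        "gain_1q": (0.10, 0.70),
        "gain_2p": (0.15, 0.50),
        "loss_16q": (0.10, 0.60),
        "gain_6p": (0.50, 0.50),
        "amp_2p_focal": (0.0, 0.17),
    }


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_samples_per_subtype: int = 30
    n_genes: int = 600
    n_cpgs: int = 600
    n_regions: int = 12
    n_marker_genes_per_block: int = 40
    n_stromal_genes: int = 30
    effect_size_expr: float = 2.0      # mean log2 shift of marker blocks
    effect_size_meth: float = 0.3      # beta-value shift of differential CpGs
    frac_island_cpgs: float = 0.4
    frac_diff_cpgs: float = 0.2
    cna_event_probs: Dict[str, Tuple[float, float]] = field(
        default_factory=_default_cna_event_probs)
    stromal_fraction_range: Tuple[float, float] = (0.0, 0.3)
    noise_sd_expr: float = 1.0
    noise_sd_meth: float = 0.05
    noise_sd_cna: float = 0.05
    meth_noise_model: str = "gaussian"  # or "logit-normal"
    baseline_expr: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples_per_subtype", "n_genes", "n_cpgs", "n_regions",
                     "n_marker_genes_per_block", "n_stromal_genes"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("frac_island_cpgs", "frac_diff_cpgs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.effect_size_meth <= 1.0:
            raise ConfigurationError("effect_size_meth must lie in [0, 1]")
        lo, hi = self.stromal_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                "stromal_fraction_range must be an interval within [0, 1]")
        for ev, probs in self.cna_event_probs.items():
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"cna_event_probs[{ev!r}] must lie in [0, 1]")
        for name in ("noise_sd_expr", "noise_sd_meth", "noise_sd_cna"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.meth_noise_model not in ("gaussian", "logit-normal"):
            raise ConfigurationError(
                "meth_noise_model must be 'gaussian' or 'logit-normal'")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    subtype: pd.Series                  # sample -> 1 | 2
    stromal_weight: pd.Series           # sample -> mixing weight in [0, 1]
    cone_genes: List[str]               # elevated in subtype 1
    neuronal_genes: List[str]           # elevated in subtype 2
    stromal_genes: List[str]
    diff_cpgs: pd.DataFrame             # index CpG, columns: direction, context
    cna_events: Dict[str, List[str]]    # sample -> planted events
    region_matrix: OmicsMatrix          # pre-averaged region x sample copy number

    def validate_against(self, expression: OmicsMatrix,
                         methylation: OmicsMatrix) -> None:
        for g in self.cone_genes + self.neuronal_genes + self.stromal_genes:
            if g not in expression.features:
                raise AssertionError(f"planted gene {g} missing from matrix")
        missing = set(self.diff_cpgs.index) - set(methylation.features)
        if missing:
            raise AssertionError(f"planted CpGs missing: {sorted(missing)[:5]}")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_cohort(config: CohortConfig
                    ) -> Tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame, GroundTruth]:
    """Generate a two-subtype multi-omics cohort.

    Returns ``(expression, methylation, segments, truth)`` where
    ``segments`` is a SEG-like table (sample, chrom, start, end,
    n_features, value) of absolute copy numbers.
    """
    config.validate()
    rng = _rng(config.seed)
    n_per = config.n_samples_per_subtype
    samples = [f"RB{i + 1:03d}" for i in range(2 * n_per)]
    subtype = pd.Series([1] * n_per + [2] * n_per, index=samples, name="subtype")

    expression, truth_genes, stromal_weight = _generate_expression(
        config, rng, samples, subtype)
    methylation, diff_cpgs = _generate_methylation(config, rng, samples, subtype)
    segments, cna_events, region_matrix = _generate_cna(
        config, rng, samples, subtype)

    truth = GroundTruth(
        subtype=subtype,
        stromal_weight=stromal_weight,
        cone_genes=truth_genes["cone"],
        neuronal_genes=truth_genes["neuronal"],
        stromal_genes=truth_genes["stromal"],
        diff_cpgs=diff_cpgs,
        cna_events=cna_events,
        region_matrix=region_matrix,
    )
    truth.validate_against(expression, methylation)
    return expression, methylation, segments, truth


def _pad_names(named: Sequence[str], n: int, prefix: str) -> List[str]:
    out = list(named[:n])
    out += [f"{prefix}{i:03d}" for i in range(len(out), n)]
    return out


def _generate_expression(config, rng, samples, subtype):
    n_block = config.n_marker_genes_per_block
    cone = _pad_names(LATE_CONE_MARKERS, n_block, "CONE")
    neuronal = _pad_names(NEURONAL_MARKERS, n_block, "NEUR")
    stromal = _pad_names(STROMAL_MARKERS, config.n_stromal_genes, "STROM")
    early = list(EARLY_CONE_MARKERS)
    n_named = len(cone) + len(neuronal) + len(stromal) + len(early)
    if config.n_genes < n_named + 10:
        raise ConfigurationError(
            f"n_genes must be at least {n_named + 10} to host marker blocks")
    filler = [f"G{i:05d}" for i in range(config.n_genes - n_named)]
    genes = early + cone + neuronal + stromal + filler

    n = len(samples)
    base = rng.normal(config.baseline_expr, 1.0, size=len(genes))
    # the named cone-panel genes share a common baseline so that relative
    # early/late marker levels carry the differentiation signal
    panel_named = set(EARLY_CONE_MARKERS) | set(LATE_CONE_MARKERS)
    base[[i for i, g in enumerate(genes) if g in panel_named]] = \
        config.baseline_expr
    X = base[:, None] + rng.normal(0.0, config.noise_sd_expr, size=(len(genes), n))
    df = pd.DataFrame(X, index=genes, columns=samples)

    is1 = (subtype == 1).to_numpy()
    is2 = ~is1
    eff = config.effect_size_expr
    # early cone markers moderately expressed in every tumor; late cone
    # markers strongly expressed only in the differentiated subtype 1
    df.loc[early] += eff / 2.0
    df.loc[cone, df.columns[is1]] += eff
    df.loc[neuronal, df.columns[is2]] += eff

    # stromal contamination: additive in linear space on the stromal block;
    # pure stroma expresses its markers ~16-fold above the tumor background
    lo, hi = config.stromal_fraction_range
    w = pd.Series(rng.uniform(lo, hi, size=n), index=samples, name="stromal_weight")
    base_mean = pd.Series(base, index=genes)
    tumor_lin = np.power(2.0, df.loc[stromal].to_numpy())
    strom_lin = np.power(2.0, base_mean[stromal].to_numpy()[:, None] + 4.0)
    mixed = (1.0 - w.to_numpy())[None, :] * tumor_lin + w.to_numpy()[None, :] * strom_lin
    df.loc[stromal] = np.log2(mixed)

    truth_genes = {"cone": cone, "neuronal": neuronal, "stromal": stromal}
    return OmicsMatrix(df, "expression"), truth_genes, w


def _generate_methylation(config, rng, samples, subtype):
    n_cpg = config.n_cpgs
    n_island = int(round(config.frac_island_cpgs * n_cpg))
    contexts = np.array(["island"] * n_island + ["open_sea"] * (n_cpg - n_island))
    cpgs = [f"cg{i:08d}" for i in range(n_cpg)]
    # baseline: islands lowly methylated, open sea highly methylated
    base = np.where(contexts == "island",
                    rng.beta(2, 10, size=n_cpg), rng.beta(10, 3, size=n_cpg))
    n = len(samples)
    B = np.repeat(base[:, None], n, axis=1)

    # plant differential CpGs: islands gain methylation in subtype 2,
    # open-sea CpGs lose methylation in subtype 2
    n_diff = int(round(config.frac_diff_cpgs * n_cpg))
    n_hyper = n_diff // 2
    n_hypo = n_diff - n_hyper
    island_idx = np.where(contexts == "island")[0]
    sea_idx = np.where(contexts == "open_sea")[0]
    hyper = rng.choice(island_idx, size=min(n_hyper, len(island_idx)), replace=False)
    hypo = rng.choice(sea_idx, size=min(n_hypo, len(sea_idx)), replace=False)
    is2 = (subtype == 2).to_numpy()
    B[np.ix_(hyper, np.where(is2)[0])] += config.effect_size_meth
    B[np.ix_(hypo, np.where(is2)[0])] -= config.effect_size_meth

    if config.meth_noise_model == "gaussian":
        B = B + rng.normal(0.0, config.noise_sd_meth, size=B.shape)
        B = np.clip(B, 0.0, 1.0)
    else:  # logit-normal: noise on the logit scale, back-transformed
        eps = 1e-4
        L = np.log(np.clip(B, eps, 1 - eps) / np.clip(1 - B, eps, 1 - eps))
        # match the gaussian beta-scale sd approximately at beta = 0.5
        L = L + rng.normal(0.0, 4.0 * config.noise_sd_meth, size=B.shape)
        B = 1.0 / (1.0 + np.exp(-L))

    df = pd.DataFrame(B, index=cpgs, columns=samples)
    diff = pd.DataFrame(
        {"direction": ["hyper"] * len(hyper) + ["hypo"] * len(hypo),
         "context": ["island"] * len(hyper) + ["open_sea"] * len(hypo)},
        index=[cpgs[i] for i in hyper] + [cpgs[i] for i in hypo])
    return OmicsMatrix(df, "methylation-beta"), diff


_EVENT_ARM = {"gain_1q": ("1", "q", +1), "gain_2p": ("2", "p", +1),
              "loss_16q": ("16", "q", -1), "gain_6p": ("6", "p", +1)}


def _generate_cna(config, rng, samples, subtype):
    rows = []
    cna_events: Dict[str, List[str]] = {}
    for s in samples:
        st = int(subtype[s])
        events = [ev for ev, probs in config.cna_event_probs.items()
                  if rng.random() < probs[st - 1]]
        cna_events[s] = events
        offset = {}
        for ev in events:
            if ev in _EVENT_ARM:
                chrom, arm, sign = _EVENT_ARM[ev]
                offset[(chrom, arm)] = offset.get((chrom, arm), 0) + sign
        pos = {}
        for chrom, arm, length in _ARMS:
            cn = 2 + offset.get((chrom, arm), 0)
            # array-derived copy numbers carry measurement noise
            cn = max(0.0, cn + rng.normal(0.0, config.noise_sd_cna))
            start = 1 if arm == "p" else pos.get(chrom, 1)
            end = start + length * MB - 1
            pos[chrom] = end + 1
            rows.append((s, chrom, start, end, length * 10, float(cn)))
        if "amp_2p_focal" in events:
            # focal high-level amplification inside 2p (MYCN-like locus)
            copies = float(np.round(np.exp(rng.uniform(np.log(14), np.log(246)))))
            rows.append((s, "2", 15 * MB + 1, 17 * MB, 20, copies))
    segments = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_features", "value"])

    # pre-averaged region matrix for direct CNA clustering
    regions = [(f"{c}{a}", c, a) for c, a, _ in _ARMS]
    reg_rows = {}
    for (name, chrom, arm) in regions[: config.n_regions]:
        vals = []
        for s in samples:
            sub = segments[(segments["sample"] == s) & (segments["chrom"] == chrom)]
            # arm boundaries from the arm model
            length = dict(((c, a), l) for c, a, l in _ARMS)[(chrom, arm)]
            if arm == "p":
                lo, hi = 1, length * MB
            else:
                p_len = dict(((c, a), l) for c, a, l in _ARMS).get((chrom, "p"), 0)
                lo = p_len * MB + 1
                hi = lo + length * MB - 1
            ov = sub[(sub["end"] >= lo) & (sub["start"] <= hi)]
            w = (np.minimum(ov["end"], hi) - np.maximum(ov["start"], lo) + 1).to_numpy(float)
            vals.append(float(np.average(ov["value"], weights=w)) if len(ov) else np.nan)
        reg_rows[name] = vals
    region_df = pd.DataFrame(reg_rows, index=samples).T
    region_matrix = OmicsMatrix(region_df, "cna-region")
    return segments, cna_events, region_matrix


# ---------------------------------------------------------------------------
# clinical covariates

def default_assoc_params() -> Dict:
    """Subtype-conditional covariate distributions emulating the clinical table.

    Bilateral disease, exophytic growth and young age characterize
    subtype 1; necrosis and endophytic growth characterize subtype 2.
    """
    return {
        "categorical": {
            "laterality": {"levels": ["bilateral", "unilateral"],
                           "probs": {1: [0.32, 0.68], 2: [0.07, 0.93]}},
            "growth_pattern": {"levels": ["endophytic", "exophytic", "mixed"],
                               "probs": {1: [0.22, 0.59, 0.19],
                                         2: [0.63, 0.22, 0.15]}},
            "necrosis": {"levels": ["yes", "none"],
                         "probs": {1: [0.53, 0.47], 2: [0.77, 0.23]}},
            "sex": {"levels": ["female", "male"],
                    "probs": {1: [0.45, 0.55], 2: [0.53, 0.47]}},
        },
        # age at diagnosis in months, log-normal per subtype
        "age_lognormal": {1: {"mu": np.log(11.0), "sigma": 0.55},
                          2: {"mu": np.log(23.9), "sigma": 0.55}},
    }


def generate_clinical_table(truth: GroundTruth,
                            assoc_params: Optional[Mapping] = None,
                            seed: int = 0) -> pd.DataFrame:
    """Draw clinical covariates conditional on the planted subtype."""
    if len(truth.subtype) == 0:
        raise ConfigurationError("cohort is empty: no samples to annotate")
    params = assoc_params if assoc_params is not None else default_assoc_params()
    for cov, spec in params.get("categorical", {}).items():
        for st, probs in spec["probs"].items():
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"probabilities for {cov!r}, subtype {st} do not sum to 1")
            if len(probs) != len(spec["levels"]):
                raise ConfigurationError(
                    f"probability row length mismatch for {cov!r}")
    rng = _rng(seed)
    out = pd.DataFrame(index=truth.subtype.index)
    out["subtype"] = truth.subtype
    for cov, spec in params.get("categorical", {}).items():
        vals = []
        for s in out.index:
            st = int(truth.subtype[s])
            vals.append(rng.choice(spec["levels"], p=spec["probs"][st]))
        out[cov] = vals
    age = params.get("age_lognormal")
    if age:
        vals = []
        for s in out.index:
            p = age[int(truth.subtype[s])]
            vals.append(float(np.exp(rng.normal(p["mu"], p["sigma"]))))
        out["age_months"] = vals
    return out


# ---------------------------------------------------------------------------
# organoid differentiation time-course

DEFAULT_TIMEPOINTS = (35, 49, 56, 84, 112, 175)

# sigmoid onset (days) per marker; GUCA1C switches on last
_MARKER_ONSET = {"OTX2": 30, "CRX": 38, "THRB": 45, "RXRG": 50,
                 "PDE6H": 90, "GNAT2": 100, "ARR3": 110, "GUCA1C": 140}


def generate_organoid_timecourse(marker_genes: Optional[Sequence[str]] = None,
                                 timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
                                 seed: int = 0,
                                 n_replicates: int = 3,
                                 noise_sd: float = 0.3,
                                 onsets: Optional[Mapping[str, float]] = None,
                                 ) -> OmicsMatrix:
    """Simulate log2 expression of cone markers along organoid differentiation.

    Each marker follows a rising sigmoid with a marker-specific onset day;
    early markers rise before late markers.  Columns are named
    ``d{timepoint}_r{replicate}``.
    """
    markers = list(marker_genes) if marker_genes is not None else list(CONE_PANEL)
    if not markers:
        raise ConfigurationError("marker gene list is empty")
    tps = list(timepoints)
    if any(b <= a for a, b in zip(tps, tps[1:])):
        raise ConfigurationError("timepoints must be strictly increasing")
    onset_map = dict(_MARKER_ONSET)
    if onsets:
        onset_map.update(onsets)
    # unknown markers get onsets spread over the time range, in list order
    unknown = [m for m in markers if m not in onset_map]
    if unknown:
        span = np.linspace(tps[0], tps[-1], len(unknown) + 2)[1:-1]
        onset_map.update(dict(zip(unknown, span)))

    rng = _rng(seed)
    base, width = 4.0, 12.0
    cols = []
    for t in tps:
        for r in range(1, n_replicates + 1):
            cols.append(f"d{t}_r{r}")
    X = np.empty((len(markers), len(cols)))
    for i, m in enumerate(markers):
        onset = onset_map[m]
        # late phototransduction markers reach higher mature levels
        amp = 8.0 if onset >= 80 else 5.0
        j = 0
        for t in tps:
            mu = base + amp / (1.0 + np.exp(-(t - onset) / width))
            for _ in range(n_replicates):
                X[i, j] = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                j += 1
    df = pd.DataFrame(X, index=markers, columns=cols)
    return OmicsMatrix(df, "expression")


def timepoint_of_column(column: str) -> int:
    """Extract the day from an organoid column name like ``d84_r2``."""
    return int(column.split("_")[0].lstrip("d"))
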
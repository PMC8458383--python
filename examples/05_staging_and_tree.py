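"""Stage tumor subtypes against a retinal-organoid time-course and build
a minimal-evolution tree on the 8-gene cone-differentiation panel."""

import pandas as pd

import rbsubtyper as rb
from rbsubtyper.matrix import OmicsMatrix
from rbsubtyper.staging import StagingPanel, organoid_centroids

expr, _, _, truth = rb.generate_cohort(rb.CohortConfig(seed=1))
organoids = rb.generate_organoid_timecourse(seed=2)
panel = StagingPanel()

centroids = pd.DataFrame({
    f"subtype{c}": expr.values.loc[
        list(panel.markers),
        truth.subtype.index[truth.subtype == c]].median(axis=1)
    for c in (1, 2)})
corr, assigned = rb.stage_by_centroid_correlation(centroids, organoids,
                                                  panel)
print("Pearson correlation with organoid differentiation days:")
print(corr.round(2).to_string())
print(f"assigned stages: {assigned.to_dict()}")

taxa = pd.concat([organoid_centroids(organoids, panel), centroids], axis=1)
D = rb.euclidean_distance_matrix(OmicsMatrix(taxa, "expression"), panel)
tree = rb.build_me_tree(D, method="balanced_me")
print("minimal-evolution tree:")
print(tree.newick)
# Subtype 1 (late cone markers expressed) correlates best with the latest
# organoid day; subtype 2 matches an earlier differentiation stage, and
# the tree places each subtype next to its assigned stage.
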
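"""Cluster the 56 dose-response profiles and pick k with the figure of merit.

K-means under Pearson-correlation distance groups genes by the *shape* of
their fold-change profile across the six dilutions, not by its magnitude;
the leave-one-condition-out figure of merit (FOM) estimates predictive
error for each candidate k.
"""
from dosetx import fixtures
from dosetx.clustering import figure_of_merit, kmeans_profiles

fc = fixtures.table3_fold_changes()
_, up_set = fixtures.deg_gene_sets()

fom = figure_of_merit(fc, k_range=[2, 3, 4, 5, 6, 7], seed=0)
print("figure of merit by k (lower = better out-of-condition prediction):")
for k, v in fom.items():
    print(f"  k={k}: {v:.4f}")

res = kmeans_profiles(fc, k=5, seed=0, restarts=20)
print("\ncluster sizes at k=5:", res.assignments.value_counts().sort_index().tolist())
up_clusters = set(res.assignments.loc[up_set])
print(f"clusters holding the 7 up-regulated genes: {sorted(up_clusters)} "
      "(they share one cluster: their rising profile shape is anti-"
      "correlated with every down-regulated profile)")
print("\ncentroid profiles (mean log2 fold change per potency):")
print(res.centroids.round(3))
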
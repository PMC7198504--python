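"""Unsupervised structure of the significant gene set.

The DEG expression matrix (log2 CPM, z-scored by row) is summarized with
PCA over samples and k-means over genes, with k chosen by the elbow of the
within-cluster sum-of-squares curve.
"""

import numpy as np

import methylink as ml

config = ml.SimulationConfig(n_genes=800, frac_deg=0.15, seed=6)
counts, _, _, sample_sheet, _ = ml.simulate_cohort(config)
design = sample_sheet.set_index("sample_id")["group"]

filtered = ml.filter_low_expression(counts)
norm = ml.normalize(filtered)
de = ml.fit_glm_anova_like(filtered, design, norm)
sig = de.index[de["q_value"] < 0.05]

log_cpm = np.log2(norm.cpm.loc[sig] + 1)
z, _ = ml.zscore_rows(log_cpm)

res = ml.pca(z)
print("variance explained:", np.round(res.variance_explained[:3], 3))
print("\nPC1/PC2 sample scores:")
print(res.scores[["PC1", "PC2"]].round(2))

clus = ml.kmeans_elbow(z, k_grid=range(1, 9), seed=0)
print(f"\nelbow-selected k = {clus.k}")
print("cluster sizes:", clus.labels.value_counts().sort_index().to_dict())
print(
    "\nSamples from the same group should score near each other on the "
    "leading components; gene clusters group co-varying expression patterns."
)
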
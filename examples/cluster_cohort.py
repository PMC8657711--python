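"""Clustering tendency and structure of the per-sample signature
contribution matrix: Hopkins statistic, DIANA tree, silhouette, PCA."""

import numpy as np
import pandas as pd

from lymphsig import (SyntheticConfig, build_context_matrix,
                      diana_clustering, fit_exposures, generate_cohort,
                      hopkins_statistic, pca_projection, silhouette_widths)

data = generate_cohort(SyntheticConfig(seed=7))
matrix, _ = build_context_matrix(data.records, data.genome)
exposures, _, _ = fit_exposures(matrix, data.signatures)
X = exposures.T.to_numpy()
samples = list(exposures.columns)

h = hopkins_statistic(X, seed=7)
print(f"Hopkins statistic: {h:.2f} "
      "(~0.5 = spatially random, << 0.5 = clusterable)")

tree = diana_clustering(X)
labels = tree.cut(2)
widths, mean_width = silhouette_widths(X, labels)
print(f"DIANA cut at k=2: cluster sizes "
      f"{np.bincount(labels)[1:].tolist()}, "
      f"mean silhouette width {mean_width:.2f}")

groups = pd.Series([data.sample_groups[s] for s in samples])
print("cluster vs disease group:")
print(pd.crosstab(labels, groups).to_string())

scores, evr = pca_projection(X, 2)
print(f"PCA: PC1 explains {evr[0]:.0%}, PC2 {evr[1]:.0%} of exposure "
      "variance")
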
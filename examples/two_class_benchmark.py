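"""Classify synthetic smooth vs rough textures with the effort features.

Generates a 60-image two-class dataset with patient-like groups, extracts
(FE, FP), splits by group (no group on both sides), grid-searches a kNN
classifier on the training groups and scores the held-out groups.  Also
ranks FE/FP against ten pure-noise features with both ranking tests.
"""

import numpy as np

from cyeff import (
    default_grid,
    extract_feature_table,
    fit_evaluate,
    group_split,
    make_labeled_dataset,
    rank_features,
)

dataset = make_labeled_dataset(n_per_class=30, n_groups=5, seed=42)
table = extract_feature_table(dataset, ("cyeff",), seed=42)

train, test = group_split(table, test_fraction=0.2, seed=42)
result = fit_evaluate(train, test, "knn", grid=default_grid("knn", "fast"), seed=42)
print(f"kNN (best params {result.best_params}) on {len(test)} held-out images:")
print(f"  accuracy    = {result.accuracy:.3f}")
print(f"  sensitivity = {result.sensitivity:.3f}   (rough/malignant-like detected)")
print(f"  specificity = {result.specificity:.3f}   (smooth/benign-like recognized)")

rng = np.random.default_rng(0)
for j in range(10):
    table[f"noise{j:02d}"] = rng.normal(size=len(table))
for method in ("t_test", "wilcoxon"):
    ranked = rank_features(table, method=method)
    top = ", ".join(ranked.head(3)["feature"])
    print(f"top-3 features by {method:>8}: {top}")
print()
print("Both effort features outrank all noise features: their class-conditional")
print("distributions are far apart relative to their spread.")
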
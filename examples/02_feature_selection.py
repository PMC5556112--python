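"""Rank features by discriminant ability between positives and unlabeled.

A feature scores high when it is frequent overall yet unevenly present
between the two pools: da(f) = (as_P + as_U) * ln(|P|/as_P + |U|/as_U),
where as_P and as_U count the samples "having" the feature (continuous
columns are binarized at their pooled median). The example plants one
feature present in almost every positive but few unlabeled samples and
one with no class difference.
"""

import numpy as np

from pudti.feature_select import FeatureSelector, discriminant_score

rng = np.random.default_rng(0)
n_p, n_u = 100, 100
X_p = rng.random((n_p, 4)) < [0.9, 0.3, 0.5, 0.1]   # feature 0 marks positives
X_u = rng.random((n_u, 4)) < [0.1, 0.3, 0.5, 0.1]  # same rates except feature 0
X_p, X_u = X_p.astype(float), X_u.astype(float)

sel = FeatureSelector.fit(X_p, X_u, k=2)
print(f"|P| = {n_p}, |U| = {n_u}")
for f in range(4):
    as_p = int(X_p[:, f].sum())
    as_u = int(X_u[:, f].sum())
    da = discriminant_score(as_p, as_u, n_p, n_u)
    print(f"feature {f}: as_P = {as_p:2d}, as_U = {as_u:3d}, da = {da:7.2f}")
print("top 2 selected:", sel.selected.tolist())
print("feature 0 (frequent in P, rare in U) dominates: both factors of the\n"
      "score are large; features with matched rates in P and U score lower")
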
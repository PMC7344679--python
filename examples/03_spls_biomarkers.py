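"""Find molecular features associated with one sensory attribute by
cross-validated sparse PLS, then rank them by VIP.

A univariate sPLS model is fitted with metabolite intensities as
predictors and the panel score as the response. Hyperparameters (number
of latent components and keepX, the number of selected variables per
component) come from repeated 5-fold cross-validation maximizing held-out
Q^2. VIP scores summarize each feature's contribution; VIP > 1 marks
above-average importance.
"""

import numpy as np

from sensomet import (
    SyntheticConfig, fit_spls, generate_dataset, grid_search, preprocess,
)

table, meta, scores, db, truth = generate_dataset(SyntheticConfig(seed=0))
processed, _ = preprocess(table, meta)

X = processed.intensities.to_numpy().T
ids = [str(f) for f in processed.feature_ids]
y = scores.aligned_to(processed)["astringency"].to_numpy()

cv = grid_search(X, y, "spls", comp_grid=(1, 2, 3), keepX_grid=(50, 100, 200),
                 n_repeats=10, k=5, seed=0)
ncomp, keepx = cv.best_pair
print(f"selected (components, keepX) = {cv.best_pair}, "
      f"held-out Q^2 = {cv.criterion_at(ncomp, keepx):.3f}")

model = fit_spls(X, y, ncomp, keepx, feature_ids=ids)
order = np.argsort(-model.vip)
planted = set(truth.biomarker_map["astringency"])
print("top 10 features by VIP (star = planted biomarker):")
for i in order[:10]:
    star = "*" if ids[i] in planted else " "
    print(f"  {star} {ids[i]}  VIP={model.vip[i]:.2f}")
hits = sum(ids[i] in planted for i in order[:50])
print(f"planted biomarkers recovered in top 50: {hits}/{len(planted)}")
# High recovery shows the VIP ranking finds the features that actually
# drive the attribute score.
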
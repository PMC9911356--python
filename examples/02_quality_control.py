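"""Quality control: is there anything to match, and which pairs to drop.

Part 1 runs the sign-flip matchability test on a correlated pair and on an
independent pair.  Part 2 corrupts 10% of aligned pairs across two
clusters and lets the jointly regularized filter find them.
"""

import numpy as np

from mario import (
    ExpressionBundle,
    align_shared_features,
    matchability_test,
    regularized_kmeans_filter,
)

rng = np.random.default_rng(0)
n, p = 400, 15
names = [f"f{j}" for j in range(p)]

base = rng.normal(size=(n, p))
perm = rng.permutation(n)
x = ExpressionBundle([f"x{i}" for i in range(n)], names, base)
y_corr = ExpressionBundle([f"y{i}" for i in range(n)], names,
                          base[perm] + 0.3 * rng.normal(size=(n, p)))
y_null = ExpressionBundle([f"y{i}" for i in range(n)], names, rng.normal(size=(n, p)))

for label, yb in (("correlated", y_corr), ("independent", y_null)):
    xa, ya = align_shared_features(x, yb)
    rep = matchability_test(xa, ya, B=20, seed=1, fast=True)
    print(f"{label:12s}: observed={rep.observed:.3f} "
          f"background mean={rep.background.mean():.3f} p={rep.p_value:.3f}")
# A small p-value means the cross-dataset correlation survives far above
# the sign-flipped background, i.e. the datasets are matchable.

print()
sep = 6.0
centers = np.vstack([np.zeros(6), np.full(6, sep)])
labels = np.repeat([0, 1], 100)
xa = centers[labels] + 0.5 * rng.normal(size=(200, 6))
ya = centers[labels] + 0.5 * rng.normal(size=(200, 6))
bad = rng.choice(100, size=20, replace=False)
ya[bad] = ya[100 + bad]  # 10% of pairs now straddle the two clusters

res = regularized_kmeans_filter(xa, ya, K=2, rho=0.2, n_iter=20, seed=0)
good = np.setdiff1d(np.arange(200), bad)
print(f"injected bad pairs removed : {np.mean(~res.keep_mask[bad]):.2f}")
print(f"good pairs removed         : {np.mean(~res.keep_mask[good]):.2f}")
# Pairs whose per-dataset cluster labels disagree are flagged as spurious.
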
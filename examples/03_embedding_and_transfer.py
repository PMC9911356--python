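"""Joint embedding of matched pairs and kNN label transfer.

After matching, the aligned pairs are embedded by CCA (scores z-scored
within dataset); population labels known only for Y are transferred to X
by majority vote over the interpolated cross-distance.
"""

import numpy as np

from mario import (
    MarioParams,
    joint_embed,
    knn_label_transfer,
    match_pipeline,
    normalize_features,
)
from mario.simdata import SynthConfig, generate_pair, population_labels

cfg = SynthConfig(n_populations=5, n_cells_x=300, n_cells_y=600,
                  p_shared=20, p_distinct_x=20, p_distinct_y=20, seed=3)
x, y, truth = generate_pair(cfg)
x, y = normalize_features(x), normalize_features(y)

result = match_pipeline(x, y, MarioParams(seed=3), return_distance=True)
m = result.matching

emb = joint_embed(x.matrix_full, y.matrix_full[m.pairs], r=10)
print(f"embedding components : {emb.scores[0].shape[1]}")
print(f"top-3 canonical corr : {np.round(emb.correlations[:3], 3)}")

idx, d_lambda = result.distances[0]
pred = knn_label_transfer(d_lambda, population_labels(truth, "y"), k=5)
acc = np.mean(pred == population_labels(truth, "x"))
print(f"label transfer accuracy: {acc:.3f} (Y population labels voted onto X cells)")
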
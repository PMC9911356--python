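"""Benchmarking metrics and perturbation scenarios.

Seven scores evaluate a matching/embedding: matching accuracy and
proportion on the matching itself; structure alignment, Silhouette F1,
ARI F1 and average mixing on the joint embedding; and the error-avoidance
score for the deleted-cell-type scenario.  Three perturbations stress the
pipeline: accumulative removal of shared features, Gaussian noise spiked
into the normalized values, and deletion of whole cell types from the
dataset being matched against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .matching import UNMATCHED, Matching

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkReport",
    "matching_accuracy",
    "matching_proportion",
    "structure_alignment",
    "silhouette_f1",
    "ari_f1",
    "avg_mixing",
    "error_avoidance",
    "scenario_perturb",
]


@dataclass
class BenchmarkReport:
    matching_accuracy: float
    matching_proportion: float
    structure_alignment: float | None = None
    silhouette_f1: float | None = None
    ari_f1: float | None = None
    avg_mixing: float | None = None
    error_avoidance: float | None = None
    matching_accuracy_matched_only: float | None = None
    scenario: dict = field(default_factory=dict)


def matching_accuracy(
    matching: Matching,
    labels_x: np.ndarray,
    labels_y: np.ndarray,
    denominator: str = "all",
) -> float:
    """Fraction of X cells paired with a Y cell of the same type.

    ``denominator="all"`` divides by every X cell (matched or not), so
    filtering trades the numerator against the proportion transparently;
    ``denominator="matched"`` divides by the matched cells only.
    """
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    matched = matching.matched_mask
    correct = int(
        np.sum(labels_x[matched] == labels_y[matching.pairs[matched]])
    )
    if denominator == "all":
        denom = len(matching.pairs)
    elif denominator == "matched":
        denom = int(matched.sum())
    else:
        raise ValueError("denominator must be 'all' or 'matched'")
    return correct / denom if denom else 0.0


def matching_proportion(matching: Matching) -> float:
    """Fraction of X cells that still have a match after quality control."""
    return matching.n_matched / len(matching.pairs) if len(matching.pairs) else 0.0


def structure_alignment(original: np.ndarray, embedded: np.ndarray) -> float:
    """Structural preservation of one dataset through the embedding.

    Per cell, the Pearson correlation between its row of the full-feature
    Euclidean distance matrix and its row of the embedding distance
    matrix; averaged over cells.  Cells whose distance row is constant in
    either space are skipped with a warning.  For a matched pair, apply to
    X and Y separately and average the two scores.
    """
    original = np.asarray(original, dtype=float)
    embedded = np.asarray(embedded, dtype=float)
    if original.shape[0] != embedded.shape[0]:
        raise ValueError("original and embedded must have the same cells")
    d_full = cdist(original, original)
    d_part = cdist(embedded, embedded)
    scores = []
    skipped = 0
    for i in range(original.shape[0]):
        a, b = d_full[i], d_part[i]
        if a.std() <= 1e-12 or b.std() <= 1e-12:
            skipped += 1
            continue
        scores.append(np.corrcoef(a, b)[0, 1])
    if skipped:
        warnings.warn(f"structure_alignment: {skipped} degenerate cell(s) skipped", stacklevel=2)
    if not scores:
        raise ValueError("all cells degenerate; structure alignment undefined")
    return float(np.mean(scores))


def _normalized_silhouette(emb: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width mapped from [-1, 1] to [0, 1]."""
    s = silhouette_score(emb, labels)
    return (s + 1.0) / 2.0


def _harmonic(a: float, b: float) -> float:
    if a + b <= 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def silhouette_f1(
    embedding: np.ndarray, dataset_labels: np.ndarray, type_labels: np.ndarray
) -> float:
    """Harmonic mean of dataset mixing (1 - normalized silhouette over the
    dataset label) and information preservation (normalized silhouette over
    the cell-type label)."""
    slt_mix = 1.0 - _normalized_silhouette(embedding, dataset_labels)
    slt_clust = _normalized_silhouette(embedding, type_labels)
    return _harmonic(slt_mix, slt_clust)


def ari_f1(
    embedding: np.ndarray,
    dataset_labels: np.ndarray,
    type_labels: np.ndarray,
    K: int,
    seed: int = 0,
) -> float:
    """Like the Silhouette F1 but with the adjusted Rand index of a seeded
    k-means clustering of the embedding; ARI values are clipped at 0
    because the harmonic mean requires non-negative parts."""
    clusters = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(embedding)
    ari_mix = 1.0 - min(max(adjusted_rand_score(dataset_labels, clusters), 0.0), 1.0)
    ari_clust = min(max(adjusted_rand_score(type_labels, clusters), 0.0), 1.0)
    return _harmonic(ari_mix, ari_clust)


def avg_mixing(
    embedding: np.ndarray,
    dataset_labels: np.ndarray,
    cluster_labels: np.ndarray,
) -> float:
    """Kolmogorov-Smirnov-based dataset mixing.

    Per cluster and per embedding coordinate, 1 - KS statistic between the
    two datasets' coordinate values; per-cluster score is the median over
    coordinates and the final score the mean over clusters.
    """
    embedding = np.asarray(embedding, dtype=float)
    dataset_labels = np.asarray(dataset_labels)
    cluster_labels = np.asarray(cluster_labels)
    ds = np.unique(dataset_labels)
    if len(ds) != 2:
        raise ValueError("avg_mixing requires exactly 2 dataset labels")
    scores = []
    for cl in np.unique(cluster_labels):
        in_cl = cluster_labels == cl
        a = embedding[in_cl & (dataset_labels == ds[0])]
        b = embedding[in_cl & (dataset_labels == ds[1])]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"avg_mixing: cluster {cl!r} absent from one dataset; skipped", stacklevel=2)
            continue
        per_coord = [
            1.0 - ks_2samp(a[:, j], b[:, j]).statistic for j in range(embedding.shape[1])
        ]
        scores.append(float(np.median(per_coord)))
    if not scores:
        raise ValueError("no cluster present in both datasets")
    return float(np.mean(scores))


def error_avoidance(
    matching: Matching,
    dropped_type,
    labels_x: np.ndarray,
    inverted: bool = False,
) -> float:
    """sqrt(a / b) over X cells of a deliberately deleted Y cell type.

    ``a`` counts cells of that type in X that are still matched after
    quality control, ``b`` all X cells of that type.  The literal formula
    increases when forced matches toward the deleted type survive;
    ``inverted=True`` reports 1 - sqrt(a/b) so that larger means better
    avoided.
    """
    labels_x = np.asarray(labels_x)
    of_type = labels_x == dropped_type
    b = int(of_type.sum())
    if b == 0:
        raise ValueError(f"no X cells of type {dropped_type!r}")
    a = int((of_type & matching.matched_mask).sum())
    score = float(np.sqrt(a / b))
    return 1.0 - score if inverted else score


def scenario_perturb(
    x,
    y,
    *,
    drop_features: list[str] | None = None,
    noise_sd: float | None = None,
    drop_types: list | None = None,
    labels_y: np.ndarray | None = None,
    seed: int = 0,
):
    """Apply one of the three benchmark perturbations to an aligned pair.

    drop_features removes the named shared features from both datasets;
    noise_sd adds seeded N(0, sd^2) noise to every value of both datasets
    (intended for already-normalized values); drop_types removes all Y
    cells whose label is listed (X is untouched).  Returns the perturbed
    (X, Y) pair; with drop_types and ``labels_y`` given, also the retained
    Y labels.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    labels_out = labels_y
    if drop_features is not None:
        for bundle_name, bundle in (("X", x), ("Y", y)):
            missing = set(drop_features) - set(bundle.feature_names)
            if missing:
                raise ValueError(f"{bundle_name} lacks features {sorted(missing)}")
        x = x.subset_features(
            np.array([j for j, nm in enumerate(x.feature_names) if nm not in drop_features], dtype=int)
        )
        y = y.subset_features(
            np.array([j for j, nm in enumerate(y.feature_names) if nm not in drop_features], dtype=int)
        )
    if noise_sd is not None and noise_sd > 0:
        x = replace(x, values=x.values + rng.normal(0.0, noise_sd, x.values.shape))
        y = replace(y, values=y.values + rng.normal(0.0, noise_sd, y.values.shape))
    if drop_types:
        if labels_y is None:
            raise ValueError("drop_types requires labels_y")
        labels_y = np.asarray(labels_y)
        keep = ~np.isin(labels_y, list(drop_types))
        y = y.subset_cells(np.flatnonzero(keep))
        labels_out = labels_y[keep]
    if drop_types:
        return x, y, labels_out
    return x, y
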
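"""Joint embedding of matched datasets and kNN label transfer.

After filtering, the surviving aligned pairs X*, Y* are embedded by CCA:
each dataset's sample canonical scores, z-scored per component within the
dataset, form the joint low-dimensional coordinates.  For three or more
row-aligned datasets the MAXVAR formulation of generalized CCA is used: a
common score matrix maximizing the summed squared correlation with each
dataset's best projection, obtained from the SVD of the concatenated
orthonormal column bases.  Label transfer runs a majority vote over the
k nearest Y cells in the interpolated cross-distance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .matching import CrossDistance, fit_cca

logger = logging.getLogger(__name__)

__all__ = ["JointEmbedding", "joint_embed", "gcca_embed", "knn_label_transfer"]


@dataclass
class JointEmbedding:
    """Per-dataset canonical score matrices (cells x r), scaled within
    dataset to zero mean and unit variance per component, plus the
    per-component correlations."""

    scores: list[np.ndarray]
    correlations: np.ndarray


def _scale_columns(m: np.ndarray) -> np.ndarray:
    c = m - m.mean(axis=0, keepdims=True)
    sd = c.std(axis=0, ddof=1, keepdims=True) if m.shape[0] > 1 else np.ones((1, m.shape[1]))
    sd = np.where(sd <= 1e-12, 1.0, sd)
    return c / sd


def joint_embed(xstar: np.ndarray, ystar: np.ndarray, r: int, ridge: float | None = None) -> JointEmbedding:
    """CCA joint embedding of the filtered aligned pair."""
    xstar = np.asarray(xstar, dtype=float)
    ystar = np.asarray(ystar, dtype=float)
    r_max = min(xstar.shape[1], ystar.shape[1], xstar.shape[0] - 1)
    if r > r_max:
        logger.warning("embedding r=%d clipped to %d", r, r_max)
        r = r_max
    model = fit_cca(xstar, ystar, r=r, ridge=ridge)
    sx = _scale_columns(model.scores_x(xstar))
    sy = _scale_columns(model.scores_y(ystar))
    return JointEmbedding(scores=[sx, sy], correlations=model.correlations)


def _orthobasis(m: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    c = m - m.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(c, full_matrices=False)
    rank = int(np.sum(s > tol * s.max())) if s.size else 0
    return u[:, :rank]

def gcca_embed(datasets: list[np.ndarray], r: int) -> JointEmbedding:
    """MAXVAR generalized CCA for two or more row-aligned datasets.

    The common scores are the top-r left singular vectors of the
    concatenation of the datasets' orthonormal column bases; per-dataset
    scores are the projections of the common scores onto each dataset's
    column space.  For two datasets the per-dataset score subspaces
    coincide with those of ordinary CCA.
    """
    if len(datasets) < 2:
        raise ValueError("gCCA requires at least 2 datasets")
    mats = [np.asarray(m, dtype=float) for m in datasets]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("all datasets must share the same number of rows")
    bases = [_orthobasis(m) for m in mats]
    concat = np.hstack(bases)
    u, s, _ = np.linalg.svd(concat, full_matrices=False)
    r_max = min(min(b.shape[1] for b in bases), u.shape[1])
    if r > r_max:
        logger.warning("gCCA r=%d clipped to %d", r, r_max)
        r = r_max
    g = u[:, :r]
    scores = [_scale_columns(b @ (b.T @ g)) for b in bases]
    # per-component mean pairwise correlation between dataset scores
    corrs = np.empty(r)
    for j in range(r):
        cs = []
        for a in range(len(scores)):
            for b in range(a + 1, len(scores)):
                cs.append(np.corrcoef(scores[a][:, j], scores[b][:, j])[0, 1])
        corrs[j] = np.mean(cs)
    return JointEmbedding(scores=scores, correlations=corrs)


def knn_label_transfer(
    d: CrossDistance | np.ndarray, labels_y: np.ndarray, k: int = 5
) -> np.ndarray:
    """Transfer Y labels to X cells by majority vote over the k nearest Y
    cells in the interpolated cross-distance.

    Ties between labels with equal votes are broken by the label of the
    single nearest cell among the tied labels.
    """
    vals = d.values if isinstance(d, CrossDistance) else np.asarray(d, dtype=float)
    vals = np.asarray(vals if isinstance(vals, np.ndarray) else vals.toarray(), dtype=float)
    labels_y = np.asarray(labels_y)
    n_x, n_y = vals.shape
    if labels_y.shape[0] != n_y:
        raise ValueError("labels_y must be total on Y")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_y:
        logger.warning("k=%d clipped to n_y=%d", k, n_y)
        k = n_y
    out = np.empty(n_x, dtype=labels_y.dtype)
    for i in range(n_x):
        nn = np.argpartition(vals[i], k - 1)[:k]
        nn = nn[np.argsort(vals[i][nn], kind="stable")]
        votes = Counter(labels_y[nn].tolist())
        top = max(votes.values())
        tied = {lab for lab, c in votes.items() if c == top}
        for j in nn:  # nearest-first walk settles ties
            if labels_y[j] in tied:
                out[i] = labels_y[j]
                break
    return out
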
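"""Quality control: matchability testing and jointly regularized filtering.

Two safeguards sit between matching and embedding.  The *matchability
test* asks whether the two datasets are correlated at all: random
sign-flips of cell rows destroy inter-dataset correlation while leaving
each dataset's own covariance intact, so re-running the matcher on
flipped replicates builds a null distribution for the post-alignment
canonical-correlation statistic.  *Jointly regularized filtering* then
removes individually spurious pairs: a regularized k-means objective ties
per-dataset cluster labels to a global label through a Hamming penalty
log((1-rho)/(rho/(K-1))); matched pairs whose two individual labels
disagree at the optimum are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .matching import UNMATCHED, MarioParams, Matching, fit_cca, match_pipeline

logger = logging.getLogger(__name__)

__all__ = [
    "MatchabilityReport",
    "FilterResult",
    "matchability_test",
    "spectral_init",
    "regularized_kmeans_filter",
    "apply_filter",
]


@dataclass
class MatchabilityReport:
    B: int
    p_flip: float
    background: np.ndarray  # mean top-k canonical correlation per flip replicate
    observed: float
    p_value: float
    n_dropped: int = 0


@dataclass
class FilterResult:
    """Labels, centroids and keep-mask of the jointly regularized filter."""

    K: int
    rho: float
    z_star: np.ndarray
    z_x: np.ndarray
    z_y: np.ndarray
    mu: np.ndarray  # K x p_x centroids for X
    nu: np.ndarray  # K x p_y centroids for Y
    keep_mask: np.ndarray
    penalty_weight: float
    objective_history: list[float] = field(default_factory=list)


def _alignment_statistic(
    x_full: np.ndarray, y_full: np.ndarray, pairs: np.ndarray, top_k: int
) -> float:
    ya = y_full[pairs]
    r = min(top_k, x_full.shape[1], y_full.shape[1], x_full.shape[0] - 1)
    model = fit_cca(x_full, ya, r=r, top_k=top_k)
    return model.mean_top_k(top_k)


def _shared_only_matcher(x, y, params: MarioParams) -> Matching:
    """Fast mode: initial shared-feature matching only (no refinement)."""
    from .matching import correlation_distance, denoise_shared, solve_assignment, sparsify

    r_share = min(params.n_components_ovlp, x.matrix_shared.shape[1])
    den = denoise_shared(x.matrix_shared, y.matrix_shared, r_share)
    d = correlation_distance(den.x_hat, den.y_hat)
    sp = params.sparsity if params.sparsity < y.n_cells else None
    return solve_assignment(d if sp is None else sparsify(d, sp))


def matchability_test(
    x,
    y,
    B: int = 20,
    p_flip: float = 0.2,
    top_k: int = 10,
    seed: int = 0,
    params: MarioParams | None = None,
    fast: bool = False,
    conservative: bool = True,
) -> MatchabilityReport:
    """Sign-flip test of the null that X and Y are uncorrelated.

    For each of B replicates, every row of X and of Y is multiplied by an
    independent Rademacher sign (-1 with probability ``p_flip``); the
    matcher is rerun on the flipped pair and the mean of the top-k sample
    canonical correlations after alignment is recorded.  The p-value is
    the proportion of background statistics at least as large as the
    observed one; ``conservative=True`` uses (#{>=} + 1)/(B + 1) so the
    p-value can never be exactly zero at finite B.  ``fast=True``
    restricts each replicate to the shared-feature initial matching.
    """
    if not (0 < p_flip <= 0.5):
        raise ValueError("p_flip must lie in (0, 0.5]")
    if B < 1:
        raise ValueError("B must be >= 1")
    params = params or MarioParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def run(xb, yb) -> float:
        if fast:
            m = _shared_only_matcher(xb, yb, params)
        else:
            m = match_pipeline(xb, yb, params).matching
        return _alignment_statistic(xb.matrix_full, yb.matrix_full, m.pairs, top_k)

    observed = run(x, y)
    background: list[float] = []
    dropped = 0
    for b in range(B):
        eps_x = np.where(rng.random(x.n_cells) < p_flip, -1.0, 1.0)
        eps_y = np.where(rng.random(y.n_cells) < p_flip, -1.0, 1.0)
        xb = replace(x, values=x.values * eps_x[:, None])
        yb = replace(y, values=y.values * eps_y[:, None])
        try:
            background.append(run(xb, yb))
        except Exception as e:  # matcher failure on a replicate
            dropped += 1
            warnings.warn(f"matchability replicate {b} dropped: {e}", stacklevel=2)
    if dropped > 0.2 * B:
        raise RuntimeError(
            f"{dropped}/{B} matchability replicates failed; data unusable for the test"
        )
    bg = np.asarray(background)
    n_ge = int((bg >= observed).sum())
    if conservative:
        p_value = (n_ge + 1) / (len(bg) + 1)
    else:
        p_value = n_ge / len(bg)
    return MatchabilityReport(
        B=B,
        p_flip=p_flip,
        background=bg,
        observed=float(observed),
        p_value=float(p_value),
        n_dropped=dropped,
    )


def spectral_init(
    xa: np.ndarray, ya: np.ndarray, K: int, seed: int = 0
) -> np.ndarray:
    """Spectral warm start for the filter.

    Computes the sample canonical scores of the aligned pair, averages the
    two score matrices, takes the top-K left singular vectors of the
    average and runs seeded k-means on them.
    """
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    n = xa.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of pairs {n}")
    if K == 1:
        return np.zeros(n, dtype=int)
    r = min(xa.shape[1], ya.shape[1], n - 1)
    model = fit_cca(xa, ya, r=r)
    avg = 0.5 * (model.scores_x(xa) + model.scores_y(ya))
    u, s, _ = np.linalg.svd(avg, full_matrices=False)
    k_eff = min(K, u.shape[1])
    basis = u[:, :k_eff] * s[:k_eff]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    return km.fit_predict(basis)


def _objective(
    xa, ya, mu, nu, z_star, z_x, z_y, penalty: float
) -> float:
    dx = 0.5 * np.sum((xa - mu[z_x]) ** 2)
    dy = 0.5 * np.sum((ya - nu[z_y]) ** 2)
    pen = penalty * (np.sum(z_x != z_star) + np.sum(z_y != z_star))
    return float(dx + dy + pen)


def _label_update(
    cost_x: np.ndarray, cost_y: np.ndarray, penalty: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair exact minimization over (z_star, z_x, z_y) by enumeration.

    For each hypothesized global label k, the best individual labels
    decouple; ties are resolved toward the smallest label index (and the
    smallest global label), matching a lexicographic exhaustive search.
    """
    n, K = cost_x.shape
    pen = penalty * (1.0 - np.eye(K))  # pen[k, j] for z_star=k, label j
    tot_x = cost_x[:, None, :] + pen[None, :, :]  # (n, K_star, K_label)
    tot_y = cost_y[:, None, :] + pen[None, :, :]
    zx_k = np.argmin(tot_x, axis=2)
    zy_k = np.argmin(tot_y, axis=2)
    best = np.min(tot_x, axis=2) + np.min(tot_y, axis=2)  # (n, K_star)
    z_star = np.argmin(best, axis=1)
    rows = np.arange(n)
    return z_star, zx_k[rows, z_star], zy_k[rows, z_star]


def regularized_kmeans_filter(
    xa: np.ndarray,
    ya: np.ndarray,
    K: int = 10,
    rho: float = 0.2,
    n_iter: int = 20,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
) -> FilterResult:
    """Jointly regularized k-means over the aligned matched pairs.

    Block coordinate descent alternates (i) centroid updates (per-label
    means of X rows and of Y rows) and (ii) the exact per-pair label
    update enumerating all global-label hypotheses.  The objective is
    non-increasing at every half step; clusters that empty out retain
    their previous centroid.  Pairs whose X and Y labels disagree at the
    end are flagged for removal.
    """
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    n = xa.shape[0]
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("Xa and Ya must be row-aligned")
    if not (0 < rho < 1 - 1 / K):
        raise ValueError(f"rho must lie in (0, 1 - 1/K) = (0, {1 - 1 / K:.4f})")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    penalty = float(np.log((1 - rho) / (rho / (K - 1))))

    if init_labels is None:
        init_labels = spectral_init(xa, ya, K, seed=seed)
    z_x = np.asarray(init_labels, dtype=int).copy()
    z_y = z_x.copy()
    z_star = z_x.copy()

    mu = np.empty((K, xa.shape[1]))
    nu = np.empty((K, ya.shape[1]))
    # deterministic initial centroids; empty initial clusters get the
    # global mean so later "retain previous" updates are well defined
    gx, gy = xa.mean(axis=0), ya.mean(axis=0)
    for k in range(K):
        mx, my = z_x == k, z_y == k
        mu[k] = xa[mx].mean(axis=0) if mx.any() else gx
        nu[k] = ya[my].mean(axis=0) if my.any() else gy

    history: list[float] = [_objective(xa, ya, mu, nu, z_star, z_x, z_y, penalty)]
    for _ in range(n_iter):
        # (i) centroid update
        for k in range(K):
            mx, my = z_x == k, z_y == k
            if mx.any():
                mu[k] = xa[mx].mean(axis=0)
            else:
                logger.debug("cluster %d empty for X; centroid retained", k)
            if my.any():
                nu[k] = ya[my].mean(axis=0)
            else:
                logger.debug("cluster %d empty for Y; centroid retained", k)
        history.append(_objective(xa, ya, mu, nu, z_star, z_x, z_y, penalty))
        # (ii) label update
        cost_x = 0.5 * (
            np.sum(xa**2, axis=1)[:, None]
            - 2 * xa @ mu.T
            + np.sum(mu**2, axis=1)[None, :]
        )
        cost_y = 0.5 * (
            np.sum(ya**2, axis=1)[:, None]
            - 2 * ya @ nu.T
            + np.sum(nu**2, axis=1)[None, :]
        )
        z_star, z_x, z_y = _label_update(cost_x, cost_y, penalty)
        history.append(_objective(xa, ya, mu, nu, z_star, z_x, z_y, penalty))
    return FilterResult(
        K=K,
        rho=rho,
        z_star=z_star,
        z_x=z_x,
        z_y=z_y,
        mu=mu,
        nu=nu,
        keep_mask=z_x == z_y,
        penalty_weight=penalty,
        objective_history=history,
    )


def apply_filter(matching: Matching, result: FilterResult) -> Matching:
    """Drop matched pairs flagged by the filter (keep_mask False).

    ``result`` must have been computed on the matching's aligned pairs, in
    matched order; removal can only shrink the map, so injectivity holds.
    """
    matched_idx = np.flatnonzero(matching.matched_mask)
    if matched_idx.size != result.keep_mask.size:
        raise ValueError(
            f"filter computed on {result.keep_mask.size} pairs but matching has "
            f"{matched_idx.size} matched cells"
        )
    pairs = matching.pairs.copy()
    pairs[matched_idx[~result.keep_mask]] = UNMATCHED
    return Matching(pairs=pairs, lambda_used=matching.lambda_used, quality=matching.quality)
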
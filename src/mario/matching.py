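"""Cross-dataset cell matching via rectangular linear assignment.

The matching is built in three stages.  First, the shared feature blocks
of both datasets are jointly denoised by a truncated SVD of their vertical
concatenation and an initial matching is solved on the Pearson
cross-distance of the denoised rows.  Second, that initial alignment is
used to fit CCA on the *full* feature matrices (shared + distinct), and a
refined distance is computed between the canonical scores of all cells so
that the distinct panels contribute.  Third, the two distance matrices are
interpolated on a lambda grid; for each interpolated matching the mean of
the top-k sample canonical correlations after alignment serves as a
quality proxy, and the best lambda is kept.

Assignment problems are solved globally (never greedily): dense instances
through ``scipy.optimize.linear_sum_assignment``, sparsified instances
through ``scipy.sparse.csgraph.min_weight_full_bipartite_matching``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import (
    maximum_bipartite_matching,
    min_weight_full_bipartite_matching,
)

logger = logging.getLogger(__name__)

UNMATCHED = -1

__all__ = [
    "UNMATCHED",
    "Matching",
    "CrossDistance",
    "CCAModel",
    "DenoisedShared",
    "MarioParams",
    "MatchResult",
    "denoise_shared",
    "correlation_distance",
    "laplacian_distance",
    "solve_assignment",
    "sparsify",
    "fit_cca",
    "refine_distance",
    "interpolate_and_select",
    "match_pipeline",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Matching:
    """An injective map from X cells to Y cells.

    ``pairs[i]`` is the Y index matched to X cell ``i`` or ``UNMATCHED``
    (-1).  Before filtering the map is total on X; filtering may only
    remove pairs, which preserves injectivity.
    """

    pairs: np.ndarray
    lambda_used: float | None = None
    quality: float | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.validate()

    @classmethod
    def unchecked(cls, pairs, lambda_used=None, quality=None) -> "Matching":
        """Construct without the injectivity check (multi-batch, non-strict
        mode, where Y reuse across batches is documented behaviour)."""
        m = cls.__new__(cls)
        m.pairs = np.asarray(pairs, dtype=int)
        m.lambda_used = lambda_used
        m.quality = quality
        return m

    def validate(self) -> None:
        matched = self.pairs[self.pairs != UNMATCHED]
        if len(np.unique(matched)) != len(matched):
            raise ValueError("matching is not injective: a Y cell appears twice")

    @property
    def matched_mask(self) -> np.ndarray:
        return self.pairs != UNMATCHED

    @property
    def n_matched(self) -> int:
        return int(self.matched_mask.sum())


@dataclass
class CrossDistance:
    """An n_x-by-n_y cross-data distance, dense or row-sparse candidates.

    ``kind`` records provenance (share / all / interpolated); Pearson-based
    entries lie in [0, 2].  The sparse form stores per X row a candidate
    list of Y columns with distances.
    """

    values: np.ndarray | csr_matrix
    kind: str = "share"
    lam: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_sparse(self) -> bool:
        return not isinstance(self.values, np.ndarray)


@dataclass
class DenoisedShared:
    x_hat: np.ndarray
    y_hat: np.ndarray
    r_share: int
    singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class CCAModel:
    """Paired canonical loading matrices with training-set column means.

    Scores are computed as ``(M - mean) @ W``; ``correlations`` is the
    descending vector of sample canonical correlations in [0, 1].
    """

    w_x: np.ndarray
    w_y: np.ndarray
    correlations: np.ndarray
    r: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    top_k: int = 10

    def scores_x(self, m: np.ndarray) -> np.ndarray:
        return (np.asarray(m, dtype=float) - self.mean_x) @ self.w_x

    def scores_y(self, m: np.ndarray) -> np.ndarray:
        return (np.asarray(m, dtype=float) - self.mean_y) @ self.w_y

    def mean_top_k(self, top_k: int | None = None) -> float:
        k = min(top_k or self.top_k, len(self.correlations))
        return float(np.mean(self.correlations[:k]))


@dataclass
class MarioParams:
    """Pipeline parameters.

    n_components_ovlp : rank kept when denoising the shared blocks
        (clipped to the number of shared features).
    n_components_all : CCA components for the refined, all-feature distance
        (clipped to the available rank).
    sparsity : per-row candidate count for the assignment search space;
        values >= n_y leave the problem dense.
    n_batch : number of random equal-sized X batches, each matched against
        the full Y dataset.
    """

    n_components_ovlp: int = 10
    n_components_all: int = 20
    sparsity: int = 5000
    n_batch: int = 1
    lambda_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 10))
    top_k: int = 10
    distance: str = "pearson"  # or "laplacian"
    bandwidth: float | str = "median"
    ridge: float | None = None  # None => trace-scaled 1e-6 default in fit_cca
    strict_batches: bool = False
    seed: int = 0


@dataclass
class MatchResult:
    """Output of :func:`match_pipeline`: the concatenated matching plus
    per-batch metadata and (optionally) the interpolated distances."""

    matching: Matching
    batch_info: list[dict]
    distances: list[tuple[np.ndarray, CrossDistance]] | None = None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def denoise_shared(xs: np.ndarray, ys: np.ndarray, r_share: int) -> DenoisedShared:
    """Joint low-rank denoising of the column-aligned shared blocks.

    Stacks X_share over Y_share, truncates the SVD of the stack at
    ``r_share`` components and splits the reconstruction back.  Both
    reconstructions therefore use identical right singular vectors and
    singular values.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape[1] != ys.shape[1]:
        raise ValueError("shared blocks must be column-aligned")
    p = xs.shape[1]
    if r_share < 1:
        raise ValueError("r_share must be >= 1")
    if r_share > p:
        logger.warning("r_share=%d clipped to p_share=%d", r_share, p)
        r_share = p
    stack = np.vstack([xs, ys])
    u, d, vt = np.linalg.svd(stack, full_matrices=False)
    recon = (u[:, :r_share] * d[:r_share]) @ vt[:r_share]
    return DenoisedShared(
        x_hat=recon[: xs.shape[0]],
        y_hat=recon[xs.shape[0] :],
        r_share=r_share,
        singular_values=d,
    )


def _standardize_rows(m: np.ndarray) -> tuple[np.ndarray, int]:
    """Center and unit-normalize rows; zero-variance rows become 0 rows."""
    m = np.asarray(m, dtype=float)
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    flat = norm[:, 0] <= 1e-300
    norm[flat] = 1.0
    out = c / norm
    out[flat] = 0.0
    return out, int(flat.sum())


def correlation_distance(a: np.ndarray, b: np.ndarray, kind: str = "share") -> CrossDistance:
    """Pearson cross-distance: entry (i, i') = 1 - cor(A_i, B_i').

    Rows with zero variance have undefined correlation; they are treated
    as correlation 0 (distance 1) and counted in the log.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("row dimension mismatch")
    if a.shape[1] < 2:
        raise ValueError("row-wise Pearson correlation requires >= 2 features")
    an, fa = _standardize_rows(a)
    bn, fb = _standardize_rows(b)
    if fa or fb:
        logger.warning(
            "%d zero-variance rows treated as correlation 0 (distance 1)", fa + fb
        )
    d = 1.0 - an @ bn.T
    np.clip(d, 0.0, 2.0, out=d)
    return CrossDistance(values=d, kind=kind)


def laplacian_distance(
    a: np.ndarray,
    b: np.ndarray,
    bandwidth: float | str = "median",
    seed: int = 0,
    kind: str = "share",
) -> CrossDistance:
    """Laplacian-kernel cross-distance: 1 - exp(-||A_i - B_i'||_1 / h).

    ``bandwidth="median"`` estimates h as the median L1 distance over a
    seeded subsample of at most 1000 row pairs.
    """
    from scipy.spatial.distance import cdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("row dimension mismatch")
    if bandwidth == "median":
        rng = np.random.default_rng(seed)
        n_pairs = min(1000, a.shape[0] * b.shape[0])
        ia = rng.integers(0, a.shape[0], n_pairs)
        ib = rng.integers(0, b.shape[0], n_pairs)
        h = float(np.median(np.abs(a[ia] - b[ib]).sum(axis=1)))
        if h <= 0:
            h = 1.0
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    d = 1.0 - np.exp(-cdist(a, b, metric="cityblock") / h)
    return CrossDistance(values=d, kind=kind)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def _canonicalize_pairs(pairs: np.ndarray, d: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Make an optimal assignment canonical: among cost-neutral transpositions,
    prefer the lexicographically smallest pair list."""
    pairs = pairs.copy()
    n = len(pairs)
    for _ in range(10):
        changed = False
        for i in range(n - 1):
            ji = pairs[i]
            tail = pairs[i + 1 :]
            cand = np.flatnonzero(tail < ji)
            if cand.size == 0:
                continue
            js = tail[cand]
            delta = d[i, js] + d[i + 1 + cand, ji] - d[i, ji] - d[i + 1 + cand, js]
            ok = np.abs(delta) <= atol
            if ok.any():
                pick = cand[ok][np.argmin(js[ok])]
                k = i + 1 + pick
                pairs[i], pairs[k] = pairs[k], pairs[i]
                ji = pairs[i]
                changed = True
        if not changed:
            break
    return pairs


def solve_assignment(d: CrossDistance | np.ndarray) -> Matching:
    """Globally optimal injective matching minimizing the total distance.

    Ties between equal-cost optima are broken toward the lexicographically
    smallest pair list so outputs are reproducible across platforms.
    """
    if isinstance(d, np.ndarray):
        d = CrossDistance(values=d, kind="dense")
    n_x, n_y = d.shape
    if n_x > n_y:
        raise ValueError(f"assignment infeasible: n_x={n_x} > n_y={n_y}")
    if d.is_sparse:
        mat = d.values.tocsr()
        try:
            rows, cols = min_weight_full_bipartite_matching(mat)
        except ValueError as e:  # pragma: no cover - prevented by sparsify
            raise ValueError(f"infeasible sparse assignment instance: {e}") from e
        pairs = np.full(n_x, UNMATCHED, dtype=int)
        pairs[rows] = cols
        return Matching(pairs=pairs)
    vals = np.asarray(d.values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("distance matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(vals)
    pairs = np.full(n_x, UNMATCHED, dtype=int)
    pairs[rows] = cols
    if n_x * n_y <= 4_000_000:
        pairs = _canonicalize_pairs(pairs, vals)
    return Matching(pairs=pairs)


def sparsify(d: CrossDistance, sparsity: int) -> CrossDistance:
    """Restrict the assignment search space to the ``sparsity`` nearest Y
    candidates per X row.

    If the resulting bipartite graph admits no perfect matching, high-cost
    fallback entries (max kept distance + 1) are added for the rows of the
    deficient structure until feasibility holds; augmentations are logged.
    Stored costs are shifted by +1 so that no explicit zero is lost in the
    sparse representation (a constant per-assigned-entry shift does not
    change the argmin).
    """
    if sparsity < 1:
        raise ValueError("sparsity must be >= 1")
    if d.is_sparse:
        return d
    vals = np.asarray(d.values, dtype=float)
    n_x, n_y = vals.shape
    if sparsity >= n_y:
        return d
    keep = np.argpartition(vals, sparsity - 1, axis=1)[:, :sparsity]
    rows = np.repeat(np.arange(n_x), sparsity)
    cols = keep.ravel()
    data = vals[rows, cols] + 1.0
    fallback = float(vals[rows, cols].max()) + 1.0 + 1.0
    mat = csr_matrix((data, (rows, cols)), shape=(n_x, n_y))
    # augment until a perfect matching exists
    for _ in range(n_x):
        match = maximum_bipartite_matching(mat, perm_type="column")
        missing = np.flatnonzero(match == -1)
        if missing.size == 0:
            break
        logger.warning(
            "sparsify: augmenting %d row(s) with fallback candidates", missing.size
        )
        lil = mat.tolil()
        for i in missing:
            dense_row = np.full(n_y, fallback)
            dense_row[keep[i]] = vals[i, keep[i]] + 1.0  # keep cheaper candidates
            lil[i] = dense_row
        mat = lil.tocsr()
    return CrossDistance(values=mat, kind=d.kind, lam=d.lam)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------


def _inv_sqrt_psd(s: np.ndarray, ridge: float, label: str) -> np.ndarray:
    w, v = np.linalg.eigh(s + ridge * np.eye(s.shape[0]))
    tol = 1e-10 * max(w.max(), 1.0)
    if w.min() <= tol:
        raise np.linalg.LinAlgError(
            f"{label} within-set covariance is rank deficient; pass ridge > 0"
        )
    return (v / np.sqrt(w)) @ v.T


def fit_cca(
    xa: np.ndarray,
    ya: np.ndarray,
    r: int,
    ridge: float | None = None,
    top_k: int = 10,
) -> CCAModel:
    """Canonical correlation analysis on row-aligned pairs.

    Solved deterministically by whitening both within-set covariances and
    taking the SVD of the whitened cross-covariance.  ``ridge`` adds a
    lambda*I stabilizer to each covariance; the default is trace-scaled
    1e-6 (i.e. 1e-6 * mean covariance eigenvalue), which keeps the solver
    rank-robust without noticeably biasing correlations.
    """
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    n, p1 = xa.shape
    n2, p2 = ya.shape
    if n != n2:
        raise ValueError("Xa and Ya must have the same number of rows")
    if n < 3:
        raise ValueError("CCA requires at least 3 aligned pairs")
    r_max = min(p1, p2, n - 1)
    if r > r_max:
        logger.warning("r=%d clipped to maximum available %d", r, r_max)
        r = r_max
    if r < 1:
        raise ValueError("r must be >= 1")
    mean_x = xa.mean(axis=0)
    mean_y = ya.mean(axis=0)
    xc = xa - mean_x
    yc = ya - mean_y
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    if ridge is None:
        ridge_x = 1e-6 * np.trace(sxx) / p1
        ridge_y = 1e-6 * np.trace(syy) / p2
    else:
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        ridge_x = ridge_y = float(ridge)
    try:
        isx = _inv_sqrt_psd(sxx, ridge_x, "X")
        isy = _inv_sqrt_psd(syy, ridge_y, "Y")
    except np.linalg.LinAlgError:
        raise
    u, s, vt = np.linalg.svd(isx @ sxy @ isy)
    corr = np.clip(s[:r], 0.0, 1.0)
    return CCAModel(
        w_x=isx @ u[:, :r],
        w_y=isy @ vt[:r].T,
        correlations=corr,
        r=r,
        mean_x=mean_x,
        mean_y=mean_y,
        top_k=top_k,
    )


# ---------------------------------------------------------------------------
# refinement and interpolation
# ---------------------------------------------------------------------------


def refine_distance(
    x_full: np.ndarray,
    y_full: np.ndarray,
    init: Matching,
    r_all: int,
    ridge: float | None = None,
) -> tuple[CrossDistance, CCAModel]:
    """All-feature refined distance computed in the CCA latent space.

    Y rows are aligned to X via the initial matching, CCA is fitted on the
    full feature matrices, every cell of both datasets is scored, and the
    Pearson cross-distance of the score matrices is returned.
    """
    if not init.matched_mask.all():
        raise ValueError("initial matching must be total on X")
    ya = y_full[init.pairs]
    model = fit_cca(x_full, ya, r=r_all, ridge=ridge)
    sx = model.scores_x(x_full)
    sy = model.scores_y(y_full)
    d = correlation_distance(sx, sy, kind="all")
    return d, model


def _quality(
    x_full: np.ndarray,
    y_full: np.ndarray,
    matching: Matching,
    top_k: int,
    ridge: float | None,
) -> float:
    """Mean of the top-k sample canonical correlations after alignment."""
    ya = y_full[matching.pairs]
    r = min(top_k, x_full.shape[1], y_full.shape[1], x_full.shape[0] - 1)
    model = fit_cca(x_full, ya, r=r, ridge=ridge, top_k=top_k)
    return model.mean_top_k(top_k)


def interpolate_and_select(
    d_share: CrossDistance,
    d_all: CrossDistance,
    x_full: np.ndarray,
    y_full: np.ndarray,
    grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 10)),
    top_k: int = 10,
    sparsity: int | None = None,
    ridge: float | None = None,
) -> tuple[Matching, CrossDistance]:
    """Solve the assignment on each convex combination of the two distances
    and keep the matching with the best CCA quality proxy.

    Ties are broken toward smaller lambda, i.e. toward the more
    conservative shared-feature matching.  Returns the selected matching
    (with ``lambda_used`` and ``quality`` set) and the selected
    interpolated distance.
    """
    if d_share.shape != d_all.shape:
        raise ValueError("distance matrices must have the same shape")
    grid = tuple(float(g) for g in grid)
    if 0.0 not in grid or 1.0 not in grid:
        raise ValueError("lambda grid must contain both 0 and 1")
    ds = np.asarray(d_share.values, dtype=float)
    da = np.asarray(d_all.values, dtype=float)
    best: tuple[float, float, Matching, CrossDistance] | None = None
    for lam in grid:
        d_lam = CrossDistance(values=(1.0 - lam) * ds + lam * da, kind="interpolated", lam=lam)
        problem = d_lam if sparsity is None else sparsify(d_lam, sparsity)
        m = solve_assignment(problem)
        q = _quality(x_full, y_full, m, top_k, ridge)
        logger.debug("lambda=%.2f quality=%.4f", lam, q)
        if best is None or q > best[0] + 1e-12:
            best = (q, lam, m, d_lam)
    assert best is not None
    q, lam, m, d_lam = best
    m.lambda_used = lam
    m.quality = q
    return m, d_lam


def match_pipeline(
    x,
    y,
    params: MarioParams | None = None,
    return_distance: bool = False,
) -> MatchResult:
    """Run the full matching workflow on aligned bundles.

    Per batch: denoise shared blocks, initial matching on the shared
    distance, CCA refinement on all features, lambda interpolation and
    quality-based selection.  Each batch of X is matched against the full
    Y dataset (per-batch global optimality); in consequence a Y cell may
    be reused across batches, which is logged.  ``strict_batches`` removes
    already-matched Y cells between batches instead.
    """
    from .preprocess import make_batches

    params = params or MarioParams()
    if not (x.is_aligned and y.is_aligned):
        raise ValueError("bundles must be aligned (align_shared_features) first")
    n_x, n_y = x.n_cells, y.n_cells
    plan = make_batches(x, params.n_batch, seed=params.seed, n_y=n_y)
    pairs = np.full(n_x, UNMATCHED, dtype=int)
    batch_info: list[dict] = []
    distances: list[tuple[np.ndarray, CrossDistance]] = []
    y_full = y.matrix_full
    y_share = y.matrix_shared
    available = np.ones(n_y, dtype=bool)
    for b in range(plan.n_batch):
        idx = plan.batch_indices(b)
        xb = x.subset_cells(idx)
        if params.strict_batches:
            cols = np.flatnonzero(available)
        else:
            cols = np.arange(n_y)
        if idx.size > cols.size:
            raise ValueError(
                f"batch {b}: {idx.size} X cells but only {cols.size} available Y cells"
            )
        ysh = y_share[cols]
        yfl = y_full[cols]
        r_share = min(params.n_components_ovlp, xb.matrix_shared.shape[1])
        den = denoise_shared(xb.matrix_shared, ysh, r_share)
        if params.distance == "laplacian":
            d_share = laplacian_distance(
                den.x_hat, den.y_hat, bandwidth=params.bandwidth, seed=params.seed
            )
        else:
            d_share = correlation_distance(den.x_hat, den.y_hat)
        sp = params.sparsity if params.sparsity < cols.size else None
        init = solve_assignment(d_share if sp is None else sparsify(d_share, sp))
        x_full_b = xb.matrix_full
        d_all, _model = refine_distance(
            x_full_b, yfl, init, r_all=params.n_components_all, ridge=params.ridge
        )
        m, d_lam = interpolate_and_select(
            d_share,
            d_all,
            x_full_b,
            yfl,
            grid=params.lambda_grid,
            top_k=params.top_k,
            sparsity=sp,
            ridge=params.ridge,
        )
        pairs[idx] = cols[m.pairs]
        if params.strict_batches:
            available[cols[m.pairs]] = False
        batch_info.append(
            {"batch": b, "size": int(idx.size), "lambda": m.lambda_used, "quality": m.quality}
        )
        if return_distance:
            d_lam_global = d_lam
            if params.strict_batches and cols.size != n_y:
                full = np.full((idx.size, n_y), np.inf)
                full[:, cols] = d_lam.values
                d_lam_global = CrossDistance(values=full, kind="interpolated", lam=d_lam.lam)
            distances.append((idx, d_lam_global))
    dup = n_x - len(np.unique(pairs))
    if dup > 0:
        logger.warning("%d Y cell(s) reused across batches (non-strict mode)", dup)
        matching = Matching.unchecked(pairs)
    else:
        matching = Matching(
            pairs=pairs,
            lambda_used=batch_info[0]["lambda"] if len(batch_info) == 1 else None,
            quality=batch_info[0]["quality"] if len(batch_info) == 1 else None,
        )
    return MatchResult(
        matching=matching,
        batch_info=batch_info,
        distances=distances if return_distance else None,
    )
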
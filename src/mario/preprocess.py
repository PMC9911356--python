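"""Loading, validation, normalization and batching of expression matrices.

Two datasets enter the pipeline as cell-by-feature matrices that have
already been through modality-standard preprocessing (arcsinh for mass
cytometry, CLR for antibody capture, etc.).  This module handles the
remaining plumbing: strict parsing, per-feature standardization, the
shared/distinct feature partition, and the random segmentation of the
smaller dataset into batches when it has more cells than the larger one
can absorb in a single rectangular assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBundle",
    "BatchPlan",
    "load_dataset",
    "load_mtx",
    "write_dataset",
    "normalize_features",
    "align_shared_features",
    "make_batches",
]


@dataclass
class ExpressionBundle:
    """One dataset's matrix plus its shared/distinct feature partition.

    ``shared_block`` and ``distinct_block`` are ordered column-index arrays.
    They are empty until :func:`align_shared_features` assigns them; after
    alignment they partition the feature index set, and the shared blocks of
    the two aligned bundles refer to the same biological features in the
    same order.
    """

    cell_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    shared_block: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    distinct_block: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x features matrix")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        dup = _duplicates(self.cell_ids)
        if dup:
            raise ValueError(f"duplicate cell IDs: {sorted(dup)}")
        dup = _duplicates(self.feature_names)
        if dup:
            raise ValueError(f"duplicate feature names: {sorted(dup)}")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values (NaN); reject-at-load policy")
        self.shared_block = np.asarray(self.shared_block, dtype=int)
        self.distinct_block = np.asarray(self.distinct_block, dtype=int)

    # -- shapes ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_aligned(self) -> bool:
        return self.shared_block.size > 0

    # -- feature blocks -------------------------------------------------
    @property
    def matrix_shared(self) -> np.ndarray:
        self._require_aligned()
        return self.values[:, self.shared_block]

    @property
    def matrix_distinct(self) -> np.ndarray:
        self._require_aligned()
        return self.values[:, self.distinct_block]

    @property
    def matrix_full(self) -> np.ndarray:
        """Shared columns first, then distinct (the concatenated layout)."""
        self._require_aligned()
        order = np.concatenate([self.shared_block, self.distinct_block])
        return self.values[:, order]

    def _require_aligned(self) -> None:
        if not self.is_aligned:
            raise ValueError(
                "shared/distinct blocks unassigned; call align_shared_features first"
            )

    def subset_cells(self, idx: np.ndarray) -> "ExpressionBundle":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            cell_ids=[self.cell_ids[i] for i in idx],
            values=self.values[idx],
        )

    def subset_features(self, keep: np.ndarray) -> "ExpressionBundle":
        """Keep the given column indices; shared/distinct blocks are remapped."""
        keep = np.asarray(keep, dtype=int)
        pos = {int(j): k for k, j in enumerate(keep)}
        bundle = ExpressionBundle(
            cell_ids=list(self.cell_ids),
            feature_names=[self.feature_names[j] for j in keep],
            values=self.values[:, keep],
        )
        if self.is_aligned:
            bundle.shared_block = np.array(
                [pos[int(j)] for j in self.shared_block if int(j) in pos], dtype=int
            )
            bundle.distinct_block = np.array(
                [pos[int(j)] for j in self.distinct_block if int(j) in pos], dtype=int
            )
        return bundle


@dataclass
class BatchPlan:
    """Random equal-sized segmentation of the X dataset."""

    n_batch: int
    assignments: np.ndarray  # per-X-cell batch index
    seed: int

    def batch_indices(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == b)


def _duplicates(names: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in names:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def load_dataset(path, sep: str | None = None) -> ExpressionBundle:
    """Read a delimited matrix: header = feature names, first column = cell IDs.

    Any non-numeric or missing body cell is a hard error naming the offending
    row and column (1-based data coordinates).
    """
    # pandas silently renames duplicated header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n\r")
    use_sep = sep or ("\t" if "\t" in header else ",")
    raw_features = [c.strip() for c in header.split(use_sep)][1:]
    dup = _duplicates(raw_features)
    if dup:
        raise ValueError(f"duplicate feature names: {sorted(dup)}")
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=str)
    cell_ids = [str(c) for c in df.index]
    feature_names = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[r, c]
        raise ValueError(
            f"non-numeric value {raw!r} at row {r + 1}, column {c + 1} "
            f"(cell {cell_ids[r]!r}, feature {feature_names[c]!r})"
        )
    # numpy's string-to-float conversion is correctly rounded; pandas'
    # to_numeric fast path can be off by one ulp, breaking exact round-trips
    values = df.to_numpy(dtype="U32").astype(np.float64)
    return ExpressionBundle(cell_ids, feature_names, values)


def load_mtx(mtx_path, cells_path, features_path) -> ExpressionBundle:
    """Read a MatrixMarket matrix with cell/feature name sidecars (densified)."""
    from scipy.io import mmread
    from scipy.sparse import issparse

    m = mmread(mtx_path)
    values = np.asarray(m.todense() if issparse(m) else m, dtype=float)
    cells = [ln.strip() for ln in open(cells_path) if ln.strip()]
    feats = [ln.strip() for ln in open(features_path) if ln.strip()]
    return ExpressionBundle(cells, feats, values)


def write_dataset(bundle: ExpressionBundle, path) -> None:
    """Write back in the same layout :func:`load_dataset` reads."""
    pd.DataFrame(
        bundle.values, index=bundle.cell_ids, columns=bundle.feature_names
    ).to_csv(path, float_format="%.17g")


def normalize_features(
    bundle: ExpressionBundle, method: str = "zscore"
) -> ExpressionBundle:
    """Per-feature standardization within one dataset.

    zscore: mean 0, unit sample sd per column; columns with zero variance are
    centered only (a warning reports how many).  center: mean 0.  none:
    identity.
    """
    if method == "none":
        return bundle
    vals = bundle.values - bundle.values.mean(axis=0, keepdims=True)
    if method == "center":
        pass
    elif method == "zscore":
        sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
        flat = sd <= 1e-12
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance feature(s) centered only: "
                f"{[bundle.feature_names[j] for j in np.flatnonzero(flat)[:5]]}",
                stacklevel=2,
            )
        scale = np.where(flat, 1.0, sd)
        vals = vals / scale
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(bundle, values=vals)


def align_shared_features(
    x: ExpressionBundle,
    y: ExpressionBundle,
    mapping: list[tuple[str, str]] | None = None,
) -> tuple[ExpressionBundle, ExpressionBundle]:
    """Populate the shared/distinct partition of both bundles.

    Without ``mapping`` the shared set is the exact feature-name
    intersection, ordered as in X.  With ``mapping`` (pairs of
    (X-name, Y-name)) differently named panels can be joined; names are
    matched by exact string equality only.
    """
    x_pos = {nm: j for j, nm in enumerate(x.feature_names)}
    y_pos = {nm: j for j, nm in enumerate(y.feature_names)}
    if mapping is None:
        shared_names = [nm for nm in x.feature_names if nm in y_pos]
        pairs = [(nm, nm) for nm in shared_names]
    else:
        pairs = list(mapping)
        for xn, yn in pairs:
            if xn not in x_pos:
                raise ValueError(f"mapping refers to unknown X feature {xn!r}")
            if yn not in y_pos:
                raise ValueError(f"mapping refers to unknown Y feature {yn!r}")
    if not pairs:
        raise ValueError("no shared features between the two datasets")
    xs = np.array([x_pos[xn] for xn, _ in pairs], dtype=int)
    ys = np.array([y_pos[yn] for _, yn in pairs], dtype=int)
    xd = np.array([j for j in range(x.n_features) if j not in set(xs.tolist())], dtype=int)
    yd = np.array([j for j in range(y.n_features) if j not in set(ys.tolist())], dtype=int)
    return (
        replace(x, shared_block=xs, distinct_block=xd),
        replace(y, shared_block=ys, distinct_block=yd),
    )


def make_batches(
    x: ExpressionBundle, n_batch: int, seed: int, n_y: int | None = None
) -> BatchPlan:
    """Randomly segment X cells into ``n_batch`` near-equal batches.

    The rectangular assignment requires each batch to be no larger than the
    Y dataset; pass ``n_y`` to enforce feasibility up front.
    """
    if n_batch < 1:
        raise ValueError("n_batch must be >= 1")
    n = x.n_cells
    sizes = np.full(n_batch, n // n_batch, dtype=int)
    sizes[: n % n_batch] += 1
    if n_y is not None and sizes.max() > n_y:
        raise ValueError(
            f"largest batch ({sizes.max()}) exceeds n_y ({n_y}); raise n_batch"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    start = 0
    for b, s in enumerate(sizes):
        assignments[order[start : start + s]] = b
        start += s
    return BatchPlan(n_batch=n_batch, assignments=assignments, seed=seed)
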
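"""End-to-end run orchestration: config validation, full pipeline, artifacts.

``run_full`` chains preprocess -> match -> matchability test -> joint
regularized filtering -> embedding and writes plain-text artifacts
(matching.csv, qc_report.json, embedding CSVs, manifest.json).  A
matchability p-value above the threshold aborts the embedding with an
explicit "datasets not matchable" report unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .embedding import joint_embed
from .matching import MarioParams, match_pipeline
from .preprocess import align_shared_features, load_dataset, normalize_features
from .qc import apply_filter, matchability_test, regularized_kmeans_filter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_full", "NotMatchableError"]


class NotMatchableError(RuntimeError):
    """Raised when the matchability test fails and --force is not set."""


@dataclass
class RunConfig:
    """All stage parameters with their package defaults."""

    # matching
    n_components_ovlp: int = 10
    n_components_all: int = 20
    sparsity: int = 5000
    n_batch: int = 1
    lambda_grid: list[float] = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(11)])
    top_k: int = 10
    distance: str = "pearson"
    # matchability
    B: int = 20
    p_flip: float = 0.2
    matchability_alpha: float = 0.05
    matchability_fast: bool = False
    # filtering
    K: int = 10
    rho: float = 0.2
    n_iter: int = 20
    # embedding / transfer
    n_components_embed: int = 20
    knn_k: int = 5
    # misc
    normalization: str = "zscore"
    seed: int = 0

    def to_params(self) -> MarioParams:
        return MarioParams(
            n_components_ovlp=self.n_components_ovlp,
            n_components_all=self.n_components_all,
            sparsity=self.sparsity,
            n_batch=self.n_batch,
            lambda_grid=tuple(self.lambda_grid),
            top_k=self.top_k,
            distance=self.distance,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a JSON file path or a dict.

    Every violation is reported at once; unknown keys are rejected by
    name.  An empty file/dict yields all defaults.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text().strip()
        data = json.loads(text) if text else {}
    else:
        data = dict(source or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key {k!r}" for k in data if k not in known]
    cfg = RunConfig(**{k: v for k, v in data.items() if k in known})
    if cfg.n_components_ovlp < 1:
        errors.append("n_components_ovlp must be >= 1")
    if cfg.n_components_all < 1:
        errors.append("n_components_all must be >= 1")
    if cfg.sparsity < 1:
        errors.append("sparsity must be >= 1")
    if cfg.n_batch < 1:
        errors.append("n_batch must be >= 1")
    if not cfg.lambda_grid or 0.0 not in cfg.lambda_grid or 1.0 not in cfg.lambda_grid:
        errors.append("lambda_grid must contain 0 and 1")
    if any(not (0 <= g <= 1) for g in cfg.lambda_grid):
        errors.append("lambda_grid values must lie in [0, 1]")
    if cfg.top_k < 1:
        errors.append("top_k must be >= 1")
    if cfg.B < 1:
        errors.append("B must be >= 1")
    if not (0 < cfg.p_flip <= 0.5):
        errors.append("p_flip must lie in (0, 0.5]")
    if cfg.K < 2:
        errors.append("K must be >= 2")
    elif not (0 < cfg.rho < 1 - 1 / cfg.K):
        errors.append(f"rho must lie in (0, 1 - 1/K) = (0, {1 - 1 / cfg.K:.4f})")
    if cfg.n_iter < 1:
        errors.append("n_iter must be >= 1")
    if cfg.distance not in {"pearson", "laplacian"}:
        errors.append("distance must be 'pearson' or 'laplacian'")
    if cfg.normalization not in {"zscore", "center", "none"}:
        errors.append("normalization must be one of zscore/center/none")
    if cfg.knn_k < 1:
        errors.append("knn_k must be >= 1")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(
    config: RunConfig,
    x_path,
    y_path,
    out_dir,
    mapping: list[tuple[str, str]] | None = None,
    force: bool = False,
) -> dict:
    """Execute the whole workflow on two delimited matrices.

    Returns a summary dict and writes matching.csv, qc_report.json,
    embedding_x.csv / embedding_y.csv and manifest.json to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    x = normalize_features(load_dataset(x_path), config.normalization)
    y = normalize_features(load_dataset(y_path), config.normalization)
    if x.n_cells > y.n_cells:
        raise ValueError(
            f"X must be the smaller dataset (n_x={x.n_cells} > n_y={y.n_cells}); swap inputs"
        )
    x, y = align_shared_features(x, y, mapping=mapping)
    logger.info(
        "loaded: n_x=%d n_y=%d p_share=%d (%.1fs)",
        x.n_cells, y.n_cells, len(x.shared_block), time.time() - t0,
    )

    params = config.to_params()
    result = match_pipeline(x, y, params, return_distance=True)
    matching = result.matching
    logger.info("matched %d cells; per-batch info: %s", matching.n_matched, result.batch_info)

    report = matchability_test(
        x, y,
        B=config.B, p_flip=config.p_flip, top_k=config.top_k,
        seed=config.seed + 1, params=params, fast=config.matchability_fast,
    )
    logger.info("matchability: observed=%.4f p=%.4f", report.observed, report.p_value)

    matchable = report.p_value <= config.matchability_alpha
    filter_summary = None
    if matchable or force:
        xa = x.matrix_full
        ya = y.matrix_full[matching.pairs]
        filt = regularized_kmeans_filter(
            xa, ya, K=config.K, rho=config.rho, n_iter=config.n_iter, seed=config.seed + 2
        )
        filtered = apply_filter(matching, filt)
        kept = np.flatnonzero(filtered.matched_mask)
        emb = joint_embed(
            xa[kept], y.matrix_full[filtered.pairs[kept]], r=config.n_components_embed
        )
        pd.DataFrame(
            emb.scores[0], index=[x.cell_ids[i] for i in kept]
        ).to_csv(out_dir / "embedding_x.csv")
        pd.DataFrame(
            emb.scores[1], index=[y.cell_ids[j] for j in filtered.pairs[kept]]
        ).to_csv(out_dir / "embedding_y.csv")
        removed_per_cluster = {
            int(k): int(np.sum((filt.z_x == k) & ~filt.keep_mask)) for k in range(config.K)
        }
        filter_summary = {
            "n_pairs_in": int(matching.n_matched),
            "n_kept": int(filtered.n_matched),
            "n_removed": int(matching.n_matched - filtered.n_matched),
            "removed_per_cluster": removed_per_cluster,
        }
        final = filtered
    else:
        final = matching

    pd.DataFrame(
        {
            "x_cell_id": x.cell_ids,
            "y_cell_id": [
                y.cell_ids[j] if j >= 0 else "" for j in final.pairs
            ],
            "lambda": final.lambda_used if final.lambda_used is not None else "",
            "matched_flag": final.matched_mask.astype(int),
        }
    ).to_csv(out_dir / "matching.csv", index=False)

    qc_report = {
        "matchability": {
            "B": report.B,
            "p_flip": report.p_flip,
            "observed": report.observed,
            "background": report.background.tolist(),
            "p_value": report.p_value,
            "matchable": bool(matchable),
            "alpha": config.matchability_alpha,
        },
        "filter": filter_summary,
    }
    (out_dir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "inputs": {"x": _sha256(x_path), "y": _sha256(y_path)},
        "batch_info": result.batch_info,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if not matchable and not force:
        raise NotMatchableError(
            f"datasets not matchable (p={report.p_value:.4f} > "
            f"alpha={config.matchability_alpha}); rerun with force to override"
        )
    return {
        "matching": final,
        "matchability": report,
        "filter": filter_summary,
        "out_dir": out_dir,
    }
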
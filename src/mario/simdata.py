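"""Synthetic paired two-modality datasets with cell-level ground truth.

The generator emulates the setting the matcher is built for: latent cell
populations observed through two modality-specific feature panels that
overlap only partially.  Each cell carries a latent state (its population
centroid plus within-population Gaussian spread); shared features are a
common linear readout of that state, distinct features are
modality-specific readouts, and each modality adds its own measurement
noise and a systematic per-feature shift.  Every X cell has a noisy
"twin" in Y that observed the same latent state, so a perfect matching
exists and accuracy is interpretable; Y additionally contains extra cells
without twins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionBundle, write_dataset

__all__ = [
    "SynthConfig",
    "generate_pair",
    "population_labels",
    "drop_types_from_truth",
    "write_fixture",
]


@dataclass
class SynthConfig:
    """Generator settings.

    separation scales the spread of population centroids in latent space
    relative to the unit within-population spread; noise_sd is the
    per-feature measurement noise; modality_shift a systematic per-feature
    offset applied to the second modality (it mimics batch effects and is
    removed by per-dataset z-scoring).
    """

    n_populations: int = 20
    n_cells_x: int = 1000
    n_cells_y: int = 2000
    p_shared: int = 20
    p_distinct_x: int = 20
    p_distinct_y: int = 20
    latent_dim: int = 10
    separation: float = 2.0
    noise_sd: float = 0.5
    modality_shift: float = 0.3
    proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_x > self.n_cells_y:
            raise ValueError("n_cells_x must be <= n_cells_y (every X cell needs a twin)")
        if min(self.n_populations, self.p_shared, self.latent_dim) < 1:
            raise ValueError("population, feature and latent counts must be positive")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.noise_sd < 0 or self.modality_shift < 0:
            raise ValueError("noise_sd and modality_shift must be >= 0")
        if self.proportions is not None:
            pr = np.asarray(self.proportions, dtype=float)
            if len(pr) != self.n_populations or not np.isclose(pr.sum(), 1.0):
                raise ValueError("proportions must sum to 1, one per population")


def generate_pair(
    config: SynthConfig,
) -> tuple[ExpressionBundle, ExpressionBundle, pd.DataFrame]:
    """Draw a paired dataset; fully deterministic given ``config.seed``.

    Returns aligned bundles (shared/distinct blocks populated) and a truth
    table with columns x_id, y_id (twin), population.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_pop, d = config.n_populations, config.latent_dim
    centroids = config.separation * rng.standard_normal((n_pop, d))

    pr = (
        np.asarray(config.proportions, dtype=float)
        if config.proportions is not None
        else np.full(n_pop, 1.0 / n_pop)
    )
    pop_x = rng.choice(n_pop, size=config.n_cells_x, p=pr)
    latent_x = centroids[pop_x] + rng.standard_normal((config.n_cells_x, d))

    n_extra = config.n_cells_y - config.n_cells_x
    pop_extra = rng.choice(n_pop, size=n_extra, p=pr)
    latent_extra = centroids[pop_extra] + rng.standard_normal((n_extra, d))
    # Y observes the twins' latent states plus the extras, in shuffled order
    latent_y = np.vstack([latent_x, latent_extra])
    pop_y = np.concatenate([pop_x, pop_extra])
    perm = rng.permutation(config.n_cells_y)
    latent_y = latent_y[perm]
    pop_y = pop_y[perm]
    twin_of_x = np.empty(config.n_cells_x, dtype=int)
    twin_of_x[np.arange(config.n_cells_x)] = np.argsort(perm)[: config.n_cells_x]

    scale = 1.0 / np.sqrt(d)
    a_share = rng.standard_normal((d, config.p_shared)) * scale
    a_x = rng.standard_normal((d, config.p_distinct_x)) * scale
    a_y = rng.standard_normal((d, config.p_distinct_y)) * scale
    shift = config.modality_shift * rng.standard_normal(config.p_shared + config.p_distinct_y)

    def observe(latent, loadings, noise_shape):
        return latent @ loadings + config.noise_sd * rng.standard_normal(noise_shape)

    x_vals = np.hstack(
        [
            observe(latent_x, a_share, (config.n_cells_x, config.p_shared)),
            observe(latent_x, a_x, (config.n_cells_x, config.p_distinct_x)),
        ]
    )
    y_vals = (
        np.hstack(
            [
                observe(latent_y, a_share, (config.n_cells_y, config.p_shared)),
                observe(latent_y, a_y, (config.n_cells_y, config.p_distinct_y)),
            ]
        )
        + shift
    )

    shared_names = [f"S{j:03d}" for j in range(config.p_shared)]
    x_names = shared_names + [f"XD{j:03d}" for j in range(config.p_distinct_x)]
    y_names = shared_names + [f"YD{j:03d}" for j in range(config.p_distinct_y)]
    x_ids = [f"x{i:05d}" for i in range(config.n_cells_x)]
    y_ids = [f"y{i:05d}" for i in range(config.n_cells_y)]

    x = ExpressionBundle(
        cell_ids=x_ids,
        feature_names=x_names,
        values=x_vals,
        shared_block=np.arange(config.p_shared),
        distinct_block=np.arange(config.p_shared, config.p_shared + config.p_distinct_x),
    )
    y = ExpressionBundle(
        cell_ids=y_ids,
        feature_names=y_names,
        values=y_vals,
        shared_block=np.arange(config.p_shared),
        distinct_block=np.arange(config.p_shared, config.p_shared + config.p_distinct_y),
    )
    truth = pd.DataFrame(
        {
            "x_id": x_ids,
            "y_id": [y_ids[t] for t in twin_of_x],
            "population": [f"pop{p:02d}" for p in pop_x],
        }
    )
    truth.attrs["pop_y"] = np.array([f"pop{p:02d}" for p in pop_y])
    return x, y, truth


def population_labels(truth: pd.DataFrame, side: str = "x") -> np.ndarray:
    """Ground-truth population label per cell (X order, or Y order)."""
    if side == "x":
        return truth["population"].to_numpy()
    if side == "y":
        return truth.attrs["pop_y"]
    raise ValueError("side must be 'x' or 'y'")


def drop_types_from_truth(truth: pd.DataFrame, types: list[str]) -> pd.DataFrame:
    """Mark twins of removed Y populations as unmatched (y_id = NA) for
    scoring the deleted-cell-type scenario."""
    out = truth.copy()
    out.attrs = dict(truth.attrs)
    mask = out["population"].isin(types)
    out.loc[mask, "y_id"] = pd.NA
    return out


def write_fixture(
    x: ExpressionBundle, y: ExpressionBundle, truth: pd.DataFrame, out_dir
) -> dict[str, Path]:
    """Write the CSV trio (X, Y, truth) consumed by the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "x": out_dir / "X.csv",
        "y": out_dir / "Y.csv",
        "truth": out_dir / "truth.csv",
    }
    write_dataset(x, paths["x"])
    write_dataset(y, paths["y"])
    truth[["x_id", "y_id", "population"]].to_csv(paths["truth"], index=False)
    return paths
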
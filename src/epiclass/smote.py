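"""Synthetic minority oversampling (SMOTE) for the labeled attribute matrix.

Decision trees trained on heavily imbalanced epitope/nonepitope k-mer sets
collapse onto the majority class; oversampling the minority class with
interpolated synthetic instances counteracts that.  For each minority row x,
``oversample_percent / 100`` synthetic rows are drawn as

    x_new = x + u * (x_nn - x),   u ~ Uniform[0, 1],

with x_nn sampled among x's k nearest minority neighbors (Euclidean
distance).  Synthetic rows therefore live on segments between minority
points and never leave the minority class's convex hull.

Applied inside each training fold only — never to held-out data — so
evaluation metrics are not inflated by leakage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclasses.dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    oversample_percent: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.oversample_percent < 100 or self.oversample_percent % 100:
            raise ValueError("oversample_percent must be a multiple of 100, >= 100")


def smote_minority(
    X_min: np.ndarray, cfg: SmoteConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Synthetic rows for a minority-class matrix; (n * percent/100, p)."""
    X_min = np.asarray(X_min, dtype=float)
    n = X_min.shape[0]
    if n < cfg.k_neighbors + 1:
        raise ValueError(
            f"minority class has {n} rows; SMOTE with k={cfg.k_neighbors} needs "
            f"at least {cfg.k_neighbors + 1}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    per_row = cfg.oversample_percent // 100
    parents = np.repeat(np.arange(n), per_row)
    return _interpolate(X_min, parents, cfg.k_neighbors, rng)


def _interpolate(
    X_min: np.ndarray, parents: np.ndarray, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    # first neighbor is the point itself
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    chosen = neighbors[parents, rng.integers(0, k_neighbors, size=parents.size)]
    u = rng.uniform(0.0, 1.0, size=parents.size)[:, None]
    return X_min[parents] + u * (X_min[chosen] - X_min[parents])


def rebalance(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SmoteConfig | None = None,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a binary matrix toward ``target_ratio``.

    y is boolean (True = positive).  The oversample percent is derived as the
    largest multiple of 100 that does not push the minority class past
    ``target_ratio`` times the majority count; original rows are kept
    unchanged and synthetic rows are appended at the end.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to rebalance")
    minority_is_pos = n_pos <= n_neg
    n_min, n_maj = (n_pos, n_neg) if minority_is_pos else (n_neg, n_pos)
    deficit = int(round(target_ratio * n_maj)) - n_min
    if deficit <= 0:
        return X, y
    base = cfg or SmoteConfig()
    k = min(base.k_neighbors, n_min - 1)
    if k < 1:
        raise ValueError("minority class needs at least 2 rows for SMOTE")
    rng = np.random.default_rng(base.seed if seed is None else seed)
    parents = np.concatenate(
        [
            np.repeat(np.arange(n_min), deficit // n_min),
            rng.choice(n_min, size=deficit % n_min, replace=False),
        ]
    ).astype(int)
    X_min = X[y] if minority_is_pos else X[~y]
    synth = _interpolate(X_min, parents, k, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(len(synth), minority_is_pos)])
    return X_out, y_out
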
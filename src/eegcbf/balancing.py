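"""SMOTE: synthetic minority oversampling inside training folds.

New minority samples are convex combinations ``x + u * (neighbor - x)``
with ``u ~ Uniform(0, 1)`` and the neighbor drawn from the k nearest
minority-class points. The minority class is grown until it matches the
majority count; majority samples and the original minority rows are
preserved verbatim. Applied to training data only — never to held-out
animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_augment"]


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be at least 1")


def smote_augment(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equalize class counts by synthesizing minority samples.

    Returns ``(X, y, synthetic)`` where ``synthetic`` flags the appended
    rows; original rows come first, unchanged and in their input order.
    """
    cfg = config or SmoteConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"SMOTE needs exactly two classes, got {classes.size}")
    minority = classes[np.argmin(counts)]
    n_minority, n_majority = counts.min(), counts.max()
    n_new = int(n_majority - n_minority)
    if n_minority <= cfg.k_neighbors:
        raise ValueError(
            f"minority class has {n_minority} samples but k={cfg.k_neighbors} "
            "neighbors were requested; use a smaller k"
        )
    if n_new == 0:
        return X.copy(), y.copy(), np.zeros(len(y), dtype=bool)

    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xm)
    # drop the first neighbor (the point itself)
    neighbor_idx = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = Xm[base]
    neighbors = Xm[neighbor_idx[base, pick]]
    synthetic_rows = anchors + u[:, None] * (neighbors - anchors)

    X_out = np.vstack([X, synthetic_rows])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    flag = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_new, dtype=bool)])
    return X_out, y_out, flag
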
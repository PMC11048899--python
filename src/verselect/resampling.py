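"""Class-imbalance oversampling for training partitions.

The progression class is rare (roughly 1 in 10), so training folds are
rebalanced before model fitting.  Default is random duplication of minority
rows up to the configured minority:majority ratio; a minimal SMOTE
(synthetic interpolation between minority nearest neighbours) is available
as an alternative.  Oversampling must only ever touch training partitions —
the cross-validation harness enforces that.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def _check_binary(y: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(
            f"oversampling requires both classes present; got classes {classes.tolist()}"
        )
    minority = int(classes[np.argmin(counts)])
    majority = int(classes[np.argmax(counts)])
    if counts[0] == counts[1]:
        minority, majority = int(classes[0]), int(classes[1])
    return minority, majority


def random_oversample(
    X: np.ndarray, y: np.ndarray, ratio: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority rows (with replacement) until
    ``n_minority >= ratio * n_majority``.  Already-balanced input is
    returned unchanged; the same seed yields the same resampled index
    multiset."""
    minority, majority = _check_binary(y)
    idx_min = np.where(y == minority)[0]
    idx_maj = np.where(y == majority)[0]
    target = int(round(ratio * len(idx_maj)))
    if len(idx_min) >= target:
        return X, y
    rng = np.random.default_rng(seed)
    extra = rng.choice(idx_min, size=target - len(idx_min), replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return X[keep], y[keep]


def smote_oversample(
    X: np.ndarray, y: np.ndarray, ratio: float = 1.0, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE-style oversampling: synthesise minority rows by linear
    interpolation between a minority row and one of its k nearest minority
    neighbours."""
    minority, majority = _check_binary(y)
    idx_min = np.where(y == minority)[0]
    idx_maj = np.where(y == majority)[0]
    target = int(round(ratio * len(idx_maj)))
    n_new = target - len(idx_min)
    if n_new <= 0:
        return X, y
    if len(idx_min) < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    k = min(k_neighbors, len(idx_min) - 1)
    rng = np.random.default_rng(seed)
    X_min = X[idx_min]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, len(idx_min), size=n_new)
    partner = neigh[base, rng.integers(0, k, size=n_new)]
    gamma = rng.uniform(size=(n_new, 1))
    X_new = X_min[base] + gamma * (X_min[partner] - X_min[base])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


_OVERSAMPLERS = {"random": random_oversample, "smote": smote_oversample}


def oversample(
    X: np.ndarray, y: np.ndarray, method: str = "random", ratio: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the configured oversampler; ``method='none'`` is a no-op."""
    if method == "none":
        return X, y
    try:
        fn = _OVERSAMPLERS[method]
    except KeyError:
        raise ValueError(f"unknown oversampling method {method!r}") from None
    return fn(X, y, ratio=ratio, seed=seed)
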
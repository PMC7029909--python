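"""ReliefF filter feature ranking.

ReliefF scores each feature by how well it separates nearby instances of
different classes.  For each evaluated instance the k nearest *hits*
(same class) and k nearest *misses* (other class) are found in
min-max-normalized feature space, and the feature weight is updated with
the average normalized difference to misses minus the average difference
to hits:

    w_f  +=  Σ_miss diff(f, x, miss) / (m·k)  −  Σ_hit diff(f, x, hit) / (m·k)

where diff(f, a, b) = |a_f − b_f| / (max_f − min_f) and m is the number
of evaluated instances.  A feature whose values contrast across the class
boundary but agree within a class accumulates positive weight; weights
lie in [−1, 1] and a constant feature scores exactly 0.

This implementation is the exhaustive deterministic variant: every
instance is evaluated (no subsampling), distances are L1 in the
normalized space, and neighbour ties break toward the lower instance
index, so a fixed dataset yields a unique ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd


@dataclass
class RankedFeatures:
    """A ReliefF ranking: ``feature_names[0]`` is the most relevant."""

    feature_names: list[str]
    weights: np.ndarray  # aligned with feature_names, non-increasing
    activity: str = ""
    k_neighbors: int = 10
    n_sample_iterations: int | None = None  # None = exhaustive
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights and feature_names must align")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing in rank order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activity": self.activity,
                "rank": np.arange(1, len(self.feature_names) + 1),
                "feature": self.feature_names,
                "weight": self.weights,
            }
        )


def relieff_weights(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 10
) -> np.ndarray:
    """Raw ReliefF weights for a binary-labelled feature matrix.

    Exhaustive over instances; k is truncated (with a warning) when a
    class has too few members to supply k hits or misses.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are constant; ReliefF needs both classes")
    if counts.min() < 2:
        raise ValueError(
            f"each class needs >= 2 instances; got counts {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    # hits exclude the instance itself -> at most min_count-1 same-class
    # neighbours are available
    k_max = int(min(counts.min() - 1, counts.max()))
    k = k_neighbors
    if k > k_max:
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds available neighbours; truncating to {k_max}",
            stacklevel=2,
        )
        k = k_max

    span = X.max(axis=0) - X.min(axis=0)
    nonconstant = span > 0
    Xn = np.zeros_like(X)
    Xn[:, nonconstant] = (X[:, nonconstant] - X.min(axis=0)[nonconstant]) / span[nonconstant]

    weights = np.zeros(p)
    # L1 distance matrix in normalized space, chunked to bound memory
    chunk = max(1, int(2e7 // (n * p)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = np.abs(Xn[start:stop, None, :] - Xn[None, :, :])  # (b, n, p)
        dists = block.sum(axis=2)
        for local, i in enumerate(range(start, stop)):
            d = dists[local]
            same = y == y[i]
            # ties in distance break toward the lower instance index
            # (argsort is stable over the index-ordered candidates)
            hit_idx = np.flatnonzero(same)
            hit_idx = hit_idx[hit_idx != i]
            miss_idx = np.flatnonzero(~same)
            hits = hit_idx[np.argsort(d[hit_idx], kind="stable")[:k]]
            misses = miss_idx[np.argsort(d[miss_idx], kind="stable")[:k]]
            weights += block[local, misses, :].sum(axis=0) / (n * k)
            weights -= block[local, hits, :].sum(axis=0) / (n * k)
    return weights


def relieff_rank(
    feature_table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int | None = None,
    activity: str = "",
) -> RankedFeatures:
    """Rank a feature table's columns by ReliefF relevance.

    ``feature_table`` must contain only feature columns (no metadata) and
    no missing values.  ``n_iterations=None`` evaluates every instance —
    the deterministic default; an integer subsamples that many instances
    without replacement using ``seed``.
    """
    if feature_table.isna().any().any():
        raise ValueError("feature table contains missing values")
    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(y) != len(X):
        raise ValueError("labels must align with the feature table rows")
    if n_iterations is not None and n_iterations < len(X):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(X), size=n_iterations, replace=False))
        # subsampled variant still searches neighbours in the full set:
        # evaluate weights on the subsample against all instances
        X_eval, y_eval = X[idx], y[idx]
        if len(np.unique(y_eval)) < 2:
            raise ValueError("subsample lost one class; increase n_iterations")
        weights = relieff_weights(X_eval, y_eval, k_neighbors)
    else:
        weights = relieff_weights(X, y, k_neighbors)
    order = np.lexsort((np.arange(len(weights)), -weights))
    names = [feature_table.columns[i] for i in order]
    return RankedFeatures(
        feature_names=names,
        weights=weights[order],
        activity=activity,
        k_neighbors=k_neighbors,
        n_sample_iterations=n_iterations,
        seed=seed,
    )


def top_k(ranking: RankedFeatures, k: int) -> list[str]:
    """First k feature names in rank order."""
    if not (1 <= k <= len(ranking.feature_names)):
        raise ValueError(
            f"k must be in [1, {len(ranking.feature_names)}], got {k}"
        )
    return ranking.feature_names[:k]
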
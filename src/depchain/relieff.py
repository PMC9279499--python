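"""RReliefF feature importance for a continuous target.

RReliefF estimates, for each feature, how much its value differences track
target differences among near neighbors: a feature is rewarded when neighbors
with different responses also differ in the feature, and penalized when
neighbors with the same response differ in it.  For each sampled instance and
its k nearest neighbors (Euclidean distance in min-max-normalized feature
space) the accumulators

    N_dC        += diff(y)            * w
    N_dA[f]     += diff(f)            * w
    N_dC&dA[f]  += diff(y) * diff(f)  * w

are updated with uniform neighbor influence w = 1/k, where diff() is the
absolute difference divided by the attribute's observed range.  The weights

    W[f] = N_dC&dA[f] / N_dC  -  (N_dA[f] - N_dC&dA[f]) / (m - N_dC)

(m = number of sampled instances) are guaranteed to lie in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ImportanceWeights:
    weights: np.ndarray
    feature_names: list[str]

    @property
    def ranking(self) -> np.ndarray:
        """Permutation of feature indices, descending weight, ties by index."""
        return np.lexsort((np.arange(len(self.weights)), -self.weights))


def _minmax(a: np.ndarray) -> np.ndarray:
    lo = a.min(axis=0)
    rng = a.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    return (a - lo) / safe


def rrelieff(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ImportanceWeights:
    """RReliefF weights for each column of X against the continuous target y.

    By default every instance is used once (n_iterations = n); passing a
    smaller n_iterations samples instances without replacement using `seed`.
    Constant features receive weight 0.  Raises if the target has zero
    variance or if k is not in [1, n-1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_feat = X.shape
    if y.shape != (n,):
        raise ValueError("X and y sizes disagree")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if y.max() == y.min():
        raise ValueError("target has zero variance; RReliefF is undefined")

    Xn = _minmax(X)
    yn = (y - y.min()) / (y.max() - y.min())

    if n_iterations is None or n_iterations >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = np.sort(
            rng.choice(n, size=int(n_iterations), replace=False)
        )
    m = len(sample_idx)

    dist = cdist(Xn[sample_idx], Xn)
    dist[np.arange(m), sample_idx] = np.inf  # exclude self
    # k nearest neighbors, distance ties broken by index for determinism
    order = np.lexsort(
        (np.broadcast_to(np.arange(n), dist.shape), dist), axis=1
    )
    nbr = order[:, :k]

    w = 1.0 / k
    n_dc = 0.0
    n_da = np.zeros(n_feat)
    n_dcda = np.zeros(n_feat)
    for row, i in enumerate(sample_idx):
        js = nbr[row]
        d_y = np.abs(yn[i] - yn[js])  # (k,)
        d_a = np.abs(Xn[i] - Xn[js])  # (k, n_feat)
        n_dc += w * d_y.sum()
        n_da += w * d_a.sum(axis=0)
        n_dcda += w * (d_y[:, None] * d_a).sum(axis=0)

    weights = np.zeros(n_feat)
    if n_dc > 0:
        weights = n_dcda / n_dc
    if m - n_dc > 0:
        weights = weights - (n_da - n_dcda) / (m - n_dc)
    names = feature_names or [f"f{i}" for i in range(n_feat)]
    return ImportanceWeights(weights=weights, feature_names=list(names))


def rank_features(importance: ImportanceWeights) -> list[str]:
    """Feature labels in descending-importance order (ties by input order)."""
    return [importance.feature_names[i] for i in importance.ranking]
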
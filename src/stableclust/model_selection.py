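"""Choosing the number of clusters k by repeated t-SNE + average silhouette.

t-SNE is a stochastic map, so a single embedding can mislead the silhouette
criterion. The pipeline therefore embeds the distance matrix n times
(default 50) with distinct seeds, picks for each embedding the k in a
configured range (default 2..20) that maximises the mean silhouette of a
k-means clustering, and takes the rounded average of those n choices as the
final k.

The silhouette of point i is s(i) = (b(i) - a(i)) / max(a(i), b(i)), where
a(i) is the mean distance from i to the other members of its own cluster and
b(i) is the smallest mean distance from i to the points of any other
cluster. Points in singleton clusters are assigned s(i) = 0 (a(i) is
undefined there).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .containers import DistanceMatrix, Embedding
from .embedding import embed, feasible_perplexity

__all__ = [
    "KSelectionResult",
    "silhouette_values",
    "best_k",
    "select_k",
    "round_half_away",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (3.5 -> 4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class KSelectionResult:
    """Audit trail of the repeated-embedding k selection."""

    k_final: int
    per_repeat_k: list[int]
    per_repeat_silhouette_curves: dict[int, dict[int, float]]
    seeds: list[int]

    def __post_init__(self) -> None:
        if self.k_final != round_half_away(float(np.mean(self.per_repeat_k))):
            raise ValueError("k_final must be the rounded mean of per-repeat k")


def silhouette_values(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s(i) with Euclidean distances on ``points``.

    Requires at least two non-empty clusters; values lie in [-1, 1].
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters (b(i) undefined)")
    n = len(labels)
    d = cdist(points, points)
    sizes = {c: int(np.sum(labels == c)) for c in clusters}
    # mean distance from each point to each cluster
    mean_to = np.empty((n, len(clusters)))
    for j, c in enumerate(clusters):
        mean_to[:, j] = d[:, labels == c].mean(axis=1)
    s = np.zeros(n)
    for i in range(n):
        ci = np.flatnonzero(clusters == labels[i])[0]
        size = sizes[clusters[ci]]
        if size == 1:
            continue  # singleton: a(i) undefined, s(i) := 0
        # own-cluster mean excludes the point itself
        a = mean_to[i, ci] * size / (size - 1)
        b = np.min(np.delete(mean_to[i], ci))
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def best_k(
    points: np.ndarray,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """k maximising mean silhouette of k-means on the embedded coordinates.

    Returns the arg-max k (ties broken toward the smaller k) and the full
    k -> mean-silhouette curve. The range is truncated (with a warning) when
    it exceeds n_cells - 1.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to choose k")
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2:
        raise ValueError("k range must start at 2 or above")
    if k_hi > n - 1:
        logger.warning("k range upper bound %d truncated to n_cells - 1 = %d", k_hi, n - 1)
        k_hi = n - 1
    curve: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(points)
        if len(np.unique(labels)) < 2:
            curve[k] = -1.0
            continue
        curve[k] = float(np.mean(silhouette_values(points, labels)))
    ks = sorted(curve)
    best = max(ks, key=lambda k: (curve[k], -k))
    return best, curve


def select_k(
    d: DistanceMatrix,
    n_repeats: int = 50,
    k_range: tuple[int, int] = (2, 20),
    base_seed: int = 0,
    perplexity: float | None = None,
    l: int = 2,
) -> KSelectionResult:
    """Repeat t-SNE ``n_repeats`` times and average the per-repeat best k.

    Repeat r uses seed ``base_seed + r`` so the run is reproducible yet the
    embeddings are distinct. The final k is the mean of the per-repeat
    choices rounded half away from zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    perp = feasible_perplexity(d.n_cells) if perplexity is None else perplexity
    seeds = [int(base_seed) + r for r in range(n_repeats)]
    per_repeat_k: list[int] = []
    curves: dict[int, dict[int, float]] = {}
    for r, seed in enumerate(seeds):
        emb = embed(d, l=l, perplexity=perp, seed=seed)
        k_r, curve = best_k(emb.coords, k_range=k_range, seed=seed)
        per_repeat_k.append(k_r)
        curves[r] = curve
        logger.info("k-selection repeat %d/%d: k=%d", r + 1, n_repeats, k_r)
    k_final = round_half_away(float(np.mean(per_repeat_k)))
    return KSelectionResult(
        k_final=k_final,
        per_repeat_k=per_repeat_k,
        per_repeat_silhouette_curves=curves,
        seeds=seeds,
    )
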
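"""Selecting the most stable k-means clustering under noise resampling.

The working hypothesis: a genuine grouping of cells survives small
perturbations of the data. Given the embedded coordinates D' and the chosen
k, the procedure generates n candidate k-means clusterings, and scores each
by resampling: m times, a fixed fraction (default 5%) of cells is replaced
in place by draws from a noise distribution (uniform over the data's
bounding box expanded by 10% per side), the perturbed data is re-clustered
with the same k, and each original cluster is matched to its most similar
resampled cluster by the Jaccard coefficient J(A, B) = |A ∩ B| / |A ∪ B|,
computed after excluding the noise cells. A cluster counts as preserved in a
resample when its best Jaccard match is >= 0.75. A cluster's stability is
the fraction of resamples in which it is preserved; a clustering's overall
stability is the mean over its k clusters; the candidate with the maximum
overall stability is the final solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .containers import Clustering, Embedding

__all__ = [
    "StabilityReport",
    "StableClusteringResult",
    "jaccard",
    "perturb",
    "cluster_preserved",
    "stability_of",
    "most_stable_clustering",
]

logger = logging.getLogger(__name__)

DEFAULT_NOISE_FRACTION = 0.05
DEFAULT_JACCARD_THRESHOLD = 0.75
BBOX_EXPANSION = 0.10  # per side, as a fraction of each axis range
_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class StabilityReport:
    """Per-cluster and overall stability of one candidate clustering."""

    per_cluster_stability: tuple[float, ...]
    overall_stability: float
    m: int
    jaccard_threshold: float
    noise_fraction: float

    def __post_init__(self) -> None:
        per = tuple(float(x) for x in self.per_cluster_stability)
        object.__setattr__(self, "per_cluster_stability", per)
        if not all(0.0 <= x <= 1.0 for x in per):
            raise ValueError("per-cluster stabilities must lie in [0, 1]")
        if abs(self.overall_stability - float(np.mean(per))) > 1e-12:
            raise ValueError("overall stability must be the mean of per-cluster values")


@dataclass(frozen=True)
class StableClusteringResult:
    """The chosen clustering plus the full candidate audit trail."""

    chosen: Clustering
    chosen_report: StabilityReport
    chosen_index: int
    all_reports: tuple[StabilityReport, ...]
    embedding_used: Embedding | None = None
    candidates: tuple[Clustering, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        best = max(r.overall_stability for r in self.all_reports)
        if self.chosen_report.overall_stability < best - 1e-12:
            raise ValueError("chosen clustering must have maximal overall stability")


def jaccard(a: Iterable[int], b: Iterable[int]) -> float:
    """Jaccard coefficient |A ∩ B| / |A ∪ B| between two sets of indices."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def _noise_box(points: np.ndarray, expansion: float = BBOX_EXPANSION):
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = (hi - lo) * expansion
    return lo - pad, hi + pad


def perturb(
    points: np.ndarray,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    seed: int = 0,
    expansion: float = BBOX_EXPANSION,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a random subset of cells with noise points, in place.

    Exactly round(noise_fraction * n_cells) distinct cells (half-away-from-
    zero rounding) are chosen uniformly without replacement and their
    coordinates overwritten with uniform draws from the bounding box of
    ``points`` expanded by ``expansion`` per side. Returns the perturbed
    copy and a boolean mask marking the replaced cells.
    """
    if not 0.0 < noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in (0, 1)")
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    n_noise = int(np.floor(noise_fraction * n + 0.5))
    if n_noise == 0:
        raise ValueError(
            f"noise_fraction {noise_fraction} selects no cells out of {n}; "
            "use a larger dataset or fraction"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_noise, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    lo, hi = _noise_box(points, expansion)
    out = points.copy()
    out[mask] = rng.uniform(lo, hi, size=(n_noise, points.shape[1]))
    return out, mask


def cluster_preserved(
    c: Iterable[int],
    resampled: Clustering,
    noise_mask: np.ndarray,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> tuple[bool, float]:
    """Best Jaccard match of an original cluster in a resampled clustering.

    Noise cells are excluded from both sides of every comparison. Returns
    (preserved, best_jaccard) where preserved means best_jaccard >=
    ``threshold``. A cluster entirely replaced by noise is reported as not
    preserved with best_jaccard 0.
    """
    noise = set(np.flatnonzero(noise_mask).tolist())
    c_clean = set(c) - noise
    if not c_clean:
        logger.warning("cluster entirely replaced by noise; counted as not preserved")
        return False, 0.0
    best = 0.0
    for c_prime in range(resampled.k):
        members = set(np.flatnonzero(resampled.labels == c_prime).tolist()) - noise
        if not members:
            continue
        best = max(best, jaccard(c_clean, members))
    return best >= threshold, best


def _fit_kmeans(points: np.ndarray, k: int, seed: int, init: str, n_init: int) -> Clustering:
    km = KMeans(n_clusters=k, init=init, n_init=n_init, random_state=seed)
    labels = km.fit_predict(points)
    return Clustering(labels=labels, k=k, centroids=km.cluster_centers_)


def stability_of(
    c: Clustering,
    points: np.ndarray,
    m: int,
    k: int,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
    seed: int = 0,
    resample_init: str = "k-means++",
    resample_n_init: int = 10,
) -> StabilityReport:
    """Stability of every cluster of ``c`` across ``m`` noise resamplings."""
    if m < 1:
        raise ValueError("m must be >= 1")
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    preserved_counts = np.zeros(c.k, dtype=int)
    originals = [c.members(i) for i in range(c.k)]
    for _ in range(m):
        perturb_seed = int(rng.integers(_MAX_SEED))
        kmeans_seed = int(rng.integers(_MAX_SEED))
        noisy, mask = perturb(points, noise_fraction, seed=perturb_seed)
        try:
            resampled = _fit_kmeans(noisy, k, kmeans_seed, resample_init, resample_n_init)
        except Exception:  # resample counted as non-preserving for all clusters
            logger.exception("k-means failed on a resample; counted as non-preserving")
            continue
        for i, orig in enumerate(originals):
            ok, _ = cluster_preserved(orig, resampled, mask, threshold)
            if ok:
                preserved_counts[i] += 1
    per = tuple(preserved_counts / m)
    return StabilityReport(
        per_cluster_stability=per,
        overall_stability=float(np.mean(per)),
        m=m,
        jaccard_threshold=threshold,
        noise_fraction=noise_fraction,
    )


def most_stable_clustering(
    points: np.ndarray | Embedding,
    k: int,
    n_candidates: int = 20,
    m: int = 1000,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
    seed: int = 0,
    resample_init: str = "k-means++",
    resample_n_init: int = 10,
) -> StableClusteringResult:
    """Generate candidate clusterings and return the most stable one.

    Candidates are k-means runs on the same coordinates differing only in
    their seeded initialisation. Ties in overall stability are broken toward
    the first candidate generated.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    emb = points if isinstance(points, Embedding) else None
    coords = points.coords if isinstance(points, Embedding) else np.asarray(points, float)
    rng = np.random.default_rng(seed)
    candidates: list[Clustering] = []
    reports: list[StabilityReport] = []
    for i in range(n_candidates):
        cand_seed = int(rng.integers(_MAX_SEED))
        score_seed = int(rng.integers(_MAX_SEED))
        cand = _fit_kmeans(coords, k, cand_seed, resample_init, resample_n_init)
        report = stability_of(
            cand, coords, m=m, k=k,
            noise_fraction=noise_fraction, threshold=threshold, seed=score_seed,
            resample_init=resample_init, resample_n_init=resample_n_init,
        )
        logger.info("candidate %d/%d: overall stability %.3f",
                    i + 1, n_candidates, report.overall_stability)
        candidates.append(cand)
        reports.append(report)
    best = int(np.argmax([r.overall_stability for r in reports]))  # first max wins
    return StableClusteringResult(
        chosen=candidates[best],
        chosen_report=reports[best],
        chosen_index=best,
        all_reports=tuple(reports),
        embedding_used=emb,
        candidates=tuple(candidates),
    )
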
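"""Cell-cell Euclidean distances and their 2-D t-SNE embedding.

The pipeline measures dissimilarity between cells with the Euclidean metric
on the (filtered, log-transformed) expression profiles, then reduces the
resulting cell × cell distance matrix D to an l-dimensional map D' with
t-SNE run in precomputed-distance mode. l = 2 throughout unless configured
otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .containers import DistanceMatrix, Embedding, ExpressionMatrix

__all__ = ["pairwise_euclidean", "embed", "feasible_perplexity"]

DEFAULT_PERPLEXITY = 30.0


def pairwise_euclidean(m: ExpressionMatrix) -> DistanceMatrix:
    """Euclidean distance between every pair of cells (columns of ``m``)."""
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to compute pairwise distances")
    d = squareform(pdist(m.values.T, metric="euclidean"))
    return DistanceMatrix(values=d, cell_ids=list(m.cell_ids))


def feasible_perplexity(n_cells: int, requested: float = DEFAULT_PERPLEXITY) -> float:
    """Largest usable perplexity: floor((n_cells - 1) / 3), strictly below
    the (n_cells - 1) / 3 bound, capped at ``requested``."""
    limit = (n_cells - 1) / 3
    cap = float(np.floor(limit))
    if cap >= limit:  # limit is an integer; stay strictly below it
        cap -= 1.0
    if cap < 1.0:
        raise ValueError(f"too few cells ({n_cells}) for any usable perplexity")
    return min(float(requested), cap)


def embed(
    d: DistanceMatrix,
    l: int = 2,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 0,
) -> Embedding:
    """t-SNE embedding of a precomputed distance matrix.

    Deterministic for a fixed ``seed``. ``perplexity`` must be below
    (n_cells - 1) / 3; use :func:`feasible_perplexity` to pick a safe value
    for small datasets.
    """
    n = d.n_cells
    limit = (n - 1) / 3
    if perplexity >= limit:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n} cells; "
            f"must be < {limit:.2f} (feasible maximum "
            f"{feasible_perplexity(n, perplexity)})"
        )
    tsne = TSNE(
        n_components=l,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=int(seed),
        n_jobs=1,
    )
    coords = tsne.fit_transform(d.values)
    return Embedding(coords=np.asarray(coords, dtype=float), seed=int(seed),
                     cell_ids=list(d.cell_ids))
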
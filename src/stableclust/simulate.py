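"""Synthetic gene × cell matrices with known labels and tunable separability.

The generator draws k cell populations from a log-normal cluster model:
expression is Gaussian on the log2 scale, where each cluster shifts a random
subset of "marker" genes (default 20% of genes per cluster) away from a
shared baseline programme. ``separability`` is the ratio of the marker-gene
mean shift to the within-cluster standard deviation on the log scale, so
separability 0 makes all clusters identically distributed while large values
produce essentially disjoint populations. Values are mapped back to the
expression scale with 2**x − 1 (the inverse of the pipeline's log2(x + 1)
transform), rounded, and clipped at zero. Technical dropout is emulated by
independent Bernoulli zeroing of entries, and a configurable fraction of
genes is zeroed entirely to exercise the gene filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["SimulationSpec", "simulate"]

DEFAULT_MARKER_FRACTION = 0.20
BASELINE_LOG_MEAN = 4.0
BASELINE_LOG_SD = 1.5
WITHIN_CLUSTER_SD = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset."""

    n_clusters: int
    cells_per_cluster: int | tuple[int, ...] = 50
    n_genes: int = 500
    separability: float = 10.0
    dropout_rate: float = 0.3
    zero_gene_fraction: float = 0.0
    marker_fraction: float = DEFAULT_MARKER_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        sizes = self.cluster_sizes
        if any(s < 1 for s in sizes):
            raise ValueError("every cluster must contain at least one cell")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.zero_gene_fraction < 1.0:
            raise ValueError("zero_gene_fraction must be in [0, 1)")
        if not 0.0 < self.marker_fraction <= 1.0:
            raise ValueError("marker_fraction must be in (0, 1]")

    @property
    def cluster_sizes(self) -> tuple[int, ...]:
        if isinstance(self.cells_per_cluster, int):
            return (self.cells_per_cluster,) * self.n_clusters
        sizes = tuple(int(s) for s in self.cells_per_cluster)
        if len(sizes) != self.n_clusters:
            raise ValueError("cells_per_cluster list must have n_clusters entries")
        return sizes

    @property
    def n_cells(self) -> int:
        return sum(self.cluster_sizes)


def simulate(spec: SimulationSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate one synthetic expression matrix and its true labels.

    Deterministic for a fixed ``spec.seed``. Returns a genes × cells
    :class:`ExpressionMatrix` and an integer label per cell (clusters are
    contiguous blocks of columns).
    """
    rng = np.random.default_rng(spec.seed)
    g, sizes = spec.n_genes, spec.cluster_sizes

    baseline = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=g)
    shift = spec.separability * WITHIN_CLUSTER_SD
    cluster_means = np.tile(baseline, (spec.n_clusters, 1))
    n_markers = max(1, int(round(spec.marker_fraction * g)))
    for c in range(spec.n_clusters):
        markers = rng.choice(g, size=n_markers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_markers)
        cluster_means[c, markers] += signs * shift

    blocks = []
    labels = []
    for c, size in enumerate(sizes):
        logx = cluster_means[c][:, None] + rng.normal(
            0.0, WITHIN_CLUSTER_SD, size=(g, size)
        )
        blocks.append(logx)
        labels.extend([c] * size)
    logx = np.concatenate(blocks, axis=1)
    values = np.maximum(np.round(2.0**logx - 1.0), 0.0)

    if spec.dropout_rate > 0:
        values[rng.random(values.shape) < spec.dropout_rate] = 0.0
    # guarantee every gene is expressed somewhere before deliberate silencing,
    # so zero_gene_fraction controls the all-zero gene count exactly
    silent = ~np.any(values > 0, axis=1)
    values[silent, 0] = 1.0
    if spec.zero_gene_fraction > 0:
        n_zero = int(round(spec.zero_gene_fraction * g))
        zero_genes = rng.choice(g, size=n_zero, replace=False)
        values[zero_genes, :] = 0.0

    gene_ids = [f"gene_{i}" for i in range(g)]
    cell_ids = [f"cell_{j}" for j in range(len(labels))]
    return (
        ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids),
        np.asarray(labels, dtype=int),
    )
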
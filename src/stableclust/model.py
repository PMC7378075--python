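"""Model/Results facade over the stable-clustering pipeline.

``StableClusterModel`` holds an expression matrix and a configuration;
``fit()`` runs gene filtering, log transformation, Euclidean distances,
repeated-t-SNE k selection, and stability-based candidate selection, and
returns a ``StableClusterResults`` carrying the cluster assignment, the
chosen k, per-cluster stability diagnostics and the full audit trail.

    >>> from stableclust import StableClusterModel, SimulationSpec, simulate
    >>> expr, truth = simulate(SimulationSpec(n_clusters=3, seed=1))
    >>> res = StableClusterModel(expr).fit()      # doctest: +SKIP
    >>> res.k, res.overall_stability              # doctest: +SKIP
    (3, 1.0)
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .config import PipelineConfig
from .containers import Embedding, ExpressionMatrix
from .embedding import embed, feasible_perplexity, pairwise_euclidean
from .model_selection import KSelectionResult, select_k
from .preprocess import filter_unexpressed_genes, log_transform
from .stability import StableClusteringResult, most_stable_clustering

__all__ = ["StableClusterModel", "StableClusterResults"]

logger = logging.getLogger(__name__)


class StableClusterModel:
    """Stability-based clustering of a genes × cells expression matrix.

    Parameters
    ----------
    expression
        A validated :class:`ExpressionMatrix`.
    config
        Pipeline tunables; defaults to the published operating point.
    """

    def __init__(self, expression: ExpressionMatrix,
                 config: PipelineConfig | None = None) -> None:
        if not isinstance(expression, ExpressionMatrix):
            raise TypeError("expression must be an ExpressionMatrix; "
                            "see StableClusterModel.from_dataframe")
        self.expression = expression
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       orientation: str = "gene_by_cell",
                       config: PipelineConfig | None = None) -> "StableClusterModel":
        """Build a model from a DataFrame of expression values.

        ``orientation`` is ``"gene_by_cell"`` (rows are genes) or
        ``"cell_by_gene"`` (rows are cells, as in the SingleCellExperiment
        convention); the matrix is stored internally as genes × cells.
        """
        if orientation == "cell_by_gene":
            df = df.T
        elif orientation != "gene_by_cell":
            raise ValueError("orientation must be 'gene_by_cell' or 'cell_by_gene'")
        m = ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
        )
        return cls(m, config=config)

    def fit(self, k: int | None = None) -> "StableClusterResults":
        """Run the full pipeline and return the fitted results.

        If ``k`` is given the repeated-embedding selection stage is skipped
        and the provided number of clusters is used directly.
        """
        cfg = self.config
        t0 = time.perf_counter()

        m = filter_unexpressed_genes(self.expression)
        n_removed = self.expression.n_genes - m.n_genes
        logger.info("gene filtering: removed %d of %d genes",
                    n_removed, self.expression.n_genes)
        if cfg.log_transform:
            m = log_transform(m)

        d = pairwise_euclidean(m)
        perp = feasible_perplexity(d.n_cells, cfg.perplexity)
        if perp < cfg.perplexity:
            logger.info("perplexity lowered to %.0f for %d cells", perp, d.n_cells)

        k_selection: KSelectionResult | None = None
        if k is None:
            k_selection = select_k(
                d, n_repeats=cfg.n_tsne_repeats,
                k_range=(cfg.k_min, min(cfg.k_max, d.n_cells - 1)),
                base_seed=cfg.seed, perplexity=perp, l=cfg.tsne_dims,
            )
            k = k_selection.k_final
            logger.info("selected k = %d", k)

        # fresh embedding for the stability stage, seeded past the k-selection runs
        final_seed = cfg.seed + cfg.n_tsne_repeats
        emb = embed(d, l=cfg.tsne_dims, perplexity=perp, seed=final_seed)

        stable = most_stable_clustering(
            emb, k=k,
            n_candidates=cfg.n_candidates, m=cfg.n_resamplings,
            noise_fraction=cfg.noise_fraction, threshold=cfg.jaccard_threshold,
            seed=cfg.seed, resample_init=cfg.resample_init,
            resample_n_init=cfg.resample_n_init,
        )
        elapsed = time.perf_counter() - t0
        logger.info("pipeline finished in %.1f s (k=%d, stability=%.3f)",
                    elapsed, k, stable.chosen_report.overall_stability)
        return StableClusterResults(
            model=self, k=k, k_selection=k_selection,
            stable=stable, embedding=emb,
            n_genes_removed=n_removed, elapsed_seconds=elapsed,
        )


@dataclass
class StableClusterResults:
    """Fitted results: assignment, k, stability diagnostics, audit trail."""

    model: StableClusterModel
    k: int
    k_selection: KSelectionResult | None
    stable: StableClusteringResult
    embedding: Embedding
    n_genes_removed: int
    elapsed_seconds: float = field(default=0.0)

    @property
    def labels(self) -> np.ndarray:
        return self.stable.chosen.labels

    @property
    def cell_ids(self) -> list[str]:
        return list(self.model.expression.cell_ids)

    @property
    def overall_stability(self) -> float:
        return self.stable.chosen_report.overall_stability

    @property
    def per_cluster_stability(self) -> tuple[float, ...]:
        return self.stable.chosen_report.per_cluster_stability

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels})

    def evaluate(self, truth: Sequence) -> dict:
        """ARI / AMI / V-measure of the fitted labels against known labels."""
        truth = np.asarray(truth)
        if len(truth) != len(self.labels):
            raise ValueError("truth labels must have one entry per cell")
        return _metrics.evaluate_clustering(truth, self.labels)

    def to_report_dict(self) -> dict:
        """Everything needed to reproduce and audit the run, JSON-ready."""
        cfg = self.model.config
        report = {
            "config": cfg.to_dict(),
            "n_cells": self.model.expression.n_cells,
            "n_genes_input": self.model.expression.n_genes,
            "n_genes_removed": self.n_genes_removed,
            "k": self.k,
            "chosen_candidate_index": self.stable.chosen_index,
            "per_cluster_stability": list(self.per_cluster_stability),
            "overall_stability": self.overall_stability,
            "candidate_overall_stabilities": [
                r.overall_stability for r in self.stable.all_reports
            ],
            "final_embedding_seed": self.embedding.seed,
        }
        if self.k_selection is not None:
            report["k_selection"] = {
                "k_final": self.k_selection.k_final,
                "per_repeat_k": self.k_selection.per_repeat_k,
                "seeds": self.k_selection.seeds,
            }
        return report

    def save(self, assignments_path, report_path) -> None:
        """Write the assignments CSV and the audit-report JSON atomically
        (nothing is written if serialisation fails)."""
        payload = json.dumps(self.to_report_dict(), indent=2, sort_keys=True)
        csv_text = self.assignments().to_csv(index=False)
        with open(assignments_path, "w") as fh:
            fh.write(csv_text)
        with open(report_path, "w") as fh:
            fh.write(payload)

    def embedding_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.embedding.coords[:, i]
                for i in range(self.embedding.l)}
        return pd.DataFrame({"cell_id": self.cell_ids, **cols})

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.model.config
        lines = [
            "Stable clustering results",
            "=" * 60,
            f"cells: {self.model.expression.n_cells}    "
            f"genes: {self.model.expression.n_genes} "
            f"({self.n_genes_removed} unexpressed removed)",
            f"number of clusters k: {self.k}"
            + ("" if self.k_selection is None
               else f"  (mean of {len(self.k_selection.per_repeat_k)} repeats)"),
            f"candidates scored: {len(self.stable.all_reports)}    "
            f"resamplings per candidate: {cfg.n_resamplings}",
            f"noise fraction: {cfg.noise_fraction}    "
            f"Jaccard threshold: {cfg.jaccard_threshold}",
            f"overall stability: {self.overall_stability:.4f}",
            "-" * 60,
            "cluster   size   stability",
        ]
        sizes = np.bincount(self.labels, minlength=self.k)
        for c in range(self.k):
            lines.append(f"{c:>7}   {sizes[c]:>4}   {self.per_cluster_stability[c]:>9.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)
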
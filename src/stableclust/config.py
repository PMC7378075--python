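"""Pipeline configuration with validated, literature-faithful defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the stable-clustering pipeline.

    Defaults are the published operating point: 50 t-SNE repeats for k
    selection over k in [2, 20], a 2-D embedding, 20 candidate clusterings
    each scored with 1000 noise resamplings replacing 5% of cells, and a
    Jaccard preservation threshold of 0.75. ``fast()`` gives a desk-scale
    profile for interactive work and tests.
    """

    log_transform: bool = True
    n_tsne_repeats: int = 50
    k_min: int = 2
    k_max: int = 20
    tsne_dims: int = 2
    perplexity: float = 30.0
    n_candidates: int = 20
    n_resamplings: int = 1000
    noise_fraction: float = 0.05
    jaccard_threshold: float = 0.75
    resample_init: str = "k-means++"
    resample_n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "n_tsne_repeats": self.n_tsne_repeats >= 1,
            "k_min": self.k_min >= 2,
            "k_max": self.k_max >= self.k_min,
            "tsne_dims": self.tsne_dims >= 2,
            "perplexity": self.perplexity > 0,
            "n_candidates": self.n_candidates >= 1,
            "n_resamplings": self.n_resamplings >= 1,
            "noise_fraction": 0.0 < self.noise_fraction < 1.0,
            "jaccard_threshold": 0.0 < self.jaccard_threshold <= 1.0,
            "resample_init": self.resample_init in ("k-means++", "random"),
            "resample_n_init": self.resample_n_init >= 1,
        }
        bad = [key for key, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration value(s) for: {', '.join(bad)}")

    @classmethod
    def fast(cls, **overrides) -> "PipelineConfig":
        """Desk-scale profile: 10 repeats, k in [2, 10], 5 candidates,
        50 resamplings. Intended for small simulated datasets and tests."""
        base = dict(n_tsne_repeats=10, k_max=10, n_candidates=5, n_resamplings=50)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)
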
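"""External validation metrics: ARI, AMI, and V-measure.

All three compare an inferred partition against reference labels through the
R × C contingency table n_ij = |X_i ∩ Y_j|:

* ARI — pair-counting Rand index adjusted for chance,
  (Σ_ij C(n_ij,2) − E) / (½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E) with
  E = Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2); a_i row sums, b_j column sums.
* AMI — (MI − E{MI}) / (max{H(X), H(Y)} − E{MI}), where E{MI} is the exact
  expectation of the mutual information over random partitions with the
  observed margins (hypergeometric model), evaluated in log-factorial space.
* V-measure — weighted harmonic mean of homogeneity
  h = 1 − H(C|K)/H(C) and completeness c = 1 − H(K|C)/H(K).

Entropies use the natural logarithm by default; AMI, homogeneity,
completeness and V are ratios of entropies and hence base-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "contingency",
    "ari",
    "entropy",
    "mutual_information",
    "expected_mi",
    "ami",
    "conditional_entropy",
    "homogeneity",
    "completeness",
    "v_measure",
    "evaluate_clustering",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap counts n_ij between two partitions of the same points."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("contingency counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def row_sums(self) -> np.ndarray:  # a_i
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:  # b_j
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def contingency(labels_x: Sequence, labels_y: Sequence) -> ContingencyTable:
    """Contingency table counts[i, j] = |X_i ∩ Y_j| for two label vectors."""
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if len(x) != len(y):
        raise ValueError(f"label vectors differ in length: {len(x)} vs {len(y)}")
    if len(x) == 0:
        raise ValueError("label vectors must be non-empty")
    xi = _as_codes(x)
    yi = _as_codes(y)
    counts = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return ContingencyTable(counts=counts)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def ari(t: ContingencyTable) -> float:
    """Adjusted Rand index of the two partitions summarised by ``t``.

    1 for identical partitions (up to relabeling), ~0 for random agreement.
    When the chance-adjustment denominator is zero (both partitions trivial
    in the same way) the conventional value 1 is returned.
    """
    if t.n < 2:
        raise ValueError("ARI requires at least 2 points")
    sum_ij = _comb2(t.counts).sum()
    sum_a = _comb2(t.row_sums).sum()
    sum_b = _comb2(t.col_sums).sum()
    expected = sum_a * sum_b / _comb2(np.array(t.n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def entropy(labels: Sequence, base: float | None = None) -> float:
    """Shannon entropy H = −Σ_i P(i) log P(i) of a partition's cluster sizes.

    Natural log by default; pass ``base`` (e.g. 2) for other units.
    Zero exactly when there is a single cluster.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    _, sizes = np.unique(labels, return_counts=True)
    p = sizes / len(labels)
    h = float(-np.sum(p * np.log(p))) + 0.0  # normalise -0.0
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def _entropy_from_sizes(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-np.sum(p * np.log(p)))


def mutual_information(t: ContingencyTable) -> float:
    """MI = Σ_ij P(i,j) log(P(i,j) / (P(i) P(j))); zero-count terms vanish."""
    n = t.n
    if n < 1:
        raise ValueError("empty contingency table")
    nij = t.counts.astype(float)
    a = t.row_sums.astype(float)[:, None]
    b = t.col_sums.astype(float)[None, :]
    nz = nij > 0
    pij = nij[nz] / n
    return float(np.sum(pij * np.log(nij[nz] * n / (a * b + (~nz))[nz])))


def expected_mi(t: ContingencyTable) -> float:
    """Expected MI of two random partitions with the margins of ``t``.

    The expectation is over the hypergeometric model: for each cell (i, j)
    the overlap n_ij ranges over [max(1, a_i + b_j − n), min(a_i, b_j)] and
    is weighted by a_i! b_j! (n − a_i)! (n − b_j)! / (n! n_ij! (a_i − n_ij)!
    (b_j − n_ij)! (n − a_i − b_j + n_ij)!), computed with log-factorials to
    avoid overflow.
    """
    n = t.n
    if n < 1:
        raise ValueError("empty contingency table")
    lgn = gammaln(n + 1)
    total = 0.0
    for a_i in t.row_sums:
        for b_j in t.col_sums:
            lo = max(1, a_i + b_j - n)
            hi = min(a_i, b_j)
            for nij in range(int(lo), int(hi) + 1):
                log_w = (
                    gammaln(a_i + 1) + gammaln(b_j + 1)
                    + gammaln(n - a_i + 1) + gammaln(n - b_j + 1)
                    - lgn - gammaln(nij + 1)
                    - gammaln(a_i - nij + 1) - gammaln(b_j - nij + 1)
                    - gammaln(n - a_i - b_j + nij + 1)
                )
                total += (nij / n) * math.log(n * nij / (a_i * b_j)) * math.exp(log_w)
    return total


def ami(labels_x: Sequence, labels_y: Sequence) -> float:
    """Adjusted mutual information, max-entropy normalisation.

    1 for identical partitions; ~0 when MI equals its chance expectation.
    Two identical single-cluster partitions return 1 by convention; any
    other zero-denominator case is an error.
    """
    t = contingency(labels_x, labels_y)
    hx = _entropy_from_sizes(t.row_sums, t.n)
    hy = _entropy_from_sizes(t.col_sums, t.n)
    if hx == 0.0 and hy == 0.0:
        return 1.0  # both single-cluster: identical trivial partitions
    mi = mutual_information(t)
    emi = expected_mi(t)
    denom = max(hx, hy) - emi
    if denom == 0.0:
        raise ValueError(
            "AMI undefined: max entropy equals expected MI for non-identical "
            "trivial partitions"
        )
    return float((mi - emi) / denom)


def _conditional_entropy(t: ContingencyTable) -> float:
    """H(rows | columns) = H(joint) − H(columns), from the table counts."""
    n = t.n
    nij = t.counts.astype(float)
    b = t.col_sums.astype(float)[None, :]
    nz = nij > 0
    return float(-np.sum((nij[nz] / n) * np.log(nij[nz] / (b + (~nz))[nz]))) + 0.0


def conditional_entropy(rows: Sequence, cols: Sequence) -> float:
    """H(rows | cols) in nats, e.g. H(C|K) for classes C given clusters K."""
    return _conditional_entropy(contingency(rows, cols))


def homogeneity(classes: Sequence, clusters: Sequence) -> float:
    """1 − H(C|K)/H(C): each cluster contains members of a single class."""
    t = contingency(classes, clusters)
    h_c_given_k = _conditional_entropy(t)
    if h_c_given_k <= 1e-15:
        return 1.0
    h_c = _entropy_from_sizes(t.row_sums, t.n)
    return float(1.0 - h_c_given_k / h_c)


def completeness(classes: Sequence, clusters: Sequence) -> float:
    """1 − H(K|C)/H(K): all members of a class land in a single cluster."""
    return homogeneity(clusters, classes)


def v_measure(classes: Sequence, clusters: Sequence, beta: float = 1.0) -> float:
    """Weighted harmonic mean (1 + β) h c / (β h + c) of homogeneity and
    completeness; β > 1 weights completeness more strongly."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    h = homogeneity(classes, clusters)
    c = completeness(classes, clusters)
    if h + c == 0.0:
        return 0.0
    return float((1.0 + beta) * h * c / (beta * h + c))


def evaluate_clustering(truth: Sequence, predicted: Sequence) -> dict:
    """All validation metrics of a predicted partition against the truth."""
    t = contingency(truth, predicted)
    return {
        "ari": ari(t),
        "ami": ami(truth, predicted),
        "homogeneity": homogeneity(truth, predicted),
        "completeness": completeness(truth, predicted),
        "v_measure": v_measure(truth, predicted),
        "k_truth": int(t.counts.shape[0]),
        "k_pred": int(t.counts.shape[1]),
    }
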
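"""Partition-comparison metrics: Rand, adjusted Rand, matched accuracy."""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, rand_score
from sklearn.metrics.cluster import contingency_matrix

from .ahc import Partition

__all__ = [
    "contingency_table",
    "rand_index",
    "adjusted_rand_index",
    "proportion_correct",
]

PartitionLike = Union[Partition, Sequence[int]]


def _labels(p: PartitionLike) -> np.ndarray:
    if isinstance(p, Partition):
        return np.asarray(p.labels)
    return np.asarray(p, dtype=int)


def _check_same_size(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must label the same variable set")


def contingency_table(a: PartitionLike, b: PartitionLike) -> np.ndarray:
    """Cluster-by-cluster co-occurrence counts; grand total = number of variables."""
    la, lb = _labels(a), _labels(b)
    _check_same_size(la, lb)
    return np.asarray(contingency_matrix(la, lb), dtype=int)


def rand_index(a: PartitionLike, b: PartitionLike) -> float:
    """Raw Rand index: fraction of variable pairs grouped concordantly."""
    la, lb = _labels(a), _labels(b)
    _check_same_size(la, lb)
    return float(rand_score(la, lb))


def adjusted_rand_index(a: PartitionLike, b: PartitionLike) -> float:
    """Chance-corrected Rand index under the permutation model.

    Degenerate cases where both partitions are single-cluster or both
    all-singletons are identical partitions and score 1.
    """
    la, lb = _labels(a), _labels(b)
    _check_same_size(la, lb)
    return float(adjusted_rand_score(la, lb))


def proportion_correct(truth: PartitionLike, est: PartitionLike) -> float:
    """Fraction of correctly classified variables under optimal cluster matching.

    Clusters of the estimate are matched one-to-one to true clusters by the
    assignment maximizing total agreement (Hungarian algorithm on the
    contingency table); unmatched clusters contribute zero.
    """
    table = contingency_table(truth, est)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / float(table.sum())
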
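"""Baseline clustering schemes: mutual information, linkage, random, consensus.

These are the comparison methods run next to the Bayes-factor clusterings:
AHC with raw or normalized Gaussian plug-in mutual information, classical
linkage criteria on correlation-derived dissimilarities, and clustering
uniformly at random.  Also included: consensus clustering by evidence
accumulation and the lexicographic method-ranking rule used to order
benchmark results.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .ahc import Hierarchy, MergeRecord, Partition, greedy_merge
from .evidence import gaussian_mutual_information
from .linalg import log_det_pd, restrict, symmetrize

__all__ = [
    "ahc_infomut",
    "ahc_linkage",
    "random_ahc",
    "consensus_cluster",
    "rank_methods",
]

_LN_2PIE = math.log(2.0 * math.pi * math.e)

LINKAGE_CRITERIA = ("single", "average", "complete", "ward")


def _gaussian_entropy(a: np.ndarray) -> float:
    """Differential entropy 0.5 ln((2 pi e)^d |A|) of a Gaussian with covariance A."""
    a = np.atleast_2d(a)
    return 0.5 * (a.shape[0] * _LN_2PIE + log_det_pd(a))


def ahc_infomut(
    s_hat: np.ndarray,
    normalized: bool = False,
    rng: Optional[np.random.Generator] = None,
    stop: str = "full",
    normalization: str = "joint",
    names: Optional[Sequence[str]] = None,
) -> Hierarchy:
    """AHC with Gaussian plug-in mutual information as the similarity.

    ``normalized=True`` divides I_hat by the joint Gaussian differential
    entropy (``normalization='joint'``) or by the smaller marginal entropy
    (``'min'``).  Mutual information carries no model evidence, so there is
    no automatic stopping rule: ``stop='auto'`` is rejected.  Every joint
    covariance block encountered must be positive definite, which requires
    N_eff at least the joint dimension.
    """
    if stop == "auto":
        raise ValueError("mutual-information AHC has no automatic stopping rule")
    if normalization not in ("joint", "min"):
        raise ValueError(f"unknown normalization {normalization!r}")
    s_hat = symmetrize(s_hat)

    def sim_fn(mi: Tuple[int, ...], mj: Tuple[int, ...]) -> float:
        val = gaussian_mutual_information(mi, mj, s_hat)
        if not normalized:
            return val
        if normalization == "joint":
            denom = _gaussian_entropy(restrict(s_hat, tuple(sorted(mi + mj))))
        else:
            denom = min(
                _gaussian_entropy(restrict(s_hat, mi)),
                _gaussian_entropy(restrict(s_hat, mj)),
            )
        return val / denom

    return greedy_merge(
        s_hat.shape[0],
        sim_fn,
        rng=rng,
        stop="full",
        method="infomut_norm" if normalized else "infomut",
        track_evidence=False,
        names=names,
        has_stopping_rule=False,
    )


def _hierarchy_from_linkage_matrix(
    z: np.ndarray, n_vars: int, method: str, names: Optional[Sequence[str]]
) -> Hierarchy:
    members: Dict[int, Tuple[int, ...]] = {i: (i,) for i in range(n_vars)}
    merges: List[MergeRecord] = []
    for t, row in enumerate(z, start=1):
        a, b = int(row[0]), int(row[1])
        new = tuple(sorted(members[a] + members[b]))
        members[n_vars - 1 + t] = new
        # similarity recorded as the negated linkage distance
        merges.append(
            MergeRecord(step=t, left=a, right=b, similarity=-float(row[2]), members=new)
        )
    return Hierarchy(
        n_vars=n_vars,
        merges=tuple(merges),
        cumulative_evidence=None,
        stop_level=len(merges),
        method=method,
        names=tuple(names) if names is not None else None,
    )


def ahc_linkage(
    s_hat: np.ndarray,
    criterion: str = "average",
    use_abs: bool = True,
    rng: Optional[np.random.Generator] = None,
    names: Optional[Sequence[str]] = None,
) -> Hierarchy:
    """Classical linkage AHC on correlation-derived dissimilarities.

    The input covariance/correlation estimate is rescaled to correlations r;
    the dissimilarity is 1 - |r| (``use_abs=True``) or 1 - 0.5(1 + r), both
    ranging over [0, 1].  Cluster-pair distances follow the standard
    recursive update of the chosen criterion (single, average, complete,
    ward).  ``rng`` is accepted for interface symmetry; the underlying
    implementation breaks ties deterministically.
    """
    if criterion not in LINKAGE_CRITERIA:
        raise ValueError(f"criterion must be one of {LINKAGE_CRITERIA}")
    s_hat = symmetrize(s_hat)
    d = np.sqrt(np.diag(s_hat))
    if np.any(d <= 0):
        raise ValueError("non-positive variance; cannot rescale to correlations")
    r = s_hat / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    dist = 1.0 - np.abs(r) if use_abs else 1.0 - 0.5 * (1.0 + r)
    np.fill_diagonal(dist, 0.0)
    z = scipy_linkage(squareform(dist, checks=False), method=criterion)
    tag = f"linkage_{criterion}" + ("_abs" if use_abs else "")
    return _hierarchy_from_linkage_matrix(z, s_hat.shape[0], tag, names)


def random_ahc(
    n_vars: int,
    rng: Optional[np.random.Generator] = None,
    names: Optional[Sequence[str]] = None,
) -> Hierarchy:
    """Null baseline: merge a uniformly random pair of clusters at each step."""
    if n_vars < 2:
        raise ValueError("need at least two variables")
    rng = np.random.default_rng(rng)

    def sim_fn(mi: Tuple[int, ...], mj: Tuple[int, ...]) -> float:
        return 0.0  # every pair tied; the tie-breaker picks uniformly

    return greedy_merge(
        n_vars,
        sim_fn,
        rng=rng,
        stop="full",
        method="random",
        track_evidence=False,
        names=names,
        has_stopping_rule=False,
    )


def consensus_cluster(
    partitions: Sequence[Partition], k: int
) -> Tuple[np.ndarray, Partition]:
    """Evidence-accumulation consensus over an ensemble of partitions.

    The stability matrix holds the fraction of input partitions placing each
    variable pair in the same cluster; it is then used as a similarity matrix
    in a Ward-criterion AHC cut at ``k`` clusters.
    """
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    n = partitions[0].n_vars
    if any(p.n_vars != n for p in partitions):
        raise ValueError("all partitions must cover the same variable set")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be in 1..{n}")
    stability = np.zeros((n, n))
    for p in partitions:
        lab = np.asarray(p.labels)
        stability += (lab[:, None] == lab[None, :]).astype(float)
    stability /= len(partitions)
    if k == n:
        return stability, Partition(labels=tuple(range(n)))
    if k == 1 or n == 1:
        return stability, Partition(labels=(0,) * n)
    dist = 1.0 - stability
    np.fill_diagonal(dist, 0.0)
    z = scipy_linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return stability, Partition(labels=tuple(int(l) for l in labels))


def rank_methods(
    results: Mapping[str, Mapping[str, Sequence[float]]]
) -> List[str]:
    """Order methods best-first by the lexicographic benchmark rule.

    Sort keys, in order and all descending: median ARI, 25th-percentile ARI,
    5th-percentile ARI, minimum ARI, mean proportion correct.  ``results``
    maps method name to {'ari': samples, 'accuracy': samples}.
    """
    if not results:
        raise ValueError("no methods to rank")

    def key(name: str) -> Tuple[float, ...]:
        ari = np.asarray(results[name]["ari"], dtype=float)
        acc = np.asarray(results[name]["accuracy"], dtype=float)
        if ari.size == 0:
            raise ValueError(f"method {name!r} has no ARI samples")
        return (
            float(np.median(ari)),
            float(np.percentile(ari, 25)),
            float(np.percentile(ari, 5)),
            float(np.min(ari)),
            float(np.mean(acc)),
        )

    return sorted(results, key=key, reverse=True)
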
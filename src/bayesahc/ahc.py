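"""Agglomerative hierarchical clustering driven by Bayes-factor similarities.

The engine greedily merges the pair of clusters with the largest similarity.
Maxima tied within an absolute tolerance are broken uniformly at random from
the supplied generator — symmetric inputs produce genuine floating-point ties
and the random choice exposes (rather than hides) the resulting instability.

For the Bayesian and BIC similarities the merge values telescope: the
cumulative sum of merge similarities at level l equals the log evidence of the
level-l partition relative to all singletons, so the hierarchy doubles as a
model-comparison trace.  Merging is worthwhile only while the best similarity
is strictly positive; the automatic stopping rule halts there, and the stopped
partition is (greedily) the level of maximal evidence.

Similarities need not decrease along the merge sequence; nothing here assumes
monotone dendrogram heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evidence import EvidenceModel, SumOfSquares, similarity_bic
from .priors import PriorSpec, make_bayescorr_prior, make_bayescov_prior

__all__ = [
    "Partition",
    "MergeRecord",
    "Hierarchy",
    "run_ahc",
    "cut_hierarchy",
    "partition_at_level",
    "best_partition",
    "level_bayes_factor",
]

TIE_TOL = 1e-12

_METHOD_ALIASES = {
    "bayescov": "bayes_cov",
    "bayes_cov": "bayes_cov",
    "bayescorr": "bayes_corr",
    "bayes_corr": "bayes_corr",
    "bic": "bic",
}

_EVIDENCE_METHODS = ("bayes_cov", "bayes_corr", "bic")


@dataclass(frozen=True)
class Partition:
    """Assignment of variables 0..D-1 to disjoint clusters.

    Labels are canonicalized to 0..K-1 in order of first occurrence, so two
    partitions are equal iff they group the variables identically.
    """

    labels: Tuple[int, ...]

    def __post_init__(self) -> None:
        seen: Dict[int, int] = {}
        canon = []
        for lab in self.labels:
            if lab not in seen:
                seen[lab] = len(seen)
            canon.append(seen[lab])
        object.__setattr__(self, "labels", tuple(canon))

    @classmethod
    def from_sets(cls, clusters: Sequence[Sequence[int]], n_vars: int) -> "Partition":
        labels = [-1] * n_vars
        for k, members in enumerate(clusters):
            for i in members:
                if labels[i] != -1:
                    raise ValueError(f"variable {i} assigned twice")
                labels[i] = k
        if any(l == -1 for l in labels):
            raise ValueError("every variable must be assigned to a cluster")
        return cls(labels=tuple(labels))

    @property
    def n_vars(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def sets(self) -> List[Tuple[int, ...]]:
        out: Dict[int, List[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return [tuple(v) for _, v in sorted(out.items())]


@dataclass(frozen=True)
class MergeRecord:
    """One greedy merge: step index (1-based), cluster ids, similarity, members."""

    step: int
    left: int
    right: int
    similarity: float
    members: Tuple[int, ...]


@dataclass(frozen=True)
class Hierarchy:
    """Ordered merges with per-level cumulative evidence and stopping level.

    Cluster ids follow the merge-table convention: original variables are
    0..D-1 and the cluster created at step t gets id D-1+t.
    ``cumulative_evidence`` (levels 0..len(merges)) is only present for
    evidence-bearing methods (Bayes/BIC); ``stop_level`` is the number of
    merges performed before the best similarity first drops to <= 0 (equal to
    len(merges) if that never happens, or for methods with no stopping rule).
    """

    n_vars: int
    merges: Tuple[MergeRecord, ...]
    cumulative_evidence: Optional[Tuple[float, ...]]
    stop_level: int
    method: str
    names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.cumulative_evidence is not None:
            if len(self.cumulative_evidence) != len(self.merges) + 1:
                raise ValueError("cumulative evidence must have one entry per level")
            if self.cumulative_evidence[0] != 0.0:
                raise ValueError("cumulative evidence must start at 0")
        if not (0 <= self.stop_level <= len(self.merges)):
            raise ValueError("stop_level out of range")


def greedy_merge(
    n_vars: int,
    sim_fn: Callable[[Tuple[int, ...], Tuple[int, ...]], float],
    *,
    rng: Optional[np.random.Generator] = None,
    stop: str = "full",
    method: str = "custom",
    track_evidence: bool = True,
    names: Optional[Sequence[str]] = None,
    has_stopping_rule: bool = True,
) -> Hierarchy:
    """Generic greedy AHC loop over a pairwise cluster-similarity function."""
    if stop not in ("auto", "full"):
        raise ValueError(f"unknown stop mode {stop!r}")
    if n_vars < 1:
        raise ValueError("need at least one variable")
    rng = np.random.default_rng(rng)

    clusters: Dict[int, Tuple[int, ...]] = {i: (i,) for i in range(n_vars)}
    sims: Dict[Tuple[int, int], float] = {}
    merges: List[MergeRecord] = []
    cum: List[float] = [0.0]
    stop_level: Optional[int] = None
    next_id = n_vars

    while len(clusters) > 1:
        ids = sorted(clusters)
        for a, b in combinations(ids, 2):
            if (a, b) not in sims:
                sims[(a, b)] = sim_fn(clusters[a], clusters[b])
        best = max(sims.values())
        if has_stopping_rule and stop_level is None and best <= 0.0:
            stop_level = len(merges)
            if stop == "auto":
                break
        ties = [p for p, s in sims.items() if s >= best - TIE_TOL]
        a, b = ties[int(rng.integers(len(ties)))]
        members = tuple(sorted(clusters[a] + clusters[b]))
        s_ab = sims[(a, b)]
        merges.append(
            MergeRecord(
                step=len(merges) + 1, left=a, right=b, similarity=s_ab, members=members
            )
        )
        cum.append(cum[-1] + s_ab)
        del clusters[a], clusters[b]
        sims = {p: s for p, s in sims.items() if a not in p and b not in p}
        clusters[next_id] = members
        next_id += 1

    if stop_level is None:
        stop_level = len(merges)
    return Hierarchy(
        n_vars=n_vars,
        merges=tuple(merges),
        cumulative_evidence=tuple(cum) if track_evidence else None,
        stop_level=stop_level,
        method=method,
        names=tuple(names) if names is not None else None,
    )


def run_ahc(
    sos: SumOfSquares,
    method: str,
    global_prior: Optional[PriorSpec] = None,
    rng: Optional[np.random.Generator] = None,
    stop: str = "full",
) -> Hierarchy:
    """AHC with the exact Bayes-factor similarity or its BIC asymptotic form.

    ``method`` is one of ``bayes_cov`` (covariance-scale data, BayesCov
    prior), ``bayes_corr`` (correlation-rescaled data, BayesCorr prior), or
    ``bic`` (prior-free).  A custom ``global_prior`` overrides the default.
    ``stop='auto'`` halts before the first merge whose best similarity is
    <= 0; ``stop='full'`` completes all D-1 merges but still records the
    stopping level.
    """
    try:
        method = _METHOD_ALIASES[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None

    if method == "bic":
        if sos.n_eff <= 1:
            raise ValueError("BIC similarity needs n_eff > 1")
        s_hat = sos.sample_covariance()
        n_eff = sos.n_eff

        def sim_fn(mi: Tuple[int, ...], mj: Tuple[int, ...]) -> float:
            return similarity_bic(mi, mj, s_hat, n_eff)

    else:
        if method == "bayes_corr" and sos.mode != "correlation":
            sos = sos.to_correlation()
        if global_prior is None:
            global_prior = (
                make_bayescov_prior(sos)
                if method == "bayes_cov"
                else make_bayescorr_prior(sos.dim)
            )
        model = EvidenceModel(sos, global_prior)
        sim_fn = model.similarity

    return greedy_merge(
        sos.dim,
        sim_fn,
        rng=rng,
        stop=stop,
        method=method,
        track_evidence=True,
        names=sos.names,
    )


def partition_at_level(h: Hierarchy, level: int) -> Partition:
    """Partition after the first ``level`` merges (level 0 = all singletons)."""
    if not (0 <= level <= len(h.merges)):
        raise ValueError(f"level {level} out of range 0..{len(h.merges)}")
    clusters: Dict[int, Tuple[int, ...]] = {i: (i,) for i in range(h.n_vars)}
    next_id = h.n_vars
    for rec in h.merges[:level]:
        del clusters[rec.left], clusters[rec.right]
        clusters[next_id] = rec.members
        next_id += 1
    ordered = sorted(clusters.values(), key=lambda m: m[0])
    return Partition.from_sets(ordered, h.n_vars)


def cut_hierarchy(h: Hierarchy, k: int) -> Partition:
    """The partition with exactly ``k`` clusters (level D - k)."""
    if not (1 <= k <= h.n_vars):
        raise ValueError(f"k={k} must be in 1..{h.n_vars}")
    level = h.n_vars - k
    if level > len(h.merges):
        raise ValueError(
            f"hierarchy has only {len(h.merges)} merges (stopping truncated it); "
            f"cannot reach {k} clusters"
        )
    return partition_at_level(h, level)


def stopped_partition(h: Hierarchy) -> Partition:
    """Partition selected by the automatic stopping rule."""
    return partition_at_level(h, h.stop_level)


def best_partition(h: Hierarchy, search: str = "all") -> Partition:
    """Level of maximal cumulative evidence (largest marginal likelihood).

    ``search='all'`` considers every recorded level; ``search='to_stop'``
    restricts to levels up to the stopping level.  They coincide whenever the
    post-stop similarities never sum back above the running maximum, which
    holds on all reference examples.
    """
    if h.cumulative_evidence is None:
        raise ValueError(f"method {h.method!r} does not carry model evidence")
    cum = np.asarray(h.cumulative_evidence)
    if search == "to_stop":
        cum = cum[: h.stop_level + 1]
    elif search != "all":
        raise ValueError(f"unknown search mode {search!r}")
    return partition_at_level(h, int(np.argmax(cum)))


def level_bayes_factor(h: Hierarchy, level: int) -> float:
    """ln p(S | C_{l+1}) - ln p(S | C_l): the similarity of the merge at ``level``."""
    if not (0 <= level < len(h.merges)):
        raise ValueError(f"level {level} out of range 0..{len(h.merges) - 1}")
    return h.merges[level].similarity
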
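"""Marginal likelihoods and Bayes-factor similarities for Gaussian clustering.

Given i.i.d. multivariate normal data summarized by the sum-of-squares matrix
S (Wishart-distributed given the covariance Sigma) and a conjugate
inverse-Wishart prior on Sigma, the marginal likelihood of any subset of
variables has a closed form.  The similarity between two disjoint clusters
X_i, X_j is the log Bayes factor of "dependent" (free covariance across the
union) versus "independent" (block-diagonal covariance):

    s(X_i, X_j) = delta_phi(i u j) - delta_phi(i) - delta_phi(j),
    delta_phi(k) = phi(N + nu_k, Lambda_k + S_k) - phi(nu_k, Lambda_k),

where nu_k, Lambda_k come from marginalizing the global prior to cluster k.
Asymptotically s is N * I_hat - (D_i D_j / 2) ln N + O(1) with I_hat the
Gaussian plug-in mutual information — the BIC form, which needs no prior.

Only evidence *differences* (similarities, evidences relative to the
all-singletons partition) are exposed by the clustering engine: the data
constant |S|^{(N-D-1)/2} / Z(D, N) shared by all partitions is undefined when
N_eff < D, while the differences remain finite (the prior keeps
Lambda_k + S_k positive definite).  The absolute marginal likelihoods are
still available here for oracle checks at small dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .linalg import log_det_pd, log_wishart_norm, phi, restrict, symmetrize
from .priors import PriorSpec, restrict_prior

__all__ = [
    "SumOfSquares",
    "ClusterStat",
    "EvidenceModel",
    "delta_phi",
    "similarity_exact",
    "log_marginal_dependent",
    "log_marginal_independent",
    "gaussian_mutual_information",
    "similarity_bic",
    "log_evidence_relative",
]

Members = Tuple[int, ...]


@dataclass(frozen=True)
class SumOfSquares:
    """Sufficient statistic: sum-of-squares matrix with effective sample count.

    ``matrix`` is S = sum_n (x_n - mu)(x_n - mu)^T (or N_eff times the sample
    correlation matrix in correlation mode).  ``n_eff`` is N when the mean is
    known and N - 1 when the sample mean was used.
    """

    matrix: np.ndarray = field(repr=False)
    n_eff: float
    mode: str = "covariance"
    names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", symmetrize(self.matrix))
        if self.n_eff <= 0:
            raise ValueError("effective sample count must be positive")
        if self.mode not in ("covariance", "correlation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "correlation":
            diag = np.diag(self.matrix)
            if np.abs(diag - self.n_eff).max() > 1e-9 * max(self.n_eff, 1.0):
                raise ValueError(
                    "in correlation mode diag(S) must equal the effective sample count"
                )
        if self.names is not None:
            names = tuple(str(n) for n in self.names)
            if len(names) != self.dim:
                raise ValueError("number of names must match dimension")
            object.__setattr__(self, "names", names)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_data(
        cls, x: np.ndarray, names: Optional[Sequence[str]] = None
    ) -> "SumOfSquares":
        """Sum of squares about the sample mean; N_eff = N - 1."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("data must be a 2-d array (samples x variables)")
        n = x.shape[0]
        if n < 2:
            raise ValueError("need at least 2 samples to centre on the sample mean")
        centred = x - x.mean(axis=0, keepdims=True)
        return cls(
            matrix=centred.T @ centred,
            n_eff=float(n - 1),
            mode="covariance",
            names=tuple(names) if names is not None else None,
        )

    @classmethod
    def from_covariance(
        cls,
        sigma_hat: np.ndarray,
        *,
        n_obs: Optional[int] = None,
        n_eff: Optional[float] = None,
        mode: str = "covariance",
        names: Optional[Sequence[str]] = None,
    ) -> "SumOfSquares":
        """Build S = N_eff * Sigma_hat from a covariance/correlation estimate.

        Exactly one of ``n_obs`` (number of observations; the unknown-mean rule
        N_eff = N - 1 is applied) or ``n_eff`` (already mean-adjusted) must be
        given — the caller states explicitly which convention the count uses.
        """
        if (n_obs is None) == (n_eff is None):
            raise ValueError("supply exactly one of n_obs or n_eff")
        if n_obs is not None:
            if n_obs < 2:
                raise ValueError("n_obs must be >= 2")
            n_eff = float(n_obs - 1)
        sigma_hat = symmetrize(sigma_hat)
        return cls(
            matrix=float(n_eff) * sigma_hat,
            n_eff=float(n_eff),
            mode=mode,
            names=tuple(names) if names is not None else None,
        )

    def sample_covariance(self) -> np.ndarray:
        """S / N_eff — the sample covariance (or correlation) matrix."""
        return self.matrix / self.n_eff

    def to_correlation(self) -> "SumOfSquares":
        """Rescale to correlation mode: S_corr = N_eff * R_hat."""
        if self.mode == "correlation":
            return self
        diag = np.diag(self.matrix)
        if np.any(diag <= 0):
            raise ValueError("cannot rescale: non-positive diagonal entry")
        d = np.sqrt(diag)
        r = self.matrix / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        return SumOfSquares(
            matrix=self.n_eff * r,
            n_eff=self.n_eff,
            mode="correlation",
            names=self.names,
        )


@dataclass(frozen=True)
class ClusterStat:
    """A cluster's member set with its cached evidence increment delta_phi."""

    members: Members
    delta_phi: float

    @property
    def dim(self) -> int:
        return len(self.members)


def _canon(members: Iterable[int]) -> Members:
    out = tuple(sorted(int(i) for i in members))
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate members in {out}")
    return out


class EvidenceModel:
    """Caches delta_phi per member set for one (S, prior) pair.

    Merging two clusters then costs a single new evidence evaluation (the
    union's), which keeps the greedy AHC loop at O(D) evaluations per step.
    """

    def __init__(self, sos: SumOfSquares, prior: PriorSpec):
        if prior.dim != sos.dim:
            raise ValueError(
                f"prior dimension {prior.dim} does not match data dimension {sos.dim}"
            )
        self.sos = sos
        self.prior = prior
        self._cache: Dict[Members, float] = {}

    def delta_phi(self, members: Iterable[int]) -> float:
        key = _canon(members)
        val = self._cache.get(key)
        if val is None:
            p_k = restrict_prior(self.prior, key)
            s_k = restrict(self.sos.matrix, key)
            val = phi(self.sos.n_eff + p_k.nu, p_k.scale + s_k) - phi(
                p_k.nu, p_k.scale
            )
            self._cache[key] = val
        return val

    def cluster_stat(self, members: Iterable[int]) -> ClusterStat:
        key = _canon(members)
        return ClusterStat(members=key, delta_phi=self.delta_phi(key))

    def similarity(self, members_i: Iterable[int], members_j: Iterable[int]) -> float:
        mi, mj = _canon(members_i), _canon(members_j)
        if set(mi) & set(mj):
            raise ValueError("clusters must be disjoint")
        return self.delta_phi(mi + mj) - self.delta_phi(mi) - self.delta_phi(mj)

    def log_evidence_relative(self, clusters: Iterable[Iterable[int]]) -> float:
        """ln p(S | partition) - ln p(S | all singletons)."""
        clusters = [_canon(c) for c in clusters]
        flat = [i for c in clusters for i in c]
        if sorted(flat) != list(range(self.sos.dim)):
            raise ValueError("clusters must partition the full variable set")
        total = sum(self.delta_phi(c) for c in clusters)
        base = sum(self.delta_phi((d,)) for d in range(self.sos.dim))
        return total - base


def delta_phi(
    members: Iterable[int], sos: SumOfSquares, global_prior: PriorSpec
) -> float:
    """delta_phi(k) = phi(N_eff + nu_k, Lambda_k + S_k) - phi(nu_k, Lambda_k)."""
    return EvidenceModel(sos, global_prior).delta_phi(members)


def similarity_exact(
    stat_i: "ClusterStat | Iterable[int]",
    stat_j: "ClusterStat | Iterable[int]",
    sos: SumOfSquares,
    global_prior: PriorSpec,
) -> float:
    """Exact log Bayes factor s(X_i, X_j) of dependence versus independence."""
    model = EvidenceModel(sos, global_prior)
    mi = stat_i.members if isinstance(stat_i, ClusterStat) else _canon(stat_i)
    mj = stat_j.members if isinstance(stat_j, ClusterStat) else _canon(stat_j)
    return model.similarity(mi, mj)


def log_marginal_dependent(
    members: Iterable[int], sos: SumOfSquares, global_prior: PriorSpec
) -> float:
    """ln p(S_k | M_D): marginal likelihood with unrestricted covariance.

    Includes the data constant |S_k|^{(N-d-1)/2}/Z(d, N), so it requires
    N_eff > d - 1 and S_k positive definite; the similarity measures do not.
    """
    key = _canon(members)
    d = len(key)
    n = sos.n_eff
    p_k = restrict_prior(global_prior, key)
    s_k = restrict(sos.matrix, key)
    return (
        0.5 * (n - d - 1) * log_det_pd(s_k)
        - log_wishart_norm(d, n)
        + log_wishart_norm(d, n + p_k.nu)
        - log_wishart_norm(d, p_k.nu)
        + 0.5 * p_k.nu * log_det_pd(p_k.scale)
        - 0.5 * (n + p_k.nu) * log_det_pd(p_k.scale + s_k)
    )


def log_marginal_independent(
    members_i: Iterable[int],
    members_j: Iterable[int],
    sos: SumOfSquares,
    global_prior: PriorSpec,
) -> float:
    """ln p(S_{i u j} | M_I): marginal likelihood with block-diagonal covariance."""
    mi, mj = _canon(members_i), _canon(members_j)
    if set(mi) & set(mj):
        raise ValueError("clusters must be disjoint")
    if not mi or not mj:
        raise ValueError("clusters must be non-empty")
    union = _canon(mi + mj)
    d_u = len(union)
    n = sos.n_eff
    out = 0.5 * (n - d_u - 1) * log_det_pd(
        restrict(sos.matrix, union)
    ) - log_wishart_norm(d_u, n)
    for k in (mi, mj):
        d_k = len(k)
        p_k = restrict_prior(global_prior, k)
        s_k = restrict(sos.matrix, k)
        out += (
            log_wishart_norm(d_k, n + p_k.nu)
            - log_wishart_norm(d_k, p_k.nu)
            + 0.5 * p_k.nu * log_det_pd(p_k.scale)
            - 0.5 * (n + p_k.nu) * log_det_pd(p_k.scale + s_k)
        )
    return out


def gaussian_mutual_information(
    members_i: Iterable[int],
    members_j: Iterable[int],
    s_hat: np.ndarray,
) -> float:
    """Plug-in Gaussian mutual information I_hat = 0.5 ln(|S_i||S_j| / |S_{i u j}|).

    ``s_hat`` is any covariance-scale estimate; the determinant ratio is
    invariant to rescaling individual variables.  A singular joint block
    (sample covariance with N_eff < D_{i u j}) raises.
    """
    mi, mj = _canon(members_i), _canon(members_j)
    if set(mi) & set(mj):
        raise ValueError("clusters must be disjoint")
    union = _canon(mi + mj)
    s_hat = np.atleast_2d(np.asarray(s_hat, dtype=float))
    try:
        val = 0.5 * (
            log_det_pd(restrict(s_hat, mi))
            + log_det_pd(restrict(s_hat, mj))
            - log_det_pd(restrict(s_hat, union))
        )
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance block on {union}; mutual information needs "
            "N_eff >= the joint dimension"
        ) from exc
    if val < -1e-12 * len(union):
        raise ValueError(f"mutual information estimate {val} is significantly negative")
    return max(val, 0.0)


def similarity_bic(
    members_i: Iterable[int],
    members_j: Iterable[int],
    s_hat: np.ndarray,
    n_eff: float,
) -> float:
    """BIC similarity: N_eff * I_hat - (D_i D_j / 2) ln N_eff.

    The asymptotic form of the exact log Bayes factor; prior-free, and
    identical whether ``s_hat`` is the covariance or the correlation matrix.
    """
    if n_eff <= 1:
        raise ValueError("BIC similarity needs n_eff > 1")
    mi, mj = _canon(members_i), _canon(members_j)
    i_hat = gaussian_mutual_information(mi, mj, s_hat)
    return n_eff * i_hat - 0.5 * len(mi) * len(mj) * math.log(n_eff)


def log_evidence_relative(
    clusters: Iterable[Iterable[int]],
    sos: SumOfSquares,
    global_prior: PriorSpec,
) -> float:
    """Partition evidence relative to all singletons: sum_k delta_phi(k) - baseline."""
    return EvidenceModel(sos, global_prior).log_evidence_relative(clusters)
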
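"""Inverse-Wishart priors for the covariance matrix of a Gaussian vector.

Two canonical hyperparameter choices are provided:

* ``make_bayescov_prior`` ("BayesCov") — minimal degrees of freedom nu = D and
  a diagonal inverse scale matched to the observed sum-of-squares diagonal,
  Lambda_dd = (nu - D + 1)/N_eff * S_dd = S_dd/N_eff, which maximizes the
  marginal likelihood of the all-singletons model.
* ``make_bayescorr_prior`` ("BayesCorr") — nu = D + 1 with identity inverse
  scale, used on the sample *correlation* matrix; its implied marginals on
  correlation coefficients are uniform on [-1, 1].

The density convention is p(Sigma) ~ |Sigma|^{-(nu+D+1)/2} exp(-tr(Lambda
Sigma^{-1})/2), i.e. scipy's ``invwishart(df=nu, scale=Lambda)``.  Priors are
closed under marginalization to a subset of variables: nu_k = nu - D + D_k and
Lambda_k the corresponding principal submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.stats import invwishart

from .linalg import restrict, symmetrize

if TYPE_CHECKING:  # pragma: no cover
    from .evidence import SumOfSquares

__all__ = [
    "PriorSpec",
    "make_bayescov_prior",
    "make_bayescorr_prior",
    "restrict_prior",
    "sample_inverse_wishart",
]


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-Wishart prior: degrees of freedom ``nu`` and inverse scale ``scale``.

    ``mode`` records whether the prior is meant for a covariance-scale or a
    correlation-scale sum-of-squares matrix.  ``nu`` is stored as a real; the
    model places no integrality requirement on it.
    """

    nu: float
    scale: np.ndarray = field(repr=False)
    mode: str = "covariance"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", symmetrize(self.scale))
        if self.mode not in ("covariance", "correlation"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.nu <= self.dim - 1:
            raise ValueError(
                f"nu={self.nu} must exceed dim-1={self.dim - 1} for a proper prior"
            )
        # fail early on an indefinite scale matrix
        np.linalg.cholesky(self.scale)

    @property
    def dim(self) -> int:
        return self.scale.shape[0]


def make_bayescov_prior(sos: "SumOfSquares") -> PriorSpec:
    """BayesCov prior: nu = D, diagonal Lambda with Lambda_dd = S_dd / N_eff."""
    diag = np.diag(sos.matrix)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise ValueError(
            f"variable {bad} has non-positive sum of squares; "
            "constant variables cannot be clustered"
        )
    if sos.n_eff <= 0:
        raise ValueError("effective sample count must be positive")
    d = sos.dim
    return PriorSpec(nu=float(d), scale=np.diag(diag / sos.n_eff), mode="covariance")


def make_bayescorr_prior(d: int) -> PriorSpec:
    """BayesCorr prior: nu = D + 1, identity scale, correlation input mode."""
    d = int(d)
    if d < 1:
        raise ValueError("dimension must be >= 1")
    return PriorSpec(nu=float(d + 1), scale=np.eye(d), mode="correlation")


def restrict_prior(prior: PriorSpec, idx: Sequence[int]) -> PriorSpec:
    """Marginalize the prior to the variables in ``idx``.

    The inverse-Wishart family is closed under this marginalization with
    nu_k = nu - D + |idx| and Lambda_k = restrict(Lambda, idx).
    """
    idx = tuple(int(i) for i in idx)
    nu_k = prior.nu - prior.dim + len(idx)
    if nu_k <= len(idx) - 1:
        raise ValueError(
            f"restricted nu={nu_k} invalid for dimension {len(idx)}; "
            "the global prior is inconsistent"
        )
    return PriorSpec(nu=nu_k, scale=restrict(prior.scale, idx), mode=prior.mode)


def sample_inverse_wishart(prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """One draw Sigma ~ inverse-Wishart(nu, Lambda)."""
    draw = invwishart.rvs(df=prior.nu, scale=prior.scale, random_state=rng)
    return np.atleast_2d(np.asarray(draw, dtype=float))
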
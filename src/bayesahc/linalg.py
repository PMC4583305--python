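"""Numerically stable special functions and matrix primitives.

Everything downstream (marginal likelihoods, Bayes factors) is assembled from
the log Wishart normalization constant ln Z(d, n), the evidence kernel

    phi(n, A) = -(n/2) ln|A| + sum_{d'=1..d} ln Gamma((n + 1 - d')/2),

and principal-submatrix restriction.  All arithmetic stays in the natural-log
domain: the marginal likelihoods themselves overflow double precision already
for a handful of variables.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "symmetrize",
    "log_wishart_norm",
    "log_det_pd",
    "phi",
    "restrict",
]

_LN2 = math.log(2.0)
_LNPI = math.log(math.pi)


def symmetrize(a: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Validate and symmetrize a square matrix as (A + A^T)/2.

    Tolerates round-trip I/O noise up to ``rtol`` relative asymmetry; anything
    larger is treated as a genuinely non-symmetric input and rejected.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if a.shape[0] < 1:
        raise ValueError("matrix must have dimension >= 1")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix entries must be finite")
    scale = max(np.abs(a).max(), 1.0)
    if np.abs(a - a.T).max() > rtol * scale * a.shape[0]:
        raise ValueError("matrix is not symmetric within tolerance")
    return (a + a.T) / 2.0


def log_wishart_norm(d: int, n: float) -> float:
    """ln Z(d, n), the log normalization of the d-dimensional Wishart.

    Z(d, n) = 2^{nd/2} pi^{d(d-1)/4} prod_{d'=1}^{d} Gamma((n + 1 - d')/2).

    Requires n > d - 1 so that every gamma argument is positive.
    """
    d = int(d)
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    if n <= d - 1:
        raise ValueError(f"degrees of freedom n={n} must exceed d-1={d - 1}")
    dprime = np.arange(1, d + 1)
    return (
        0.5 * n * d * _LN2
        + 0.25 * d * (d - 1) * _LNPI
        + float(np.sum(gammaln((n + 1.0 - dprime) / 2.0)))
    )


def log_det_pd(a: np.ndarray) -> float:
    """ln|A| for a symmetric positive definite A via Cholesky.

    Factorization failure (``numpy.linalg.LinAlgError``) signals a singular or
    indefinite matrix; no jitter is added on the caller's behalf.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    chol = np.linalg.cholesky(a)
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def phi(n: float, a: np.ndarray) -> float:
    """Evidence kernel phi(n, A) = -(n/2) ln|A| + sum_d ln Gamma((n+1-d)/2)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    d = a.shape[0]
    if n <= d - 1:
        raise ValueError(f"degrees of freedom n={n} must exceed dim-1={d - 1}")
    dprime = np.arange(1, d + 1)
    return -0.5 * n * log_det_pd(a) + float(
        np.sum(gammaln((n + 1.0 - dprime) / 2.0))
    )


def restrict(a: np.ndarray, idx: Sequence[int]) -> np.ndarray:
    """Principal submatrix of ``a`` on the (0-based, strictly increasing) ``idx``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    idx = tuple(int(i) for i in idx)
    if len(idx) == 0:
        raise ValueError("index set must be non-empty")
    if any(i < 0 or i >= a.shape[0] for i in idx):
        raise ValueError(f"indices {idx} out of range for dim {a.shape[0]}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate indices in {idx}")
    if any(idx[k] >= idx[k + 1] for k in range(len(idx) - 1)):
        raise ValueError(f"indices {idx} must be strictly increasing")
    return a[np.ix_(idx, idx)]
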
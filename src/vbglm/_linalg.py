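"""Symmetric linear-algebra helpers shared by the estimators.

All covariance-role matrices in this package are handled through Cholesky
factorizations: inverses are realized as triangular solves, log-determinants
are read off the factor diagonal, and positive-definiteness is established
by whether the factorization succeeds.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

__all__ = [
    "NotPositiveDefiniteError",
    "sym",
    "safe_cholesky",
    "chol_logdet",
    "chol_inverse",
    "chol_solve",
    "is_pd",
]


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Raised when a matrix required to be positive-definite is not."""


def sym(a: np.ndarray) -> np.ndarray:
    """Symmetrize a matrix by averaging with its transpose."""
    return (a + a.T) / 2.0


def safe_cholesky(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Lower Cholesky factor of a symmetric p.d. matrix.

    Raises :class:`NotPositiveDefiniteError` (with the offending matrix name)
    instead of silently regularizing; callers decide how to react.
    """
    try:
        return sla.cholesky(sym(a), lower=True)
    except sla.LinAlgError as exc:
        raise NotPositiveDefiniteError(f"{name} is not positive-definite") from exc


def chol_logdet(chol_lower: np.ndarray) -> float:
    """log|A| from the lower Cholesky factor of A."""
    return 2.0 * float(np.sum(np.log(np.diag(chol_lower))))


def chol_solve(chol_lower: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve A x = b given the lower Cholesky factor of A."""
    return sla.cho_solve((chol_lower, True), b)


def chol_inverse(chol_lower: np.ndarray) -> np.ndarray:
    """Explicit inverse of A from its lower Cholesky factor."""
    n = chol_lower.shape[0]
    return sym(sla.cho_solve((chol_lower, True), np.eye(n)))


def is_pd(a: np.ndarray) -> bool:
    """Whether a symmetric matrix is positive-definite (by factorization)."""
    try:
        sla.cholesky(sym(a), lower=True)
        return True
    except sla.LinAlgError:
        return False
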
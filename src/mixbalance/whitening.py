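"""Centering and whitening transforms used before weight estimation.

Exposures and covariates are centred and orthogonalised,
``Z* = (Z - mean) S^{-1/2}``, with ``S`` the sample covariance
(divisor ``n-1``) and ``S^{-1/2}`` its *symmetric* inverse square root.
The symmetric root makes the transform basis-independent: any invertible
affine re-coding of the input columns changes the whitened matrix only by
an orthogonal rotation, which leaves the balancing-weight problem invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["whiten", "WhitenedDesign", "DegenerateCovarianceError"]


class DegenerateCovarianceError(np.linalg.LinAlgError):
    """Sample covariance is (numerically) singular and no ridge was allowed."""


def whiten(
    matrix: np.ndarray,
    ridge: float | None = None,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and whiten the columns of ``matrix``.

    Parameters
    ----------
    matrix : array, n x q
    ridge : float or None
        Floor applied to the eigenvalues of the sample covariance before
        inversion.  ``None`` (default) uses ``1e-10 * trace(S)`` as a purely
        numerical safeguard; an explicit ``0`` demands a strictly positive
        definite covariance and raises :class:`DegenerateCovarianceError`
        otherwise, naming the offending columns.
    names : sequence of str, optional
        Column names used in error messages.

    Returns
    -------
    (whitened, mean, inv_sqrt)
        ``whitened`` has column means 0 and identity sample covariance
        (divisor n-1); ``inv_sqrt`` is the symmetric inverse square root of
        the (ridged) covariance.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, q = M.shape
    if n < q + 1:
        raise ValueError(f"need at least q+1={q + 1} rows to whiten q={q} columns, got {n}")
    if names is None:
        names = [f"col{i}" for i in range(q)]
    mean = M.mean(axis=0)
    C = M - mean
    S = C.T @ C / (n - 1)
    evals, evecs = np.linalg.eigh(S)
    trace = float(np.trace(S))
    if trace <= 0.0:
        raise DegenerateCovarianceError(f"degenerate covariance: all columns constant ({list(names)})")
    floor = 1e-10 * trace if ridge is None else float(ridge)
    # numerically singular directions that the default floor must not mask
    if evals[0] <= 1e-12 * trace and (ridge is None or ridge == 0.0):
        v = evecs[:, 0]
        offending = [str(names[j]) for j in range(q) if abs(v[j]) > 0.3 / np.sqrt(q)]
        raise DegenerateCovarianceError(
            f"degenerate covariance: singular direction involving columns {offending} "
            f"(smallest eigenvalue {evals[0]:.3e}); pass ridge>0 to proceed"
        )
    evals = np.maximum(evals, floor if floor > 0.0 else evals[0])
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return C @ inv_sqrt, mean, inv_sqrt


@dataclass
class WhitenedDesign:
    """Whitened exposures and covariates with the transforms that made them."""

    t_star: np.ndarray
    x_star: np.ndarray
    t_mean: np.ndarray
    x_mean: np.ndarray
    t_cov_inv_sqrt: np.ndarray
    x_cov_inv_sqrt: np.ndarray

    @classmethod
    def from_arrays(
        cls,
        t: np.ndarray,
        x: np.ndarray,
        ridge: float | None = None,
        t_names: Sequence[str] | None = None,
        x_names: Sequence[str] | None = None,
    ) -> "WhitenedDesign":
        t_star, t_mean, t_isq = whiten(t, ridge=ridge, names=t_names)
        x_star, x_mean, x_isq = whiten(x, ridge=ridge, names=x_names)
        return cls(t_star, x_star, t_mean, x_mean, t_isq, x_isq)
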
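"""Empirical-likelihood balancing weights under cross-moment constraints.

Given whitened exposures T* (n x m) and covariates X* (n x p) the balance
constraints are collected in a single n x K matrix ``G`` with
``K = m*p + m + p`` columns:

* the ``m*p`` elementwise products ``T*_{ik} X*_{ij}`` in exposure-major
  order (k outer, j inner) — weighted exposure-covariate cross moments;
* the ``m`` columns of T* — weighted exposure means;
* the ``p`` columns of X* — weighted covariate means.

Exact balance solves the empirical-likelihood program

    max_w  sum_i log w_i   s.t.  (1/n) sum_i w_i g_i = 0,
                                 (1/n) sum_i w_i = 1,  w_i > 0,

whose unique solution has the dual form ``w_i = 1/(1 + lambda' g_i)``.
Exact balance is only attainable when zero lies in the interior of the
convex hull of the rows of G; with strongly confounded exposures and many
constraints that can fail at realistic sample sizes.  The solver therefore
also supports a *penalized* program that shrinks, rather than zeroes, the
residual moments: with prior scale ``c`` on each residual weighted
cross-moment,

    max_w  sum_i log w_i - (n / 2 c^2) ||rho(w)||^2,
           rho(w) = (1/n) sum_i w_i g_i,  (1/n) sum_i w_i = 1,  w_i > 0.

Both programs share one concave dual.  Minimizing over ``(theta, lambda)``

    D(theta, lambda) = -sum_i log(theta + lambda' g_i) + n*theta
                       + (n c^2 / 2) ||lambda||^2

yields ``w_i = 1/(theta + lambda' g_i)`` with residual moment
``rho = c^2 lambda`` (``c = 0`` recovers the exact program, where
``theta -> 1`` and the moments vanish).  The implementation runs a damped
Newton descent on ``D`` with a quadratically extended log below
``z = 1/n``; at any genuine optimum every ``z_i`` exceeds ``1/n`` because
no single weight can carry more than the whole sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["build_constraint_matrix", "solve_el_weights", "WeightSolution", "ELConvergenceError"]


class ELConvergenceError(RuntimeError):
    """The balance constraints could not be met (infeasible or solver stall)."""

    def __init__(self, message: str, max_abs_moment: float = float("nan")):
        super().__init__(f"{message} (max |weighted moment| = {max_abs_moment:.3e})")
        self.max_abs_moment = max_abs_moment


@dataclass
class WeightSolution:
    """Balancing weights with their dual multipliers and convergence evidence."""

    weights: np.ndarray
    dual: np.ndarray
    converged: bool
    max_abs_moment: float  # max_k |(1/n) sum_i w_i g_ik| at the solution
    iterations: int
    objective: float  # sum_i log w_i at the solution

    @property
    def n(self) -> int:
        return self.weights.size


def build_constraint_matrix(t_star: np.ndarray, x_star: np.ndarray) -> np.ndarray:
    """Stack the balance constraint columns for whitened T* and X*.

    Column order is fixed: products (exposure-major), then T*, then X*.
    """
    t_star = np.asarray(t_star, float)
    x_star = np.asarray(x_star, float)
    if t_star.ndim == 1:
        t_star = t_star[:, None]
    if x_star.ndim == 1:
        x_star = x_star[:, None]
    n, m = t_star.shape
    nx, p = x_star.shape
    if nx != n:
        raise ValueError(f"row mismatch: T* has {n} rows, X* has {nx}")
    products = (t_star[:, :, None] * x_star[:, None, :]).reshape(n, m * p)
    return np.concatenate([products, t_star, x_star], axis=1)


def _extended_log(z: np.ndarray, eps: float):
    """log(z) with a quadratic extension below ``eps`` (value, 1st, 2nd derivative)."""
    small = z < eps
    zc = np.where(small, eps, z)
    f = np.where(small, np.log(eps) - 1.5 + 2.0 * z / eps - z * z / (2.0 * eps * eps), np.log(zc))
    d1 = np.where(small, 2.0 / eps - z / (eps * eps), 1.0 / zc)
    d2 = np.where(small, -1.0 / (eps * eps), -1.0 / (zc * zc))
    return f, d1, d2, bool(small.any())


def solve_el_weights(
    G: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    slack: float = 0.0,
    balance_prior_sd: float | None = None,
) -> WeightSolution:
    """Solve for empirical-likelihood balancing weights.

    Parameters
    ----------
    G : array, n x K
        Constraint matrix (see :func:`build_constraint_matrix`).
    tol : float
        Convergence tolerance on the dual gradient: the weight-mean defect
        ``|mean(w) - 1|`` and, per coordinate, the distance of the weighted
        moment from its stationary value (0 when exact, ``c^2 lambda_k``
        when penalized).
    max_iter : int
        Newton iteration cap.
    slack : float
        Optional balance slack radius: with exact constraints, accept any
        iterate whose moment norm falls below ``max(tol, slack)``.
    balance_prior_sd : float or None
        Prior scale ``c`` on each residual weighted moment.  ``None`` or 0
        demands exact balance and raises if it is infeasible; a positive
        value (0.1 is the conventional acceptability threshold for a
        weighted correlation) always has a solution and leaves residual
        moments ``c^2 lambda``.

    Raises
    ------
    ELConvergenceError
        If zero is not in the interior of the convex hull of the rows of G
        (exact mode, infeasible constraints) or the solver stalls.
    """
    G = np.asarray(G, float)
    if G.ndim != 2:
        raise ValueError("G must be a 2-d array")
    n, K = G.shape
    if K >= n:
        raise ValueError(f"need more rows than constraints (n={n}, K={K})")
    if not np.all(np.isfinite(G)):
        raise ValueError("constraint matrix contains non-finite entries")
    c2 = 0.0 if balance_prior_sd is None else float(balance_prior_sd) ** 2
    exact = c2 == 0.0

    if exact:
        # a strictly signed column is a certificate of infeasibility
        cmin, cmax = G.min(axis=0), G.max(axis=0)
        signed = np.where((cmin > 0) | (cmax < 0))[0]
        if signed.size:
            k = int(signed[0])
            raise ELConvergenceError(
                f"infeasible balance constraints: column {k} of G is strictly signed, "
                "zero is outside the convex hull of the constraint rows",
                max_abs_moment=float(np.abs(G.mean(axis=0)).max()),
            )

    target = max(tol, slack) if exact else tol
    eps = 1.0 / n
    theta = 1.0
    lam = np.zeros(K)

    def dual(theta, lam):
        z = theta + G @ lam
        f, d1, d2, any_small = _extended_log(z, eps)
        val = -f.sum() / n + theta + 0.5 * c2 * (lam @ lam)
        return z, val, d1, d2, any_small

    z, val, d1, d2, any_small = dual(theta, lam)
    it = 0
    converged = False
    while it < max_iter:
        wbar = d1.mean()
        moment = G.T @ d1 / n
        g_theta = 1.0 - wbar
        g_lam = c2 * lam - moment
        gnorm = max(abs(g_theta), float(np.abs(g_lam).max()))
        if not any_small and gnorm <= target:
            converged = True
            break
        # Newton system over (theta, lambda)
        q = -d2 / n  # positive curvature weights 1/(n z^2)
        h_tt = q.sum()
        h_tl = G.T @ q
        h_ll = (G * q[:, None]).T @ G
        if c2 > 0.0:
            h_ll = h_ll + c2 * np.eye(K)
        H = np.empty((K + 1, K + 1))
        H[0, 0] = h_tt
        H[0, 1:] = h_tl
        H[1:, 0] = h_tl
        H[1:, 1:] = h_ll
        grad = np.concatenate([[g_theta], g_lam])
        try:
            delta = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = -np.linalg.solve(H + 1e-12 * np.trace(H) / (K + 1) * np.eye(K + 1), grad)
        slope = float(grad @ delta)
        if slope >= 0.0:  # loss of descent direction: fall back to steepest descent
            delta = -grad
            slope = -float(grad @ grad)
            if slope == 0.0:
                break
        step = 1.0
        accepted = False
        for _ in range(60):
            th_t = theta + step * delta[0]
            lam_t = lam + step * delta[1:]
            z_t, val_t, d1_t, d2_t, small_t = dual(th_t, lam_t)
            if val_t <= val + 1e-4 * step * slope:
                theta, lam, z, val, d1, d2, any_small = th_t, lam_t, z_t, val_t, d1_t, d2_t, small_t
                accepted = True
                break
            step *= 0.5
        it += 1
        if not accepted:
            break  # stall

    z = theta + G @ lam
    if converged and np.all(z > eps * (1.0 - 1e-12)):
        w = 1.0 / z
        mom = float(np.abs(G.T @ w).max() / n)
        return WeightSolution(
            weights=w,
            dual=lam,
            converged=True,
            max_abs_moment=mom,
            iterations=it,
            objective=float(np.log(w).sum()),
        )
    mom = float(np.abs(G.T @ (1.0 / np.maximum(z, eps))).max() / n)
    raise ELConvergenceError(
        f"empirical-likelihood solver did not converge in {it} iterations; "
        + (
            "the exact balance constraints may be infeasible for this sample "
            "(consider balance_prior_sd > 0)"
            if exact
            else "the penalized dual failed to reach the requested tolerance"
        ),
        max_abs_moment=mom,
    )
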
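"""Restricted (natural) cubic spline basis for dose-response curves.

Harrell's truncated-power parametrisation: for strictly increasing knots
``t_1 < ... < t_k`` the basis has ``k - 1`` columns — the identity (linear)
term plus ``k - 2`` cubic terms constrained to be linear beyond the boundary
knots.  Nonlinear terms are scaled by ``(t_k - t_1)^2`` so their magnitude
is comparable to the linear term.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rcs_basis", "default_knots"]


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis of ``x`` at ``knots``.

    Returns an ``n x (k-1)`` matrix whose first column is ``x`` itself
    (no intercept column).  The basis is C2-continuous everywhere and exactly
    linear outside ``[t_1, t_k]``.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {t.tolist()}")
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    d_last = t[-1] - t[-2]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / d_last
            + cube(x - t[-1]) * (t[-2] - t[j]) / d_last
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def default_knots(x: np.ndarray, weights: np.ndarray | None = None, n_knots: int = 4) -> np.ndarray:
    """Knots at weighted percentiles; 4 knots use the 5/35/65/95 placement.

    Standard quantile placements for 3-7 knots; weights (if given) define a
    weighted empirical distribution for the percentiles.
    """
    placements = {
        3: [10, 50, 90],
        4: [5, 35, 65, 95],
        5: [5, 27.5, 50, 72.5, 95],
        6: [5, 23, 41, 59, 77, 95],
        7: [2.5, 18.33, 34.17, 50, 65.83, 81.67, 97.5],
    }
    if n_knots not in placements:
        raise ValueError(f"n_knots must be in {sorted(placements)}")
    q = np.asarray(placements[n_knots], float) / 100.0
    x = np.asarray(x, float)
    if weights is None:
        knots = np.quantile(x, q)
    else:
        w = np.asarray(weights, float)
        order = np.argsort(x)
        xs, ws = x[order], w[order]
        cum = np.cumsum(ws) - 0.5 * ws
        cum /= ws.sum()
        knots = np.interp(q, cum, xs)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate knots: exposure distribution too concentrated")
    return knots
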
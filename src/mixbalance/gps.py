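"""Stabilized balancing-weight models for continuous exposure mixtures.

Two estimators of the stabilized weight ``w_i = f(T_i) / f(T_i | X_i)``:

* :class:`NonparametricCBGPS` — never specifies the exposure model.  It
  whitens T and X and solves the (penalized) empirical-likelihood program
  of :mod:`mixbalance.el`, driving every weighted exposure-covariate cross
  moment to zero exactly when that is feasible and shrinking it towards
  zero through a prior on the residual correlations otherwise.
* :class:`MultivariateGPS` — the parametric comparator.  It fits a multiple
  multivariate linear regression of T on X, assumes multivariate-normal
  errors, and forms the weight as the ratio of the marginal to the
  conditional normal density.  Its validity hinges on that exposure model
  being correct.

Both follow the Model/Results convention: construct from a
:class:`~mixbalance.data.MixtureSample`, call ``fit()``, inspect the
Results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics
from .data import MixtureSample
from .el import WeightSolution, build_constraint_matrix, solve_el_weights
from .whitening import WhitenedDesign

__all__ = [
    "NonparametricCBGPS",
    "MultivariateGPS",
    "MvgpsModel",
    "BalancingWeightsResults",
    "npmvcbgps_weights",
    "mvgps_weights",
    "fit_exposure_model",
]


class BalancingWeightsResults:
    """Weights attached to the original row order, plus diagnostics hooks."""

    def __init__(self, model, sample: MixtureSample, weights: np.ndarray, method: str):
        self.model = model
        self.sample = sample
        self.weights = np.asarray(weights, float)
        self.method = method

    def balance(self, subset=None) -> "diagnostics.BalanceReport":
        """Weighted vs unweighted exposure-covariate correlation report."""
        return diagnostics.balance_report(self.sample, self.weights, subset=subset)

    def weights_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.sample.exposures.index, name="weight")

    def summary(self) -> str:
        w = self.weights
        rep = self.balance()
        lines = [
            f"{self.method} balancing weights",
            f"  n = {w.size}, mean(w) = {w.mean():.6f}, min = {w.min():.4g}, max = {w.max():.4g}",
            f"  effective sample size = {w.sum() ** 2 / (w ** 2).sum():.1f}",
            f"  mean |weighted corr(T, X)| = {rep.mean_abs_weighted:.4f} (unweighted {rep.mean_abs_unweighted:.4f})",
        ]
        return "\n".join(lines)


class CBGPSResults(BalancingWeightsResults):
    def __init__(self, model, sample, solution: WeightSolution):
        super().__init__(model, sample, solution.weights, "npmvCBGPS")
        self.solution = solution

    @property
    def converged(self) -> bool:
        return self.solution.converged

    def summary(self) -> str:
        s = self.solution
        return (
            super().summary()
            + f"\n  converged in {s.iterations} Newton iterations, "
            + f"max |weighted moment| = {s.max_abs_moment:.2e}, sum log w = {s.objective:.4f}"
        )


class NonparametricCBGPS:
    """Nonparametric covariate-balancing weights for an exposure mixture.

    Parameters
    ----------
    sample : MixtureSample
    tol : float
        Dual-solver convergence tolerance.
    max_iter : int
        Newton iteration cap.
    ridge : float or None
        Eigenvalue floor used when whitening (see :func:`mixbalance.whitening.whiten`).
    balance_prior_sd : float or None
        Prior scale on each residual weighted cross-moment.  The default 0.1
        (the conventional acceptability threshold for a weighted
        exposure-covariate correlation) shrinks the residual moments towards
        zero and always has a solution; pass ``None`` or 0 to demand exact
        balance, which exists only when zero lies in the interior of the
        convex hull of the constraint rows.
    slack : float
        Optional balance slack radius for the exact mode.
    """

    def __init__(
        self,
        sample: MixtureSample,
        tol: float = 1e-8,
        max_iter: int = 200,
        ridge: float | None = None,
        balance_prior_sd: float | None = 0.1,
        slack: float = 0.0,
    ):
        self.sample = sample
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.balance_prior_sd = balance_prior_sd
        self.slack = slack

    @classmethod
    def from_dataframe(cls, df, exposures, covariates, outcome=None, **kwargs):
        return cls(MixtureSample.from_dataframe(df, exposures, covariates, outcome), **kwargs)

    def fit(self) -> CBGPSResults:
        s = self.sample
        design = WhitenedDesign.from_arrays(
            s.t, s.x, ridge=self.ridge, t_names=s.exposure_names, x_names=s.covariate_names
        )
        G = build_constraint_matrix(design.t_star, design.x_star)
        solution = solve_el_weights(
            G,
            tol=self.tol,
            max_iter=self.max_iter,
            slack=self.slack,
            balance_prior_sd=self.balance_prior_sd,
        )
        res = CBGPSResults(self, s, solution)
        res.design = design
        res.constraints = G
        return res


@dataclass
class MvgpsModel:
    """Fitted multivariate-normal exposure model behind the parametric weights."""

    alpha: np.ndarray  # (p+1) x m, intercept row first
    resid_cov: np.ndarray  # m x m, divisor n - p - 1
    marg_mean: np.ndarray  # m
    marg_cov: np.ndarray  # m x m, divisor n - 1


def fit_exposure_model(sample: MixtureSample) -> MvgpsModel:
    """Least-squares fit of T on [1, X] with multivariate-normal residuals."""
    t, x = sample.t, sample.x
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 = {p + 1} rows to fit the exposure model, got {n}")
    xa = np.column_stack([np.ones(n), x])
    alpha, _, rank, sv = np.linalg.lstsq(xa, t, rcond=None)
    if rank < p + 1:
        # name the columns loading on the null direction
        _, _, vt = np.linalg.svd(xa, full_matrices=False)
        v = vt[-1]
        names = ["(intercept)"] + sample.covariate_names
        offending = [names[j] for j in range(p + 1) if abs(v[j]) > 0.3 / np.sqrt(p + 1)]
        raise np.linalg.LinAlgError(f"rank-deficient exposure design; collinear columns: {offending}")
    resid = t - xa @ alpha
    resid_cov = resid.T @ resid / (n - p - 1)
    marg_mean = t.mean(axis=0)
    tc = t - marg_mean
    marg_cov = tc.T @ tc / (n - 1)
    return MvgpsModel(alpha=alpha, resid_cov=resid_cov, marg_mean=marg_mean, marg_cov=marg_cov)


def _mvn_logpdf(dev: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise multivariate normal log density of deviations ``dev`` under ``cov``."""
    m = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("exposure covariance is not positive definite") from err
    sol = np.linalg.solve(L, dev.T)
    quad = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (quad + m * np.log(2.0 * np.pi) + logdet)


class MultivariateGPS:
    """Parametric multivariate-normal GPS weights (the mvGPS comparator).

    ``trim_quantile`` optionally clips weights symmetrically at the
    (1-q, q) sample quantiles; the default is no trimming.
    """

    def __init__(self, sample: MixtureSample, trim_quantile: float | None = None):
        if trim_quantile is not None and not 0.5 < trim_quantile < 1.0:
            raise ValueError("trim_quantile must lie in (0.5, 1)")
        self.sample = sample
        self.trim_quantile = trim_quantile

    @classmethod
    def from_dataframe(cls, df, exposures, covariates, outcome=None, **kwargs):
        return cls(MixtureSample.from_dataframe(df, exposures, covariates, outcome), **kwargs)

    def fit(self) -> BalancingWeightsResults:
        s = self.sample
        model = fit_exposure_model(s)
        t, x = s.t, s.x
        xa = np.column_stack([np.ones(s.n), x])
        cond_mean = xa @ model.alpha
        log_num = _mvn_logpdf(t - model.marg_mean, model.marg_cov)
        log_den = _mvn_logpdf(t - cond_mean, model.resid_cov)
        w = np.exp(log_num - log_den)
        if self.trim_quantile is not None:
            lo, hi = np.quantile(w, [1.0 - self.trim_quantile, self.trim_quantile])
            w = np.clip(w, lo, hi)
        w = w / w.mean()  # comparability with the A3 normalization of the EL weights
        res = BalancingWeightsResults(self, s, w, "mvGPS")
        res.exposure_model = model
        return res


def npmvcbgps_weights(sample: MixtureSample, **kwargs) -> WeightSolution:
    """Functional wrapper: nonparametric balancing weights for ``sample``."""
    return NonparametricCBGPS(sample, **kwargs).fit().solution


def mvgps_weights(sample: MixtureSample, **kwargs) -> np.ndarray:
    """Functional wrapper: parametric multivariate-normal GPS weights."""
    return MultivariateGPS(sample, **kwargs).fit().weights
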
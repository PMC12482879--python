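"""Weighted marginal structural models for exposure mixtures.

After balancing weights have been estimated, causal mixture effects are
read off a *weighted* regression of the observed outcome on the original
(unwhitened) exposures,

    E[Y | T] = beta_0 + sum_k beta_k T_k  (+ optional product terms),

with a robust sandwich (HC0) covariance that treats the weights as fixed:

    cov(beta) = (X'WX)^{-1} (X'W diag(r^2) W X) (X'WX)^{-1},  W = diag(w).

Confidence intervals are Wald-normal.  For nonlinear dose-response,
each exposure can enter through a restricted cubic spline basis; the
fitted surface is summarised by two curves:

* single-exposure curve — one exposure varies over its 1st-99th
  percentile range, the others are fixed at their medians;
* joint-exposure curve — every exposure is set to its own q-th
  percentile as q sweeps a percentile grid (default 5-95 by 5).

Pointwise curve intervals come from the delta method on the sandwich
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MixtureSample
from .splines import default_knots, rcs_basis

__all__ = [
    "sandwich_covariance",
    "MixtureMSM",
    "MSMResults",
    "ExposureResponseCurve",
    "single_exposure_curve",
    "joint_exposure_curve",
]


def sandwich_covariance(design: np.ndarray, residuals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """HC0 sandwich for weighted least squares with fixed weights.

    ``(X'WX)^{-1} (X'W diag(r^2) W X) (X'WX)^{-1}`` with ``W = diag(weights)``.
    """
    X = np.asarray(design, float)
    r = np.asarray(residuals, float)
    w = np.asarray(weights, float)
    n, k = X.shape
    if r.shape != (n,) or w.shape != (n,):
        raise ValueError("design, residuals and weights dimensions disagree")
    bread = X.T @ (X * w[:, None])
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular weighted Gram matrix (bread)") from err
    meat = X.T @ (X * (w * r) [:, None] ** 2)
    cov = bread_inv @ meat @ bread_inv
    return (cov + cov.T) / 2.0


@dataclass
class _Design:
    """Maps an exposure matrix to the fitted right-hand side (minus adjustment)."""

    exposure_names: list[str]
    kind: str = "linear"  # 'linear' | 'rcs'
    interactions: tuple = ()  # pairs of exposure names, linear kind only
    knots: dict = field(default_factory=dict)  # name -> knot vector, rcs kind

    def build(self, T: np.ndarray) -> tuple[np.ndarray, list[str]]:
        T = np.atleast_2d(np.asarray(T, float))
        n = T.shape[0]
        cols, names = [np.ones(n)], ["Intercept"]
        ix = {nm: j for j, nm in enumerate(self.exposure_names)}
        if self.kind == "linear":
            for nm in self.exposure_names:
                cols.append(T[:, ix[nm]])
                names.append(nm)
            for a, b in self.interactions:
                cols.append(T[:, ix[a]] * T[:, ix[b]])
                names.append(f"{a}:{b}")
        elif self.kind == "rcs":
            for nm in self.exposure_names:
                basis = rcs_basis(T[:, ix[nm]], self.knots[nm])
                cols.append(basis.T)
                names.append(nm)
                names.extend(nm + "'" * (j + 1) for j in range(basis.shape[1] - 1))
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")
        return np.column_stack([c.T if c.ndim > 1 else c for c in cols]), names

    @property
    def descriptor(self) -> str:
        if self.kind == "linear":
            terms = list(self.exposure_names) + [f"{a}:{b}" for a, b in self.interactions]
        else:
            terms = [f"rcs({nm}, {len(self.knots[nm])})" for nm in self.exposure_names]
        return " + ".join(["1"] + terms)


class MixtureMSM:
    """Weighted outcome model for a mixture of continuous exposures.

    Parameters
    ----------
    sample : MixtureSample
        Must carry an outcome.
    weights : array or None
        Balancing weights (None = unweighted regression).
    design : 'linear' or 'rcs'
        Linear mixture terms, or an additive restricted-cubic-spline basis
        per exposure for dose-response estimation.
    interactions : sequence of (name, name)
        Product terms between exposures ('linear' design only).
    adjust : sequence of covariate names
        Covariates entered linearly alongside the exposures — used by the
        unweighted regression comparator; curves are unavailable then.
    n_knots : int
        Knots per exposure for the 'rcs' design, placed at weighted
        percentiles (4 knots: 5/35/65/95).
    """

    def __init__(
        self,
        sample: MixtureSample,
        weights: np.ndarray | None = None,
        design: str = "linear",
        interactions=(),
        adjust=(),
        n_knots: int = 4,
        knots: dict | None = None,
    ):
        if sample.outcome is None:
            raise ValueError("MixtureMSM requires a sample with an outcome column")
        self.sample = sample
        self.weights = np.ones(sample.n) if weights is None else np.asarray(weights, float)
        if self.weights.shape != (sample.n,):
            raise ValueError("weights must align with the sample rows")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if design == "rcs" and interactions:
            raise ValueError("interaction terms are only supported with the linear design")
        self.adjust = [str(c) for c in adjust]
        unknown = [c for c in self.adjust if c not in sample.covariate_names]
        if unknown:
            raise ValueError(f"unknown adjustment covariates: {unknown}")
        if design == "rcs":
            knots = dict(knots) if knots else {}
            for j, nm in enumerate(sample.exposure_names):
                if nm not in knots:
                    knots[nm] = default_knots(sample.t[:, j], self.weights, n_knots=n_knots)
        self._design = _Design(
            exposure_names=sample.exposure_names,
            kind=design,
            interactions=tuple((str(a), str(b)) for a, b in interactions),
            knots=knots or {},
        )

    @classmethod
    def from_dataframe(cls, df, exposures, covariates, outcome, weights=None, **kwargs):
        return cls(MixtureSample.from_dataframe(df, exposures, covariates, outcome), weights, **kwargs)

    def exog(self) -> tuple[np.ndarray, list[str]]:
        X, names = self._design.build(self.sample.t)
        if self.adjust:
            X = np.column_stack([X, self.sample.covariates[self.adjust].to_numpy(float)])
            names = names + self.adjust
        return X, names

    def fit(self) -> "MSMResults":
        X, names = self.exog()
        y = self.sample.y
        w = self.weights
        XtW = X.T * w
        gram = XtW @ X
        try:
            beta = np.linalg.solve(gram, XtW @ y)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular weighted design matrix") from err
        resid = y - X @ beta
        cov = sandwich_covariance(X, resid, w)
        return MSMResults(self, beta, cov, names, resid)


class MSMResults:
    """Weighted MSM coefficients with sandwich covariance and Wald inference."""

    def __init__(self, model: MixtureMSM, beta, cov, names, resid):
        self.model = model
        self.params = pd.Series(beta, index=names, name="coef")
        self.cov_params = pd.DataFrame(cov, index=names, columns=names)
        self.resid = resid
        self.nobs = model.sample.n
        self.design_descriptor = model._design.descriptor + (
            " + " + " + ".join(model.adjust) if model.adjust else ""
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index, name="se")

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.tvalues
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index, name="p")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.tvalues,
                "p": self.pvalues,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
            }
        )

    def summary(self, alpha: float = 0.05) -> str:
        head = (
            f"Weighted marginal structural model (n={self.nobs})\n"
            f"RHS: {self.design_descriptor}\n"
            f"Sandwich (HC0) standard errors, Wald-normal {100 * (1 - alpha):.0f}% CIs\n"
        )
        return head + self.summary_frame(alpha).to_string(float_format=lambda v: f"{v: .4f}")

    # -- prediction and curves -------------------------------------------------
    def predict(self, T: np.ndarray, se: bool = False):
        """Predicted outcome mean at exposure rows ``T`` (no adjustment terms)."""
        if self.model.adjust:
            raise ValueError("prediction over exposures alone is undefined with adjustment covariates")
        X, _ = self.model._design.build(T)
        fitted = X @ self.params.to_numpy()
        if not se:
            return fitted
        cov = self.cov_params.to_numpy()
        var = np.einsum("ij,jk,ik->i", X, cov, X)
        return fitted, np.sqrt(np.maximum(var, 0.0))

    def single_exposure_curve(self, exposure: str, grid_size: int = 50, grid=None, alpha: float = 0.05):
        return single_exposure_curve(self, exposure, grid_size=grid_size, grid=grid, alpha=alpha)

    def joint_exposure_curve(self, percentiles=None, alpha: float = 0.05):
        return joint_exposure_curve(self, percentiles=percentiles, alpha=alpha)


@dataclass
class ExposureResponseCurve:
    """A dose-response curve on a grid with pointwise Wald intervals."""

    grid: np.ndarray  # exposure values (single) or percentiles (joint)
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    curve_kind: str  # 'single-exposure' | 'joint-percentile'
    fixed_values: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grid": self.grid, "fitted": self.fitted, "ci_low": self.ci_low, "ci_high": self.ci_high}
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.fitted, **kwargs)
        ax.fill_between(self.grid, self.ci_low, self.ci_high, alpha=0.25)
        ax.set_ylabel("predicted outcome")
        ax.set_xlabel("exposure value" if self.curve_kind == "single-exposure" else "exposure percentile")
        return ax


def _curve_from_rows(results: MSMResults, T_rows, grid, kind, fixed, alpha):
    fitted, se = results.predict(T_rows, se=True)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return ExposureResponseCurve(
        grid=np.asarray(grid, float),
        fitted=fitted,
        ci_low=fitted - z * se,
        ci_high=fitted + z * se,
        curve_kind=kind,
        fixed_values=fixed,
    )


def single_exposure_curve(
    results: MSMResults, exposure: str, grid_size: int = 50, grid=None, alpha: float = 0.05
) -> ExposureResponseCurve:
    """Dose-response of one exposure with the others fixed at their medians."""
    sample = results.model.sample
    names = sample.exposure_names
    if exposure not in names:
        raise ValueError(f"unknown exposure {exposure!r}")
    T = sample.t
    j = names.index(exposure)
    medians = np.median(T, axis=0)
    if grid is None:
        if grid_size == 1:
            grid = np.array([medians[j]])
        else:
            lo, hi = np.percentile(T[:, j], [1, 99])
            grid = np.linspace(lo, hi, grid_size)
    grid = np.asarray(grid, float)
    rows = np.tile(medians, (grid.size, 1))
    rows[:, j] = grid
    fixed = {nm: float(medians[k]) for k, nm in enumerate(names) if k != j}
    return _curve_from_rows(results, rows, grid, "single-exposure", fixed, alpha)


def joint_exposure_curve(results: MSMResults, percentiles=None, alpha: float = 0.05) -> ExposureResponseCurve:
    """Dose-response of the whole mixture with every exposure at its own percentile."""
    sample = results.model.sample
    if percentiles is None:
        percentiles = np.arange(5, 96, 5)
    q = np.asarray(percentiles, float)
    T = sample.t
    rows = np.column_stack([np.percentile(T[:, j], q) for j in range(sample.m)])
    return _curve_from_rows(results, rows, q, "joint-percentile", {"percentile_grid": q.tolist()}, alpha)
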
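"""Covariate-balance diagnostics: weighted exposure-covariate correlations.

Balance after weighting is judged by the average absolute *weighted*
Pearson correlation between each exposure and each covariate; values
below 0.1 are conventionally taken as acceptable.  Weighted moments use
weights normalised to sum to n, with no reliability correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MixtureSample

__all__ = ["weighted_pearson", "balance_report", "BalanceReport"]


def _weighted_moments(x: np.ndarray, w: np.ndarray):
    mean = np.average(x, weights=w)
    var = np.average((x - mean) ** 2, weights=w)
    return mean, var


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation of ``x`` and ``y`` under positive weights ``w``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and w must have identical shapes")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    mx, vx = _weighted_moments(x, w)
    my, vy = _weighted_moments(y, w)
    if vx <= 0 or vy <= 0:
        raise ValueError("undefined correlation: zero weighted variance")
    cov = np.average((x - mx) * (y - my), weights=w)
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


@dataclass
class BalanceReport:
    """Weighted/unweighted exposure-covariate correlation grid with summaries."""

    pair_corr_weighted: pd.DataFrame  # m x p, exposures by covariates
    pair_corr_unweighted: pd.DataFrame
    mean_abs_weighted: float
    mean_abs_unweighted: float
    covariate_subset_label: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: exposure, covariate, weighted_r, unweighted_r."""
        wl = self.pair_corr_weighted.stack()
        ul = self.pair_corr_unweighted.stack()
        out = pd.DataFrame({"weighted_r": wl, "unweighted_r": ul}).reset_index()
        out.columns = ["exposure", "covariate", "weighted_r", "unweighted_r"]
        return out

    def summary_dict(self) -> dict:
        return {
            "covariate_subset": self.covariate_subset_label,
            "mean_abs_weighted": self.mean_abs_weighted,
            "mean_abs_unweighted": self.mean_abs_unweighted,
        }

    def plot(self, ax=None):
        """Love-style dot plot of absolute correlations before/after weighting."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, max(3, 0.3 * self.pair_corr_weighted.size)))
        long = self.to_frame()
        labels = long["exposure"] + " ~ " + long["covariate"]
        ypos = np.arange(len(long))
        ax.scatter(long["unweighted_r"].abs(), ypos, label="unweighted", marker="o")
        ax.scatter(long["weighted_r"].abs(), ypos, label="weighted", marker="x")
        ax.axvline(0.1, color="grey", linestyle="--", linewidth=1)
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlabel("|Pearson correlation|")
        ax.legend()
        return ax


def balance_report(
    sample: MixtureSample,
    weights: np.ndarray | None = None,
    subset: Sequence[str] | None = None,
) -> BalanceReport:
    """Exposure-covariate correlations before and after weighting.

    Parameters
    ----------
    sample : MixtureSample
    weights : array or None
        Balancing weights aligned to the sample rows; ``None`` means all 1
        (the weighted and unweighted panels then coincide).
    subset : sequence of covariate names, optional
        Restrict the report to these covariates (e.g. known confounders);
        the default uses all covariates.
    """
    n = sample.n
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,):
            raise ValueError(f"weights must have shape ({n},)")
    if subset is None:
        cov_names = sample.covariate_names
        label = "all covariates"
    else:
        cov_names = [str(c) for c in subset]
        missing = [c for c in cov_names if c not in sample.covariate_names]
        if missing:
            raise ValueError(f"unknown covariates in subset: {missing}")
        label = "subset: " + ",".join(cov_names)
    ones = np.ones(n)
    X = sample.covariates[cov_names].to_numpy(float)
    T = sample.t
    wmat = np.empty((sample.m, len(cov_names)))
    umat = np.empty_like(wmat)
    for k in range(sample.m):
        for j in range(len(cov_names)):
            wmat[k, j] = weighted_pearson(T[:, k], X[:, j], w)
            umat[k, j] = weighted_pearson(T[:, k], X[:, j], ones)
    idx = sample.exposure_names
    return BalanceReport(
        pair_corr_weighted=pd.DataFrame(wmat, index=idx, columns=cov_names),
        pair_corr_unweighted=pd.DataFrame(umat, index=idx, columns=cov_names),
        mean_abs_weighted=float(np.abs(wmat).mean()),
        mean_abs_unweighted=float(np.abs(umat).mean()),
        covariate_subset_label=label,
    )
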
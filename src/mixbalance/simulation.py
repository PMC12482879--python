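"""Monte-Carlo study of the mixture estimators.

The data-generating processes cover a 2 x 4 grid of exposure and outcome
models for three exposures and six covariates:

* covariates: (X1, X3, X4, X5, X6) jointly normal with mean 0, variance 1
  and pairwise covariance 0.2; X2 ~ Bernoulli(0.5), independent of the rest.
  X1-X3 confound both exposures and outcome; X4-X6 predict exposures only.
* exposure model E1 (linear):  T = X a1' + e,  e ~ N3(0, M) with unit
  variances and common off-diagonal ``trho``;
  E2 (quadratic) adds (X*X) a2', i.e. X1^2 enters every exposure.
* outcome models: Y1 linear (effects 0.6, -0.5, 0.8 on T1..T3 plus X b1),
  Y2 adds the interaction 0.2*T1*T3, Y3 adds X1^2 to Y1, Y4 adds both.

Each replicate draws a fresh dataset, runs the requested estimators
(nonparametric balancing weights, parametric mvGPS weights — both handed
the analyst-specified confounder set X1-X3 — and an unweighted regression
adjusting for all six covariates), and records
coefficient estimates, sandwich standard errors, p-values and the
post-weighting balance.  Replicate seeds are derived from
(master seed, setting fingerprint, replicate index) through a
``SeedSequence`` so every replicate is individually reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gps
from .data import MixtureSample
from .diagnostics import balance_report
from .el import ELConvergenceError
from .msm import MixtureMSM

logger = logging.getLogger(__name__)

__all__ = [
    "TRUE_EFFECTS",
    "INTERACTION_EFFECT",
    "CONFOUNDERS",
    "SimulationSetting",
    "SimulationResult",
    "simulate_covariates",
    "simulate_exposures",
    "simulate_outcome",
    "make_dataset",
    "run_replicate",
    "summarize",
    "run_simulation",
]

# ---------------------------------------------------------------------------
# fixed generating parameters of the study design
ALPHA1 = np.array(
    [
        [1, 1, 0, 1, 1, 0],
        [1, 0, 1, 1, 0, 1],
        [1, 0, 0, 0, 0, 0],
    ],
    dtype=float,
)
ALPHA2 = np.array([[1, 0, 0, 0, 0, 0]] * 3, dtype=float)  # X1^2 enters each exposure
BETA1 = np.array([1, 1, 1, 0, 0, 0], dtype=float)
BETA2 = np.array([1, 0, 0, 0, 0, 0], dtype=float)  # X1^2 enters the outcome
TRUE_EFFECTS = {"T1": 0.6, "T2": -0.5, "T3": 0.8}
INTERACTION_EFFECT = 0.2  # coefficient of T1*T3 under Y2/Y4
COVARIATE_COV_OFFDIAG = 0.2
BERNOULLI_P = 0.5
CONFOUNDERS = ["X1", "X2", "X3"]
EXPOSURE_NAMES = ["T1", "T2", "T3"]
COVARIATE_NAMES = ["X1", "X2", "X3", "X4", "X5", "X6"]
METHODS = ("npmvCBGPS", "mvGPS", "linear")


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the study grid."""

    exposure_model: str  # 'E1' | 'E2'
    outcome_model: str  # 'Y1' | 'Y2' | 'Y3' | 'Y4'
    n: int = 200
    trho: float = 0.2
    reps: int = 500
    seed: int = 0
    methods: tuple = METHODS
    weight_covariates: tuple = tuple(CONFOUNDERS)

    def __post_init__(self):
        if self.exposure_model not in ("E1", "E2"):
            raise ValueError(f"unknown exposure model {self.exposure_model!r}")
        if self.outcome_model not in ("Y1", "Y2", "Y3", "Y4"):
            raise ValueError(f"unknown outcome model {self.outcome_model!r}")
        if not -0.5 < self.trho < 1.0:
            raise ValueError("trho must lie in (-0.5, 1) for a positive definite error covariance")
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be positive")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")
        unknown = [c for c in self.weight_covariates if c not in COVARIATE_NAMES]
        if unknown:
            raise ValueError(f"unknown weight covariates {unknown}")

    @property
    def label(self) -> str:
        return f"{self.exposure_model}{self.outcome_model}"

    @property
    def with_interaction(self) -> bool:
        """Whether the fitted MSM includes the T1*T3 product term."""
        return self.outcome_model in ("Y2", "Y4")

    @property
    def truth(self) -> dict:
        t = dict(TRUE_EFFECTS)
        if self.with_interaction:
            t["T1:T3"] = INTERACTION_EFFECT
        return t

    def replicate_seed(self, rep: int) -> np.random.SeedSequence:
        fingerprint = zlib.crc32(f"{self.label}|{self.n}|{self.trho:.6g}".encode())
        return np.random.SeedSequence(entropy=(int(self.seed), int(fingerprint), int(rep)))


# ---------------------------------------------------------------------------
# data generation
def simulate_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """n x 6 covariate matrix: five equicorrelated normals and one Bernoulli (X2)."""
    if n < 1:
        raise ValueError("n must be positive")
    sigma = np.full((5, 5), COVARIATE_COV_OFFDIAG)
    np.fill_diagonal(sigma, 1.0)
    normals = rng.multivariate_normal(np.zeros(5), sigma, size=n, method="cholesky")
    x2 = rng.binomial(1, BERNOULLI_P, size=n).astype(float)
    X = np.empty((n, 6))
    X[:, 0] = normals[:, 0]  # X1
    X[:, 1] = x2  # X2
    X[:, 2:] = normals[:, 1:]  # X3..X6
    return X


def _error_cov(trho: float) -> np.ndarray:
    M = np.full((3, 3), trho)
    np.fill_diagonal(M, 1.0)
    return M


def simulate_exposures(
    X: np.ndarray, exposure_model: str, trho: float, rng: np.random.Generator, noise_scale: float = 1.0
) -> np.ndarray:
    """n x 3 exposures under E1 (linear) or E2 (adds the X1^2 term)."""
    X = np.asarray(X, float)
    if X.shape[1] != 6:
        raise ValueError("X must have 6 columns")
    M = _error_cov(trho)
    np.linalg.cholesky(M)  # raises if not PD
    T = X @ ALPHA1.T
    if exposure_model == "E2":
        T = T + (X * X) @ ALPHA2.T
    elif exposure_model != "E1":
        raise ValueError(f"unknown exposure model {exposure_model!r}")
    noise = rng.multivariate_normal(np.zeros(3), M, size=X.shape[0], method="cholesky")
    return T + noise_scale * noise


def simulate_outcome(
    T: np.ndarray, X: np.ndarray, outcome_model: str, rng: np.random.Generator, noise_scale: float = 1.0
) -> np.ndarray:
    """Outcome under Y1..Y4 with effects (0.6, -0.5, 0.8) and interaction 0.2."""
    T = np.asarray(T, float)
    X = np.asarray(X, float)
    if T.shape[0] != X.shape[0] or T.shape[1] != 3 or X.shape[1] != 6:
        raise ValueError("T must be n x 3 and X must be n x 6 with matching n")
    if outcome_model not in ("Y1", "Y2", "Y3", "Y4"):
        raise ValueError(f"unknown outcome model {outcome_model!r}")
    y = 0.6 * T[:, 0] - 0.5 * T[:, 1] + 0.8 * T[:, 2] + X @ BETA1
    if outcome_model in ("Y2", "Y4"):
        y = y + INTERACTION_EFFECT * T[:, 0] * T[:, 2]
    if outcome_model in ("Y3", "Y4"):
        y = y + (X * X) @ BETA2
    return y + noise_scale * rng.standard_normal(T.shape[0])


def make_dataset(
    exposure_model: str, outcome_model: str, n: int, trho: float, rng: np.random.Generator
) -> MixtureSample:
    """One simulated dataset as a named MixtureSample."""
    X = simulate_covariates(n, rng)
    T = simulate_exposures(X, exposure_model, trho, rng)
    y = simulate_outcome(T, X, outcome_model, rng)
    return MixtureSample(
        exposures=pd.DataFrame(T, columns=EXPOSURE_NAMES),
        covariates=pd.DataFrame(X, columns=COVARIATE_NAMES),
        outcome=pd.Series(y, name="Y"),
    )


# ---------------------------------------------------------------------------
# one replicate
def _collect_fit(fit, terms: list[str]) -> dict:
    sf = fit.summary_frame()
    out = {}
    for t in terms:
        row = sf.loc[t]
        out[t] = {
            "est": float(row["coef"]),
            "se": float(row["se"]),
            "p": float(row["p"]),
            "ci_low": float(row["ci_low"]),
            "ci_high": float(row["ci_high"]),
        }
    return out


def run_replicate(setting: SimulationSetting, rep: int) -> dict:
    """Generate one dataset and run every requested method on it.

    Returns ``{method: {"ok": bool, "terms": {...}, "balance": float}}``;
    a failed balancing-weight solve marks the method not-ok for this
    replicate instead of aborting the study.
    """
    rng = np.random.default_rng(setting.replicate_seed(rep))
    sample = make_dataset(setting.exposure_model, setting.outcome_model, setting.n, setting.trho, rng)
    # the weight models condition on the analyst-specified confounder set
    weight_sample = MixtureSample(
        sample.exposures, sample.covariates[list(setting.weight_covariates)], sample.outcome
    )
    interactions = [("T1", "T3")] if setting.with_interaction else []
    terms = list(TRUE_EFFECTS) + (["T1:T3"] if setting.with_interaction else [])
    out: dict = {}
    for method in setting.methods:
        rec: dict = {"ok": True, "terms": None, "balance": np.nan}
        try:
            if method == "npmvCBGPS":
                w = gps.npmvcbgps_weights(weight_sample).weights
            elif method == "mvGPS":
                w = gps.mvgps_weights(weight_sample)
            else:
                w = None
            if method == "linear":
                fit = MixtureMSM(sample, interactions=interactions, adjust=COVARIATE_NAMES).fit()
                rec["balance"] = balance_report(sample, None, subset=CONFOUNDERS).mean_abs_weighted
            else:
                fit = MixtureMSM(sample, weights=w, interactions=interactions).fit()
                rec["balance"] = balance_report(sample, w, subset=CONFOUNDERS).mean_abs_weighted
            rec["terms"] = _collect_fit(fit, terms)
        except (ELConvergenceError, np.linalg.LinAlgError) as err:
            logger.info("replicate %d, method %s failed: %s", rep, method, err)
            rec["ok"] = False
        out[method] = rec
    return out


# ---------------------------------------------------------------------------
# aggregation
@dataclass
class SimulationResult:
    """Per-method, per-coefficient operating characteristics over replicates."""

    setting: SimulationSetting
    summary: pd.DataFrame  # method, term, truth, bias, rmse, coverage, power, n_reps
    balance: pd.DataFrame  # method, mean_balance, n_reps
    replicates: pd.DataFrame  # audit trail of every estimate
    failures: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Wide table mirroring the usual bias/RMSE presentation."""
        return self.summary.pivot(index=["method"], columns="term", values=["bias", "rmse"])


def summarize(records: list[dict], setting: SimulationSetting) -> SimulationResult:
    """Bias, RMSE, CI coverage and power per method and coefficient."""
    truth = setting.truth
    rows = []
    for rep, rec in enumerate(records):
        for method, r in rec.items():
            if not r["ok"]:
                continue
            for term, v in r["terms"].items():
                rows.append(
                    {
                        "rep": rep,
                        "method": method,
                        "term": term,
                        "est": v["est"],
                        "se": v["se"],
                        "p": v["p"],
                        "ci_low": v["ci_low"],
                        "ci_high": v["ci_high"],
                        "balance": r["balance"],
                    }
                )
    if not rows:
        raise RuntimeError("all replicates failed; nothing to summarize")
    reps_df = pd.DataFrame(rows)
    summary_rows = []
    balance_rows = []
    failures = {}
    for method in setting.methods:
        sub = reps_df[reps_df["method"] == method]
        n_ok = sub["rep"].nunique()
        failures[method] = len(records) - n_ok
        if n_ok == 0:
            continue
        balance_rows.append(
            {"method": method, "mean_balance": sub.groupby("rep")["balance"].first().mean(), "n_reps": n_ok}
        )
        for term, tval in truth.items():
            st = sub[sub["term"] == term]
            est = st["est"].to_numpy()
            summary_rows.append(
                {
                    "method": method,
                    "term": term,
                    "truth": tval,
                    "bias": float(est.mean() - tval),
                    "rmse": float(np.sqrt(np.mean((est - tval) ** 2))),
                    "coverage": float(np.mean((st["ci_low"] <= tval) & (tval <= st["ci_high"]))),
                    "power": float(np.mean(st["p"] < 0.05)),
                    "n_reps": n_ok,
                }
            )
    return SimulationResult(
        setting=setting,
        summary=pd.DataFrame(summary_rows),
        balance=pd.DataFrame(balance_rows),
        replicates=reps_df,
        failures=failures,
    )


def run_simulation(setting: SimulationSetting, progress: bool = False) -> SimulationResult:
    """Run all replicates of one setting and aggregate the metrics."""
    records = []
    for rep in range(setting.reps):
        records.append(run_replicate(setting, rep))
        if progress and (rep + 1) % 50 == 0:
            logger.info("%s n=%d: %d/%d replicates", setting.label, setting.n, rep + 1, setting.reps)
    result = summarize(records, setting)
    for method, nfail in result.failures.items():
        if nfail:
            logger.warning(
                "%s n=%d: %d/%d replicates failed for %s",
                setting.label,
                setting.n,
                nfail,
                setting.reps,
                method,
            )
    return result
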
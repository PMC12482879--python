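"""Tabular container for a mixture analysis: exposures T, covariates X, outcome Y.

A :class:`MixtureSample` is the object every estimator in this package
consumes.  It wraps three aligned pieces of an ``n``-row table: an
``n x m`` block of continuous exposures, an ``n x p`` block of numeric
covariates (binary covariates coded 0/1) and an optional outcome vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MixtureSample", "read_sample", "write_sample"]


class SampleValidationError(ValueError):
    """Raised when a table cannot form a valid MixtureSample."""


@dataclass
class MixtureSample:
    """Exposure/covariate/outcome triple for one analysis.

    Parameters
    ----------
    exposures : DataFrame, n x m
        Continuous exposures (the treatment mixture T).
    covariates : DataFrame, n x p
        Numeric covariates X; binary columns coded 0/1.
    outcome : Series or None
        Outcome Y, required for outcome-model fitting but not for
        weight estimation or balance diagnostics.
    """

    exposures: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        self.exposures = pd.DataFrame(self.exposures).astype(float)
        self.covariates = pd.DataFrame(self.covariates).astype(float)
        if self.outcome is not None:
            self.outcome = pd.Series(self.outcome).astype(float)
        n = len(self.exposures)
        if len(self.covariates) != n or (self.outcome is not None and len(self.outcome) != n):
            raise SampleValidationError("exposures, covariates and outcome must have equal length")
        for name, block in (("exposures", self.exposures), ("covariates", self.covariates)):
            if block.shape[1] == 0:
                raise SampleValidationError(f"{name} must have at least one column")
            if block.isna().any().any():
                bad = sorted(set(block.index[block.isna().any(axis=1)]))
                raise SampleValidationError(f"missing values in {name} at rows {bad[:20]}")
        if self.outcome is not None and self.outcome.isna().any():
            bad = sorted(self.outcome.index[self.outcome.isna()])
            raise SampleValidationError(f"missing values in outcome at rows {bad[:20]}")
        m, p = self.m, self.p
        needed = m * p + m + p + 1
        if n < needed:
            raise SampleValidationError(
                f"need at least m*p+m+p+1 = {needed} rows for the balance constraint system, got {n}"
            )
        var = self.covariates.var(axis=0)
        dead = list(var.index[var <= 0.0])
        if dead:
            raise SampleValidationError(f"covariate columns with zero variance: {dead}")

    # -- basic shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.exposures)

    @property
    def m(self) -> int:
        return self.exposures.shape[1]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return [str(c) for c in self.exposures.columns]

    @property
    def covariate_names(self) -> list[str]:
        return [str(c) for c in self.covariates.columns]

    @property
    def t(self) -> np.ndarray:
        """Exposure matrix as a float ndarray."""
        return self.exposures.to_numpy(float)

    @property
    def x(self) -> np.ndarray:
        """Covariate matrix as a float ndarray."""
        return self.covariates.to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        if self.outcome is None:
            raise SampleValidationError("sample has no outcome column")
        return self.outcome.to_numpy(float)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposures: Sequence[str],
        covariates: Sequence[str],
        outcome: str | None = None,
    ) -> "MixtureSample":
        """Build a sample from a wide table by naming column roles."""
        roles = list(exposures) + list(covariates) + ([outcome] if outcome else [])
        if len(set(roles)) != len(roles):
            raise SampleValidationError("exposure/covariate/outcome column sets must be disjoint")
        missing = [c for c in roles if c not in df.columns]
        if missing:
            raise SampleValidationError(f"columns not found in input: {missing}")
        coerced = df[roles].apply(pd.to_numeric, errors="coerce")
        bad_cells = coerced.isna() & df[roles].notna()
        if bad_cells.any().any():
            cols = list(bad_cells.columns[bad_cells.any()])
            raise SampleValidationError(f"non-numeric cells in columns {cols}")
        return cls(
            exposures=coerced[list(exposures)],
            covariates=coerced[list(covariates)],
            outcome=coerced[outcome] if outcome else None,
        )

    def to_frame(self) -> pd.DataFrame:
        parts = [self.exposures, self.covariates]
        if self.outcome is not None:
            parts.append(self.outcome.rename(self.outcome.name or "Y"))
        return pd.concat(parts, axis=1)


def read_sample(
    path: str | Path,
    exposures: Sequence[str],
    covariates: Sequence[str],
    outcome: str | None = None,
) -> MixtureSample:
    """Read a delimited text file (header required) into a MixtureSample.

    Rows with any missing value in a mapped column are rejected with a
    row-indexed report rather than silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SampleValidationError(f"{path}: empty input file")
    roles = list(exposures) + list(covariates) + ([outcome] if outcome else [])
    missing = [c for c in roles if c not in df.columns]
    if missing:
        raise SampleValidationError(f"{path}: columns not found: {missing}")
    na_rows = df[roles].isna().any(axis=1)
    if na_rows.any():
        idx = [int(i) + 1 for i in df.index[na_rows]]  # 1-based data rows
        raise SampleValidationError(f"{path}: rows with missing values (1-based, excluding header): {idx[:50]}")
    return MixtureSample.from_dataframe(df, exposures, covariates, outcome)


def write_sample(sample: MixtureSample, path: str | Path) -> None:
    """Write a sample back to CSV (numeric payload round-trips via repr precision)."""
    sample.to_frame().to_csv(path, index=False, float_format="%.17g")
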
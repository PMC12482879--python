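"""Deterministic on-disk fixtures wrapping the simulation DGPs.

``make_fixture`` writes a CSV a user could feed back through the CLI, plus
a sidecar JSON of the true generating parameters for the study kinds.  The
``pfas_like`` kind is a synthetic stand-in mirroring the dimensionality of
a serum-chemical application (four log-scale exposures, eight mixed
covariates, one continuous outcome); it shares no numbers with any real
survey data.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulation as sim

__all__ = ["make_fixture", "FIXTURE_KINDS"]

_DGP_KINDS = [e + y for e in ("E1", "E2") for y in ("Y1", "Y2", "Y3", "Y4")]
FIXTURE_KINDS = _DGP_KINDS + ["pfas_like"]


def _pfas_like(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic four-exposure/eight-covariate table on a log-normal exposure scale."""
    age = rng.normal(47.0, 16.0, n).clip(20.0, 85.0)
    sex = rng.binomial(1, 0.5, n).astype(float)
    smoker = rng.binomial(1, 0.2, n).astype(float)
    educ = rng.integers(1, 6, n).astype(float)
    married = rng.binomial(1, 0.55, n).astype(float)
    pir = rng.gamma(2.5, 1.0, n).clip(0.05, 5.0)
    energy = rng.normal(2100.0, 600.0, n).clip(600.0, 5500.0)
    race = rng.integers(1, 5, n).astype(float)
    X = np.column_stack([age, sex, race, educ, married, smoker, pir, energy])
    xs = np.column_stack(
        [
            (age - 47.0) / 16.0,
            sex - 0.5,
            smoker - 0.2,
            (pir - 2.5) / 1.5,
            (energy - 2100.0) / 600.0,
        ]
    )
    loadings = np.array(
        [
            [0.25, 0.30, 0.10, 0.05, 0.02],
            [0.30, 0.35, 0.12, 0.03, 0.03],
            [0.20, 0.40, 0.08, 0.06, 0.01],
            [0.22, 0.25, 0.15, 0.04, 0.02],
        ]
    )
    corr = np.full((4, 4), 0.5)
    np.fill_diagonal(corr, 1.0)
    log_t = xs @ loadings.T + rng.multivariate_normal(np.zeros(4), 0.35 * corr, size=n, method="cholesky")
    exposures = np.exp(log_t)  # log-normal scale concentrations
    effects = np.array([0.1, -0.4, -0.25, 0.3])
    bmi = (
        27.0
        + log_t @ effects
        + 0.04 * (age - 47.0)
        - 0.8 * sex
        + 0.5 * smoker
        - 0.3 * (pir - 2.5)
        + rng.normal(0.0, 4.0, n)
    )
    cols = {f"PFAS{i + 1}": exposures[:, i] for i in range(4)}
    for name, col in zip(
        ["age", "sex", "race", "educ", "married", "smoker", "pir", "energy"], X.T
    ):
        cols[name] = col
    cols["BMI"] = bmi
    return pd.DataFrame(cols)


def make_fixture(kind: str, n: int, seed: int, path: str | Path) -> Path:
    """Write a deterministic fixture CSV; DGP kinds get a truth JSON sidecar."""
    path = Path(path)
    rng = np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(kind.encode()), n)))
    if kind in _DGP_KINDS:
        sample = sim.make_dataset(kind[:2], kind[2:], n, trho=0.2, rng=rng)
        df = sample.to_frame()
        truth = {
            "exposure_effects": sim.TRUE_EFFECTS,
            "interaction_effect": sim.INTERACTION_EFFECT if kind[2:] in ("Y2", "Y4") else 0.0,
            "exposure_model": kind[:2],
            "outcome_model": kind[2:],
            "trho": 0.2,
            "confounders": sim.CONFOUNDERS,
        }
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True))
    elif kind == "pfas_like":
        df = _pfas_like(n, rng)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    df.to_csv(path, index=False, float_format="%.12g")
    return path
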
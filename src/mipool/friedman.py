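"""Benchmark data generator based on the Friedman regression function.

The generating model used throughout the simulation machinery is

    f(x) = 10 sin(pi * x1 * x2) + 20 (x3 - 0.5)^2 + 10 x4 + 5 x5 + 0 x6

with six covariates drawn independently from Uniform(0, 1).  For a normal
outcome, y = f(x) + eps with eps ~ N(0, 9).  For a binary outcome the
(optionally noisy) signal is standardized across the dataset, passed through
an inverse-logit link, and fed into a Bernoulli draw, so the log-odds of
success follow the same functional form.

x1..x5 carry true signal of varying strength and shape (trigonometric,
U-shaped quadratic, linear); x6 has a coefficient of exactly zero and serves
as the type-I-error ("null") covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATE_NAMES",
    "OUTCOME_NAME",
    "FriedmanConfig",
    "SimulatedDataset",
    "friedman_mean",
    "simulate",
    "simulate_normal",
    "simulate_binary",
]

COVARIATE_NAMES: tuple[str, ...] = ("x1", "x2", "x3", "x4", "x5", "x6")
OUTCOME_NAME = "y"

#: truth tag per covariate: x1..x5 carry signal, x6 is null.
DEFAULT_TRUTH_TAGS: tuple[str, ...] = ("signal",) * 5 + ("null",)


@dataclass(frozen=True)
class FriedmanConfig:
    """Configuration of one simulated benchmark dataset.

    Parameters
    ----------
    n_rows : int
        Number of rows (>= 1).
    outcome_kind : {"normal", "binary"}
        Distribution of the outcome.
    noise_sd : float
        Standard deviation of the additive gaussian noise (default 3.0,
        i.e. variance 9).
    seed : int
        Root seed for the dataset; covariates are drawn column by column
        x1 -> x6 before the noise, so datasets are bit-reproducible.
    binary_include_noise : bool
        Whether the binary generator adds the gaussian noise to the signal
        before standardizing (default True).
    """

    n_rows: int
    outcome_kind: str = "normal"
    noise_sd: float = 3.0
    seed: int = 0
    binary_include_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.outcome_kind not in ("normal", "binary"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class SimulatedDataset:
    """A complete rectangle of six uniform covariates plus an outcome."""

    covariates: np.ndarray  # (n_rows, 6), entries in [0, 1]
    outcome: np.ndarray  # (n_rows,)
    outcome_kind: str = "normal"
    truth_tags: tuple[str, ...] = DEFAULT_TRUTH_TAGS
    config: FriedmanConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.covariates.ndim != 2 or self.covariates.shape[1] != 6:
            raise ValueError("covariates must be an (n_rows, 6) matrix")
        if self.outcome.shape != (self.covariates.shape[0],):
            raise ValueError("outcome length must match covariate rows")
        if np.any(self.covariates < 0) or np.any(self.covariates > 1):
            raise ValueError("covariate entries must lie in [0, 1]")
        if self.outcome_kind == "binary" and not np.isin(self.outcome, (0.0, 1.0)).all():
            raise ValueError("binary outcome entries must be exactly 0 or 1")

    @property
    def n_rows(self) -> int:
        return self.covariates.shape[0]

    @property
    def frame(self) -> pd.DataFrame:
        """The dataset as a DataFrame with columns x1..x6, y."""
        df = pd.DataFrame(self.covariates, columns=list(COVARIATE_NAMES))
        df[OUTCOME_NAME] = self.outcome
        return df

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, outcome_kind: str = "normal") -> "SimulatedDataset":
        cols = list(COVARIATE_NAMES) + [OUTCOME_NAME]
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks columns {missing}")
        return cls(
            covariates=frame[list(COVARIATE_NAMES)].to_numpy(dtype=float),
            outcome=frame[OUTCOME_NAME].to_numpy(dtype=float),
            outcome_kind=outcome_kind,
        )

    @classmethod
    def from_csv(cls, path, outcome_kind: str = "normal") -> "SimulatedDataset":
        return cls.from_frame(pd.read_csv(path), outcome_kind=outcome_kind)


def friedman_mean(x_row: Sequence[float]) -> float:
    """Deterministic mean function f(x) evaluated at one covariate row.

    x6 contributes exactly zero.  Inputs outside [0, 1] or of wrong length
    are rejected.
    """
    x = np.asarray(x_row, dtype=float)
    if x.shape != (6,):
        raise ValueError(f"expected a length-6 row, got shape {x.shape}")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("covariate entries must lie in [0, 1]")
    return float(_mean_matrix(x[None, :])[0])


def _mean_matrix(X: np.ndarray) -> np.ndarray:
    """Vectorized f(x) over an (n, 6) matrix."""
    return (
        10.0 * np.sin(X[:, 0] * X[:, 1] * np.pi)
        + 20.0 * (X[:, 2] - 0.5) ** 2
        + 10.0 * X[:, 3]
        + 5.0 * X[:, 4]
        + 0.0 * X[:, 5]
    )


def _draw_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    # column-major order x1 -> x6 so the draw sequence is part of the contract
    X = np.empty((n, 6))
    for j in range(6):
        X[:, j] = rng.uniform(0.0, 1.0, size=n)
    return X


def simulate_normal(config: FriedmanConfig) -> SimulatedDataset:
    """Simulate a normal-outcome dataset: y = f(x) + N(0, noise_sd^2)."""
    if config.outcome_kind != "normal":
        raise ValueError("simulate_normal requires outcome_kind='normal'")
    rng = np.random.default_rng(config.seed)
    X = _draw_covariates(rng, config.n_rows)
    eps = rng.normal(0.0, config.noise_sd, size=config.n_rows)
    y = _mean_matrix(X) + eps
    return SimulatedDataset(X, y, outcome_kind="normal", config=config)


def simulate_binary(config: FriedmanConfig) -> SimulatedDataset:
    """Simulate a binary-outcome dataset.

    The per-row signal s_i = f(x_i) (+ eps_i if ``binary_include_noise``) is
    standardized within the dataset, mapped through the inverse logit to a
    probability, and used in a Bernoulli draw.  The empirical standardization
    keeps the average event rate near 0.5.
    """
    if config.outcome_kind != "binary":
        raise ValueError("simulate_binary requires outcome_kind='binary'")
    rng = np.random.default_rng(config.seed)
    X = _draw_covariates(rng, config.n_rows)
    s = _mean_matrix(X)
    if config.binary_include_noise:
        s = s + rng.normal(0.0, config.noise_sd, size=config.n_rows)
    sd = float(np.std(s, ddof=1)) if config.n_rows > 1 else 0.0
    if not np.isfinite(sd) or sd <= 0.0:
        raise ValueError(
            "degenerate standardization: signal has zero variance "
            f"(n_rows={config.n_rows})"
        )
    z = (s - s.mean()) / sd
    p = 1.0 / (1.0 + np.exp(-z))
    y = (rng.uniform(size=config.n_rows) < p).astype(float)
    return SimulatedDataset(X, y, outcome_kind="binary", config=config)


def simulate(config: FriedmanConfig) -> SimulatedDataset:
    """Dispatch on ``config.outcome_kind``."""
    if config.outcome_kind == "normal":
        return simulate_normal(config)
    return simulate_binary(config)
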
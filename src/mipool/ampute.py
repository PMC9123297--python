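"""Multivariate amputation: impose MCAR / MAR / MNAR missingness.

Implements the weighted-sum-score amputation procedure commonly used to
generate realistic missingness in simulation studies.  Each row is assigned
to a candidate *pattern* (a subset of columns to blank out); whether the row
is actually amputed is decided

* uniformly at random (MCAR), or
* by a right-tailed logistic function of a weighted sum of the row's
  standardized column values (MAR: weights only on columns the pattern keeps
  observed; MNAR: weights on the columns the pattern removes),

with the logistic intercept solved numerically so that the expected
incomplete-row fraction equals the requested target (default 0.35, leaving
roughly 65% of rows fully observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .friedman import COVARIATE_NAMES, OUTCOME_NAME, SimulatedDataset

__all__ = [
    "ALL_COLUMNS",
    "MissingnessSpec",
    "AmputedDataset",
    "ampute",
    "incomplete_fraction",
    "listwise_delete",
]

logger = logging.getLogger(__name__)

ALL_COLUMNS: tuple[str, ...] = COVARIATE_NAMES + (OUTCOME_NAME,)
_N_COLS = len(ALL_COLUMNS)


def _default_patterns() -> np.ndarray:
    # one variable amputed per pattern, over x1..x6 and y
    return np.eye(_N_COLS, dtype=int)


@dataclass
class MissingnessSpec:
    """Configuration of the amputation procedure.

    Attributes
    ----------
    mechanism : {"MCAR", "MAR", "MNAR"}
    target_incomplete_prop : float
        Expected fraction of rows left with at least one missing cell;
        in [0, 1) (0 is the no-missingness limit), default 0.35.
    patterns : (P, 7) 0/1 array
        Row p has 1 in the columns amputed under pattern p (column order
        x1..x6, y).  Default: one pattern per column.
    pattern_freqs : (P,) simplex weights
        Probability of assigning a row to each pattern; default uniform.
    weight_matrix : (P, 7) array or None
        Weights forming the per-pattern sum scores on standardized columns.
        Ignored under MCAR.  Default: MAR weights 1 on observed columns,
        MNAR weights 1 on amputed columns.
    seed : int
    """

    mechanism: str = "MAR"
    target_incomplete_prop: float = 0.35
    patterns: np.ndarray | None = None
    pattern_freqs: np.ndarray | None = None
    weight_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.target_incomplete_prop < 1.0):
            raise ValueError(
                "target_incomplete_prop must lie in [0, 1); got "
                f"{self.target_incomplete_prop}"
            )
        if self.patterns is None:
            self.patterns = _default_patterns()
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=int))
        if self.patterns.shape[0] == 0:
            raise ValueError("pattern list must be non-empty")
        if self.patterns.shape[1] != _N_COLS:
            raise ValueError(f"patterns must have {_N_COLS} columns (x1..x6, y)")
        if not np.isin(self.patterns, (0, 1)).all():
            raise ValueError("patterns must be 0/1")
        if self.patterns.sum(axis=1).min() == 0:
            raise ValueError("every pattern must ampute at least one column")
        P = self.patterns.shape[0]
        if self.pattern_freqs is None:
            self.pattern_freqs = np.full(P, 1.0 / P)
        self.pattern_freqs = np.asarray(self.pattern_freqs, dtype=float)
        if self.pattern_freqs.shape != (P,) or np.any(self.pattern_freqs < 0):
            raise ValueError("pattern_freqs must be nonnegative, one per pattern")
        if abs(self.pattern_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("pattern_freqs must sum to 1")
        if self.weight_matrix is None:
            if self.mechanism == "MNAR":
                self.weight_matrix = self.patterns.astype(float)
            else:  # MAR default; unused under MCAR
                self.weight_matrix = 1.0 - self.patterns.astype(float)
        self.weight_matrix = np.asarray(self.weight_matrix, dtype=float)
        if self.weight_matrix.shape != self.patterns.shape:
            raise ValueError("weight_matrix must match patterns in shape")
        if self.mechanism == "MAR":
            bad = (self.patterns == 1) & (self.weight_matrix != 0.0)
            if bad.any():
                raise ValueError(
                    "MAR requires zero weight on columns amputed by the pattern"
                )


@dataclass
class AmputedDataset:
    """A dataset rectangle with a missingness mask imposed on it."""

    frame: pd.DataFrame  # (n, 7) with NaN at masked cells
    mask: np.ndarray  # (n, 7) bool, True = missing
    source: SimulatedDataset | None = field(default=None, repr=False)
    spec: MissingnessSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.frame.shape:
            raise ValueError("mask shape must match the data rectangle")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean indicator of rows with no masked cell."""
        return ~self.mask.any(axis=1)

    def to_csv(self, path) -> None:
        """Write CSV with empty cells for missing values."""
        self.frame.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "AmputedDataset":
        frame = pd.read_csv(path)
        return cls(frame=frame, mask=frame.isna().to_numpy())


def ampute(dataset: SimulatedDataset, spec: MissingnessSpec) -> AmputedDataset:
    """Impose the missingness described by ``spec`` on a complete dataset."""
    rng = np.random.default_rng(spec.seed)
    frame = dataset.frame
    values = frame.to_numpy(dtype=float)
    n = values.shape[0]
    prop = spec.target_incomplete_prop

    mask = np.zeros((n, _N_COLS), dtype=bool)
    if prop == 0.0 or n == 0:
        return AmputedDataset(frame=frame.copy(), mask=mask, source=dataset, spec=spec)

    pattern_of_row = rng.choice(spec.patterns.shape[0], size=n, p=spec.pattern_freqs)

    if spec.mechanism == "MCAR":
        amputed = rng.uniform(size=n) < prop
    else:
        # standardized columns keep the weights scale-free
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        Z = (values - values.mean(axis=0)) / sd
        amputed = np.zeros(n, dtype=bool)
        for p_idx in range(spec.patterns.shape[0]):
            rows = np.flatnonzero(pattern_of_row == p_idx)
            if rows.size == 0:
                continue
            scores = Z[rows] @ spec.weight_matrix[p_idx]
            shift = _solve_logistic_shift(scores, prop)
            probs = expit(scores + shift)
            amputed[rows] = rng.uniform(size=rows.size) < probs

    for p_idx in range(spec.patterns.shape[0]):
        cols = spec.patterns[p_idx] == 1
        rows = amputed & (pattern_of_row == p_idx)
        mask[np.ix_(rows, cols)] = True

    out = frame.copy()
    out_values = out.to_numpy(dtype=float)
    out_values[mask] = np.nan
    out = pd.DataFrame(out_values, columns=frame.columns)
    return AmputedDataset(frame=out, mask=mask, source=dataset, spec=spec)


def _solve_logistic_shift(scores: np.ndarray, prop: float) -> float:
    """Intercept c with mean(expit(scores + c)) == prop over the group."""
    if np.allclose(scores, scores[0]):
        # constant scores (e.g. all weights zero) degenerate to MCAR
        return float(np.log(prop / (1.0 - prop)) - scores[0])

    def gap(c: float) -> float:
        return float(expit(scores + c).mean() - prop)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def incomplete_fraction(amputed: AmputedDataset) -> float:
    """Fraction of rows with at least one masked cell."""
    if amputed.n_rows == 0:
        return 0.0
    return float(amputed.mask.any(axis=1).mean())


def listwise_delete(amputed: AmputedDataset) -> pd.DataFrame:
    """Return only fully observed rows, order preserved.

    Raises ``ValueError`` when no complete rows remain (complete-case
    analysis impossible).
    """
    keep = amputed.complete_rows
    if not keep.any():
        raise ValueError("listwise deletion removed every row; no complete cases")
    return amputed.frame.loc[keep].reset_index(drop=True)
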
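"""Pooling rules for significance tests after multiple imputation.

Given the m per-imputation test results for one covariate (p-values p_1..p_m,
test statistics d_1..d_m, and per-imputation parameter counts k_1..k_m —
effective degrees of freedom for penalized smooths, basis df for B-splines),
these rules each produce a single pooled p-value:

* MPV — the median p-value across imputations.
* mean p-value — the arithmetic mean (same idea, different central tendency).
* Cauchy combination — t0 = sum_i tan{(0.5 - p_i) pi} referred to a standard
  Cauchy distribution, pooled p = 1/2 - arctan(t0)/pi.
* D2 — the mean statistic divided by the mean parameter count, recentred by
  the between-imputation variance of sqrt(d_i) and referred to an
  F(kbar, nu2) distribution.
* Alt. D2 — identical except the centre is the mean of the per-imputation
  quotients d_i / k_i (resolves the ambiguity of a non-constant parameter
  count across imputations the other way).
* single imputation — the first chain's p-value, no pooling at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputationTestSet",
    "PooledResult",
    "mpv",
    "mean_pvalue",
    "cauchy_combine",
    "d2_pool",
    "alt_d2_pool",
    "single_imputation",
    "pool_all",
    "POOLING_METHODS",
]

logger = logging.getLogger(__name__)

_CLAMP = 1e-15  # boundary clamp for the Cauchy tangent transform

POOLING_METHODS = ("mpv", "mean_p", "cauchy", "d2", "alt_d2", "single")


@dataclass(frozen=True)
class ImputationTestSet:
    """Per-imputation test results for one covariate."""

    p_values: np.ndarray
    statistics: np.ndarray | None = None
    param_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_values, dtype=float))
        object.__setattr__(self, "p_values", p)
        if p.size == 0:
            raise ValueError("p_values must be non-empty")
        if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
            raise ValueError("p-values must lie in [0, 1]")
        for name in ("statistics", "param_counts"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_1d(np.asarray(v, dtype=float))
                object.__setattr__(self, name, v)
                if v.shape != p.shape:
                    raise ValueError(f"{name} must have the same length as p_values")
        if self.statistics is not None and np.any(self.statistics < 0):
            raise ValueError("statistics must be nonnegative")
        if self.param_counts is not None and np.any(self.param_counts <= 0):
            raise ValueError("param_counts must be positive")

    @property
    def m(self) -> int:
        return self.p_values.size


@dataclass(frozen=True)
class PooledResult:
    method: str
    pooled_p: float
    pooled_statistic: float | None = None
    reference_df: tuple[float, float] | None = None


def mpv(tests: ImputationTestSet) -> PooledResult:
    """Median p-value rule; even m uses the mean of the two central values."""
    return PooledResult("mpv", float(np.median(tests.p_values)))


def mean_pvalue(tests: ImputationTestSet) -> PooledResult:
    """Arithmetic-mean p-value rule."""
    return PooledResult("mean_p", float(np.mean(tests.p_values)))


def cauchy_combine(tests: ImputationTestSet) -> PooledResult:
    """Cauchy combination test.

    t0 = sum_i tan{(0.5 - p_i) pi}; pooled p = 1/2 - arctan(t0)/pi, the
    survival function of a standard Cauchy variate at t0.  p-values exactly
    at 0 or 1 are clamped to avoid infinite tangents.
    """
    p = tests.p_values
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        logger.warning("cauchy_combine: boundary p-value clamped to [%g, 1-%g]", _CLAMP, _CLAMP)
        p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    t0 = float(np.sum(np.tan((0.5 - p) * np.pi)))
    pooled = 0.5 - np.arctan(t0) / np.pi
    return PooledResult("cauchy", float(np.clip(pooled, 0.0, 1.0)), pooled_statistic=t0)


def _d2_core(tests: ImputationTestSet, center: float, method: str) -> PooledResult:
    d = tests.statistics
    k = tests.param_counts
    m = tests.m
    kbar = float(np.mean(k))
    r2 = (1.0 + 1.0 / m) * float(np.var(np.sqrt(d), ddof=1))
    if r2 <= 0.0:
        # all statistics identical: nu2 -> infinity, F(kbar, inf) = chi2(kbar)/kbar
        logger.info("%s: zero between-imputation variance; chi-square limit used", method)
        stat = max(center, 0.0)
        pooled = float(stats.chi2.sf(stat * kbar, kbar))
        return PooledResult(method, pooled, pooled_statistic=stat, reference_df=(kbar, np.inf))
    stat = (center - ((m + 1.0) / (m - 1.0)) * r2) / (1.0 + r2)
    stat = max(stat, 0.0)  # negative centres give pooled p = 1
    nu2 = kbar ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r2) ** 2
    pooled = float(stats.f.sf(stat, kbar, nu2))
    return PooledResult(method, pooled, pooled_statistic=stat, reference_df=(kbar, nu2))


def _require_d2_inputs(tests: ImputationTestSet, method: str) -> None:
    if tests.statistics is None or tests.param_counts is None:
        raise ValueError(f"{method} requires statistics and param_counts")
    if tests.m < 2:
        raise ValueError(
            f"{method} needs m >= 2 (a between-imputation variance); "
            "use single_imputation for m = 1"
        )


def d2_pool(tests: ImputationTestSet) -> PooledResult:
    """D2 rule: centre = mean(statistics) / mean(param_counts)."""
    _require_d2_inputs(tests, "d2_pool")
    center = float(np.mean(tests.statistics) / np.mean(tests.param_counts))
    return _d2_core(tests, center, "d2")


def alt_d2_pool(tests: ImputationTestSet) -> PooledResult:
    """Alternative D2 rule: centre = mean(statistics / param_counts)."""
    _require_d2_inputs(tests, "alt_d2_pool")
    center = float(np.mean(tests.statistics / tests.param_counts))
    return _d2_core(tests, center, "alt_d2")


def single_imputation(tests: ImputationTestSet) -> PooledResult:
    """First-chain p-value; the chain order is fixed by the seeding scheme."""
    return PooledResult("single", float(tests.p_values[0]))


_DISPATCH = {
    "mpv": mpv,
    "mean_p": mean_pvalue,
    "cauchy": cauchy_combine,
    "d2": d2_pool,
    "alt_d2": alt_d2_pool,
    "single": single_imputation,
}


def pool_all(tests: ImputationTestSet, methods=POOLING_METHODS) -> dict[str, PooledResult]:
    """Apply each requested pooling rule; m = 1 skips the D2 variants."""
    out: dict[str, PooledResult] = {}
    for name in methods:
        if name in ("d2", "alt_d2") and tests.m < 2:
            continue
        out[name] = _DISPATCH[name](tests)
    return out


def report_table(per_covariate: dict[str, ImputationTestSet],
                 methods=POOLING_METHODS) -> pd.DataFrame:
    """Pooled-p table: rows = covariates, columns = pooling methods."""
    rows = {}
    for cov, tests in per_covariate.items():
        pooled = pool_all(tests, methods)
        rows[cov] = {name: res.pooled_p for name, res in pooled.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
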
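"""Monte-Carlo harness: the full simulate → ampute → impute → fit → pool study.

One *replicate* executes the whole pipeline on one simulated dataset:

1. simulate a Friedman dataset (normal or binary outcome);
2. fit the smooth model on the full data (gold-standard benchmark);
3. ampute at the target rate under the configured mechanism;
4. fit on the listwise-deleted data (complete-case benchmark);
5. multiply impute with chained equations (PMM or RF), m chains;
6. fit the smooth model on each completed dataset;
7. pool the per-imputation tests with every pooling rule;
8. compare every p-value to the significance level.

A *scenario* aggregates S replicates into a rejection-proportion table per
covariate and method: the x6 row estimates the type-I error (its true
effect is zero), the x1..x5 rows estimate power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ampute import MissingnessSpec, ampute, listwise_delete
from .friedman import COVARIATE_NAMES, FriedmanConfig, simulate
from .impute import ImputationConfig, mice
from .pool import ImputationTestSet, pool_all
from .smooth import SmoothModelConfig, smooth_tests

__all__ = [
    "METHODS",
    "ScenarioConfig",
    "RejectionTable",
    "run_replicate",
    "run_scenario",
    "sweep_imputations",
]

logger = logging.getLogger(__name__)

#: columns of the per-replicate p-value record
METHODS = (
    "full_data",
    "complete_case",
    "mpv",
    "mean_p",
    "cauchy",
    "d2",
    "alt_d2",
    "single",
)

_MAX_FAILED_FRACTION = 0.05


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulation scenario (desk-scale defaults)."""

    outcome_kind: str = "normal"
    mechanism: str = "MAR"
    imputation_method: str = "PMM"
    model_kind: str = "penalized_gam"
    fit_method: str = "ML"
    S: int = 500
    n_rows: int = 250
    m: int = 25
    alpha: float = 0.05
    seed: int = 0
    n_workers: int = 1
    target_incomplete_prop: float = 0.35
    noise_sd: float = 3.0
    n_cycles: int = 5
    donor_count: int = 5
    n_trees: int = 10

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def at_paper_scale(self) -> "ScenarioConfig":
        """The study-scale variant: S = 10,000 replicates, m = 25."""
        return replace(self, S=10_000, m=25)

    @property
    def smooth_config(self) -> SmoothModelConfig:
        family = "gaussian_identity" if self.outcome_kind == "normal" else "binomial_logit"
        return SmoothModelConfig(
            family=family, model_kind=self.model_kind, fit_method=self.fit_method
        )


@dataclass
class RejectionTable:
    """Long-format rejection proportions with binomial Monte-Carlo SEs."""

    frame: pd.DataFrame  # columns: covariate, method, n, rejections, proportion, se
    alpha: float
    n_failed: int = 0

    def proportion(self, covariate: str, method: str) -> float:
        sel = self.frame[
            (self.frame.covariate == covariate) & (self.frame.method == method)
        ]
        return float(sel.proportion.iloc[0])

    def se(self, covariate: str, method: str) -> float:
        sel = self.frame[
            (self.frame.covariate == covariate) & (self.frame.method == method)
        ]
        return float(sel.se.iloc[0])

    def pivot(self) -> pd.DataFrame:
        return self.frame.pivot(index="covariate", columns="method", values="proportion")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _replicate_parts(config: ScenarioConfig, replicate_seed: int):
    """Full pipeline for one replicate; returns (full, cc, per-imputation tests)."""
    ss = np.random.SeedSequence(replicate_seed)
    sim_ss, amp_ss, imp_ss = ss.spawn(3)
    smooth_cfg = config.smooth_config

    sim = simulate(
        FriedmanConfig(
            n_rows=config.n_rows,
            outcome_kind=config.outcome_kind,
            noise_sd=config.noise_sd,
            seed=_seed_int(sim_ss),
        )
    )
    full_tests = smooth_tests(sim.frame, smooth_cfg)

    spec = MissingnessSpec(
        mechanism=config.mechanism,
        target_incomplete_prop=config.target_incomplete_prop,
        seed=_seed_int(amp_ss),
    )
    amputed = ampute(sim, spec)
    cc_tests = smooth_tests(listwise_delete(amputed), smooth_cfg)

    if config.target_incomplete_prop == 0.0:
        # no-missingness degeneracy: every "imputation" is the full data
        imp_tests = [full_tests] * config.m
    else:
        stack = mice(
            amputed,
            ImputationConfig(
                method=config.imputation_method,
                m=config.m,
                n_cycles=config.n_cycles,
                donor_count=config.donor_count,
                n_trees=config.n_trees,
                seed=_seed_int(imp_ss),
            ),
        )
        imp_tests = [smooth_tests(df, smooth_cfg) for df in stack.completed]
    return full_tests, cc_tests, imp_tests


def _pool_record(full_tests, cc_tests, imp_tests, m: int | None = None) -> pd.DataFrame:
    """Per-covariate p-value record (rows = covariates, columns = METHODS)."""
    use = imp_tests if m is None else imp_tests[:m]
    out = pd.DataFrame(index=list(COVARIATE_NAMES), columns=list(METHODS), dtype=float)
    for cov in COVARIATE_NAMES:
        out.loc[cov, "full_data"] = full_tests.record(cov).p_value
        out.loc[cov, "complete_case"] = cc_tests.record(cov).p_value
        recs = [t.record(cov) for t in use]
        tests = ImputationTestSet(
            p_values=[r.p_value for r in recs],
            statistics=[r.statistic for r in recs],
            param_counts=[max(r.df, 1e-8) for r in recs],
        )
        for name, res in pool_all(tests).items():
            out.loc[cov, name] = res.pooled_p
    return out


def run_replicate(config: ScenarioConfig, replicate_seed: int) -> pd.DataFrame:
    """One replicate's per-covariate, per-method p-values."""
    full_tests, cc_tests, imp_tests = _replicate_parts(config, replicate_seed)
    return _pool_record(full_tests, cc_tests, imp_tests)


def _replicate_safe(config, replicate_seed, m_grid=None):
    try:
        if m_grid is None:
            return run_replicate(config, replicate_seed)
        full_tests, cc_tests, imp_tests = _replicate_parts(config, replicate_seed)
        return {m: _pool_record(full_tests, cc_tests, imp_tests, m=m) for m in m_grid}
    except Exception as exc:  # skip-and-count failure policy
        logger.warning("replicate seed %d failed: %s", replicate_seed, exc)
        return exc


def _replicate_seeds(config: ScenarioConfig) -> list[int]:
    root = np.random.SeedSequence(config.seed)
    return [_seed_int(ss) for ss in root.spawn(config.S)]


def _run_all(config: ScenarioConfig, m_grid=None) -> list:
    seeds = _replicate_seeds(config)
    if config.n_workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.n_workers)(
            delayed(_replicate_safe)(config, s, m_grid) for s in seeds
        )
    else:
        results = [_replicate_safe(config, s, m_grid) for s in seeds]
    failures = [r for r in results if isinstance(r, Exception)]
    if len(failures) > _MAX_FAILED_FRACTION * config.S:
        raise RuntimeError(
            f"{len(failures)}/{config.S} replicates failed (> "
            f"{_MAX_FAILED_FRACTION:.0%} threshold); first error: {failures[0]}"
        )
    if failures:
        logger.warning("%d/%d replicates failed and were skipped", len(failures), config.S)
    return results


def _aggregate(records: list[pd.DataFrame], alpha: float, n_failed: int) -> RejectionTable:
    rows = []
    for cov in COVARIATE_NAMES:
        for method in METHODS:
            p = np.array([rec.loc[cov, method] for rec in records], dtype=float)
            p = p[~np.isnan(p)]
            n = len(p)
            rej = int(np.sum(p < alpha))
            prop = rej / n if n else np.nan
            se = float(np.sqrt(prop * (1 - prop) / n)) if n else np.nan
            rows.append(
                {"covariate": cov, "method": method, "n": n,
                 "rejections": rej, "proportion": prop, "se": se}
            )
    return RejectionTable(pd.DataFrame(rows), alpha=alpha, n_failed=n_failed)


def run_scenario(config: ScenarioConfig) -> RejectionTable:
    """Aggregate S replicates into a rejection-proportion table.

    The root seed fully determines the table regardless of ``n_workers``.
    """
    results = _run_all(config)
    records = [r for r in results if not isinstance(r, Exception)]
    return _aggregate(records, config.alpha, n_failed=len(results) - len(records))


def sweep_imputations(config: ScenarioConfig, m_grid) -> dict[int, RejectionTable]:
    """Rejection tables for each number of imputations in ``m_grid``.

    A single set of max(m_grid) chains is imputed per replicate and pooled
    over prefixes of length m, so the curves are comparable within
    replicate.  The m = 1 point coincides with single imputation by
    construction.
    """
    m_grid = sorted(set(int(m) for m in m_grid))
    if any(m < 1 for m in m_grid):
        raise ValueError("m_grid entries must be positive")
    config = replace(config, m=max(m_grid))
    results = _run_all(config, m_grid=m_grid)
    ok = [r for r in results if not isinstance(r, Exception)]
    n_failed = len(results) - len(ok)
    return {
        m: _aggregate([r[m] for r in ok], config.alpha, n_failed) for m in m_grid
    }
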
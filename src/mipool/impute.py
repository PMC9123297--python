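"""Multiple imputation by chained equations (MICE) with PMM and RF imputers.

Each of the m chains starts from a simple random fill (draws from each
column's observed values) and then sweeps left-to-right over the columns
with missingness for a fixed number of cycles, re-imputing each column
conditional on the current completed values of all the others.

Two column imputers are provided:

* predictive mean matching (PMM, type-1): a linear regression of the target
  on the other columns is fit on observed rows; predictions for missing rows
  use a stochastic draw of the coefficients from their sampling distribution
  while donor predictions use the least-squares fit; each missing row copies
  the observed value of one of its `donor_count` nearest-prediction donors.
* random forest (RF): a bootstrap forest is grown on the observed rows
  (regression trees for numeric targets, classification trees for binary
  ones); each missing row pools the observed values sitting in the terminal
  node it reaches in every tree and draws one uniformly.

Both imputers only ever copy observed values, so imputations stay inside the
observed support of each column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .ampute import AmputedDataset

__all__ = [
    "ImputationConfig",
    "ImputedStack",
    "initial_fill",
    "pmm_impute_column",
    "rf_impute_column",
    "mice",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings (defaults mirror common MICE software)."""

    method: str = "PMM"  # or "RF"
    m: int = 25
    n_cycles: int = 5
    donor_count: int = 5  # PMM only
    n_trees: int = 10  # RF only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("PMM", "RF"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.m < 1 or self.n_cycles < 1 or self.donor_count < 1 or self.n_trees < 1:
            raise ValueError("m, n_cycles, donor_count and n_trees must be >= 1")


@dataclass
class ImputedStack:
    """m completed copies of an amputed dataset."""

    completed: list[pd.DataFrame]
    config: ImputationConfig
    provenance: AmputedDataset = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.completed)

    def to_directory(self, path) -> None:
        """Serialize as m CSV files plus a JSON manifest."""
        import hashlib
        import json
        from pathlib import Path

        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.completed):
            df.to_csv(d / f"imputation_{i + 1:03d}.csv", index=False)
        src_csv = self.provenance.frame.to_csv(index=False)
        manifest = {
            "method": self.config.method,
            "m": self.config.m,
            "n_cycles": self.config.n_cycles,
            "donor_count": self.config.donor_count,
            "n_trees": self.config.n_trees,
            "seed": self.config.seed,
            "provenance_sha1": hashlib.sha1(src_csv.encode()).hexdigest(),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def initial_fill(amputed: AmputedDataset, seed) -> pd.DataFrame:
    """Fill each missing cell with a uniform draw from its column's observed values."""
    rng = np.random.default_rng(seed)
    return _initial_fill_rng(amputed.frame, amputed.mask, rng)


def _initial_fill_rng(frame: pd.DataFrame, mask: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    out = frame.copy()
    for j, col in enumerate(frame.columns):
        miss = mask[:, j]
        if not miss.any():
            continue
        observed = frame[col].to_numpy(dtype=float)[~miss]
        if observed.size == 0:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        out.iloc[np.flatnonzero(miss), j] = rng.choice(observed, size=int(miss.sum()))
    return out


def pmm_impute_column(
    working_data: pd.DataFrame,
    target_column: str,
    missing_mask: np.ndarray,
    donor_count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive-mean-matching draw for one column.

    Returns the imputed values for the masked rows (in row order).
    """
    miss = np.asarray(missing_mask, dtype=bool)
    y = working_data[target_column].to_numpy(dtype=float)
    X = working_data.drop(columns=[target_column]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    X_obs, y_obs = X[~miss], y[~miss]
    X_mis = X[miss]
    n_obs, q = X_obs.shape
    if n_obs < donor_count:
        raise ValueError(
            f"column {target_column!r}: {n_obs} observed rows < donor_count {donor_count}"
        )

    beta_hat, resid, XtX = _draw_safe_lstsq(X_obs, y_obs)
    # type-1 PMM: stochastic coefficients for the missing-row predictions,
    # least-squares coefficients for the donors
    df = max(n_obs - q, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(df)
    try:
        L = np.linalg.cholesky(np.linalg.inv(XtX))
        beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(q))
    except np.linalg.LinAlgError:
        logger.warning("pmm: singular design for %r; coefficient draw skipped", target_column)
        beta_star = beta_hat

    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star

    k = min(donor_count, n_obs)
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    donors = np.argpartition(dist, k - 1, axis=1)[:, :k]
    chosen = donors[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    return y_obs[chosen]


def _draw_safe_lstsq(X: np.ndarray, y: np.ndarray):
    """Least squares with a logged ridge fallback for singular designs."""
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError:
        logger.warning("pmm: rank-deficient design; ridge-regularized fit used")
        XtX = XtX + 1e-8 * np.eye(X.shape[1])
        beta = np.linalg.solve(XtX, X.T @ y)
    return beta, y - X @ beta, XtX


def rf_impute_column(
    working_data: pd.DataFrame,
    target_column: str,
    missing_mask: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-forest terminal-node draw for one column."""
    miss = np.asarray(missing_mask, dtype=bool)
    y = working_data[target_column].to_numpy(dtype=float)
    X = working_data.drop(columns=[target_column]).to_numpy(dtype=float)
    X_obs, y_obs = X[~miss], y[~miss]
    X_mis = X[miss]

    uniq = np.unique(y_obs)
    if uniq.size == 1:
        logger.warning("rf: column %r constant among observed rows; imputing that constant",
                       target_column)
        return np.full(len(X_mis), uniq[0])

    is_binary = uniq.size == 2 and np.isin(uniq, (0.0, 1.0)).all()
    cls = RandomForestClassifier if is_binary else RandomForestRegressor
    forest = cls(
        n_estimators=n_trees,
        min_samples_leaf=5,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X_obs, y_obs.astype(int) if is_binary else y_obs)

    leaves_obs = forest.apply(X_obs)  # (n_obs, n_trees)
    leaves_mis = forest.apply(X_mis)
    out = np.empty(len(X_mis))
    # pool observed values over the terminal node reached in every tree
    pools = [
        {leaf: np.flatnonzero(leaves_obs[:, t] == leaf)
         for leaf in np.unique(leaves_obs[:, t])}
        for t in range(leaves_obs.shape[1])
    ]
    for i in range(len(X_mis)):
        members = [
            pools[t].get(leaves_mis[i, t], np.empty(0, dtype=int))
            for t in range(leaves_mis.shape[1])
        ]
        pooled = np.concatenate(members)
        if pooled.size == 0:  # can only happen if no observed row shares any leaf
            pooled = np.arange(len(y_obs))
        out[i] = y_obs[rng.choice(pooled)]
    return out


def mice(amputed: AmputedDataset, config: ImputationConfig) -> ImputedStack:
    """Run m independent chained-equation chains and return the completed stack."""
    frame = amputed.frame
    mask = amputed.mask
    cols_with_missing = [
        (j, col) for j, col in enumerate(frame.columns) if mask[:, j].any()
    ]
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.m)

    completed: list[pd.DataFrame] = []
    for chain, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        work = _initial_fill_rng(frame, mask, rng)
        for cycle in range(config.n_cycles):
            for j, col in cols_with_missing:
                col_mask = mask[:, j]
                try:
                    if config.method == "PMM":
                        values = pmm_impute_column(
                            work, col, col_mask, config.donor_count, rng
                        )
                    else:
                        values = rf_impute_column(
                            work, col, col_mask, config.n_trees, rng
                        )
                except Exception as exc:
                    raise RuntimeError(
                        f"imputation failed (chain {chain + 1}, cycle {cycle + 1}, "
                        f"column {col!r}): {exc}"
                    ) from exc
                work.iloc[np.flatnonzero(col_mask), j] = values
        completed.append(work)
    return ImputedStack(completed=completed, config=config, provenance=amputed)
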
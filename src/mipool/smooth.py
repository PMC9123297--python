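"""Smooth-model fitting and per-covariate significance tests.

Two model families are provided, both with every covariate entering as its
own smooth term:

* ``penalized_gam`` — penalized cubic B-spline smooths (basis dimension
  ``basis_max`` per covariate, quantile knots, exact second-derivative
  penalties, sum-to-zero centering).  One smoothing parameter per smooth is
  selected by minimizing a profiled Laplace/marginal-likelihood criterion
  (``ML`` default; ``REML`` and ``GCV`` optional), optimized on the log
  scale by quasi-Newton with multi-starts.  Significance of smooth j uses a
  Wood-style rank-r statistic T = beta_j' V_j^{r-} beta_j with
  r = min(ceil(edf_j), basis dim), referred to F(r, residual df) for the
  gaussian family and chi-square(r) for the binomial family.

* ``bspline_lrt`` — unpenalized cubic B-spline regressions with
  ``bspline_df`` degrees of freedom per covariate (interior knots at the
  seven equally spaced quantiles by default) and likelihood-ratio tests:
  the reduced model refits without covariate j's basis columns and the
  recorded statistic is the deviance 2*(loglik_full - loglik_reduced)
  (= n log(RSS_reduced/RSS_full) for the gaussian family), which the D2
  pooling rules consume.  The gaussian p-value defaults to the exact
  nested-model F reference (the dispersion-scaled test classical ANOVA
  computes, nominally calibrated in finite samples); a raw chi-square
  reference on the deviance is available via ``lrt_reference="chisq"`` and
  is always used for the binomial family.

Effective degrees of freedom (GAM) or basis df (B-spline) double as the
per-imputation "number of parameters" consumed by the D2 pooling rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit

from . import _basis
from .friedman import COVARIATE_NAMES, OUTCOME_NAME, SimulatedDataset

__all__ = [
    "SmoothModelConfig",
    "CovariateTest",
    "SmoothTestResult",
    "BSplineFit",
    "GamFit",
    "fit_bspline",
    "bspline_lrt",
    "fit_penalized_gam",
    "gam_smooth_test",
    "fit_smooth_model",
    "smooth_tests",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class SmoothModelConfig:
    """Settings shared by both smooth-model families."""

    family: str = "gaussian_identity"  # or "binomial_logit"
    model_kind: str = "penalized_gam"  # or "bspline_lrt"
    basis_max: int = 10
    bspline_df: int = 10
    n_interior_knots: int = 7
    fit_method: str = "ML"  # ML | REML | GCV
    lrt_reference: str = "f"  # gaussian B-spline reference: "f" or "chisq"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian_identity", "binomial_logit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.model_kind not in ("penalized_gam", "bspline_lrt"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.basis_max < 3:
            raise ValueError("basis_max must be >= 3")
        if self.bspline_df != self.n_interior_knots + 3:
            raise ValueError(
                "cubic construction requires bspline_df == n_interior_knots + 3"
            )
        if self.fit_method not in ("ML", "REML", "GCV"):
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        if self.lrt_reference not in ("f", "chisq"):
            raise ValueError(f"unknown lrt_reference {self.lrt_reference!r}")


@dataclass(frozen=True)
class CovariateTest:
    """One covariate's test: statistic, df (edf or basis df), p-value."""

    covariate: str
    statistic: float
    df: float
    p_value: float


@dataclass
class SmoothTestResult:
    records: list[CovariateTest]
    model_loglik: float
    n_params: float
    fit_method: str
    model_kind: str
    family: str

    def record(self, covariate: str) -> CovariateTest:
        for r in self.records:
            if r.covariate == covariate:
                return r
        raise KeyError(covariate)

    def to_json_record(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "family": self.family,
            "fit_method": self.fit_method,
            "model_loglik": self.model_loglik,
            "n_params": self.n_params,
            "tests": [
                {"covariate": r.covariate, "statistic": r.statistic,
                 "df": r.df, "p_value": r.p_value}
                for r in self.records
            ],
        }


def _extract(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, SimulatedDataset):
        return data.covariates, data.outcome
    if isinstance(data, pd.DataFrame):
        if data.isna().any().any():
            raise ValueError("smooth models require complete data; impute first")
        return (
            data[list(COVARIATE_NAMES)].to_numpy(dtype=float),
            data[OUTCOME_NAME].to_numpy(dtype=float),
        )
    raise TypeError(f"unsupported data type {type(data)!r}")


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _binomial_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))


# ---------------------------------------------------------------------------
# B-spline regression + likelihood ratio tests
# ---------------------------------------------------------------------------


class BSplineFit:
    """Unpenalized cubic B-spline regression of y on all six covariates."""

    def __init__(self, data, config: SmoothModelConfig):
        if config.model_kind != "bspline_lrt":
            raise ValueError("BSplineFit requires model_kind='bspline_lrt'")
        X_raw, y = _extract(data)
        self.config = config
        self.y = y
        self.n = len(y)

        cols = [np.ones((self.n, 1))]
        self.blocks: list[slice] = []
        start = 1
        for j, name in enumerate(COVARIATE_NAMES):
            x = X_raw[:, j]
            interior = _basis.quantile_knots(x, config.n_interior_knots, name)
            t = _basis.knot_vector(interior, float(x.min()), float(x.max()))
            B = _basis.bspline_design(x, t)[:, 1:]  # drop one column: intercept present
            cols.append(B)
            self.blocks.append(slice(start, start + B.shape[1]))
            start += B.shape[1]
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise ValueError(f"n_rows={self.n} must exceed parameter count {self.p}")

        self.beta, self.rss, self.loglik = self._fit(self.X, check_rank=True)
        self._reduced_cache: dict[int, tuple[float, int]] = {}

    # -- fitting ------------------------------------------------------------

    def _fit(self, X: np.ndarray, check_rank: bool = False):
        if self.config.family == "gaussian_identity":
            beta, res, rank, _ = np.linalg.lstsq(X, self.y, rcond=None)
            if check_rank and rank < X.shape[1]:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design ({self._offending_covariate()})"
                )
            resid = self.y - X @ beta
            rss = float(resid @ resid)
            return beta, rss, _gaussian_loglik(rss, self.n)
        import statsmodels.api as sm

        model = sm.GLM(self.y, X, family=sm.families.Binomial())
        fit = model.fit(maxiter=200)
        mu = np.asarray(fit.mu)
        return np.asarray(fit.params), np.nan, _binomial_loglik(self.y, mu)

    def _offending_covariate(self) -> str:
        rank = 1
        for j, blk in enumerate(self.blocks):
            sub = self.X[:, : blk.stop]
            new_rank = np.linalg.matrix_rank(sub)
            if new_rank < rank + (blk.stop - blk.start):
                return f"offending covariate: {COVARIATE_NAMES[j]}"
            rank = new_rank
        return "offending covariate: unknown"

    @property
    def fitted_values(self) -> np.ndarray:
        eta = self.X @ self.beta
        if self.config.family == "binomial_logit":
            return expit(eta)
        return eta

    # -- inference ----------------------------------------------------------

    def lrt(self, j: int) -> CovariateTest:
        """Likelihood ratio test for covariate j (0-based index)."""
        blk = self.blocks[j]
        df = blk.stop - blk.start
        if df == 0:
            return CovariateTest(COVARIATE_NAMES[j], 0.0, 0.0, 1.0)
        if j not in self._reduced_cache:
            keep = np.ones(self.p, dtype=bool)
            keep[blk] = False
            _, rss_red, ll_red = self._fit(self.X[:, keep])
            self._reduced_cache[j] = (ll_red, rss_red)
        ll_red, rss_red = self._reduced_cache[j]
        stat = max(2.0 * (self.loglik - ll_red), 0.0)
        if self.config.family == "gaussian_identity" and self.config.lrt_reference == "f":
            fstat = ((rss_red - self.rss) / df) / (self.rss / (self.n - self.p))
            p = float(stats.f.sf(max(fstat, 0.0), df, self.n - self.p))
        else:
            p = float(stats.chi2.sf(stat, df))
        return CovariateTest(COVARIATE_NAMES[j], float(stat), float(df), p)

    def test_all(self) -> SmoothTestResult:
        return SmoothTestResult(
            records=[self.lrt(j) for j in range(6)],
            model_loglik=float(self.loglik),
            n_params=float(self.p),
            fit_method=self.config.fit_method,
            model_kind="bspline_lrt",
            family=self.config.family,
        )


def fit_bspline(data, config: SmoothModelConfig | None = None) -> BSplineFit:
    config = config or SmoothModelConfig(model_kind="bspline_lrt")
    return BSplineFit(data, config)


def bspline_lrt(data, config: SmoothModelConfig, j: int) -> CovariateTest:
    return fit_bspline(data, config).lrt(j)


# ---------------------------------------------------------------------------
# Penalized GAM
# ---------------------------------------------------------------------------


class GamFit:
    """Penalized-spline GAM with per-smooth smoothing parameters.

    Gaussian fits use penalized least squares with the smoothing parameters
    chosen by the profiled marginal-likelihood criterion

        V(rho) = N log(Dp / N) + log|X'X + S_lambda| - log|S_lambda|_+

    where Dp is the penalized residual sum of squares, N = n for ML and
    n - M_p (M_p = penalty null-space dimension) for REML.  Binomial fits
    replace the inner solve by penalized IRLS and Dp by the penalized
    deviance (Laplace approximation).  GCV minimizes n*RSS/(n - edf)^2.
    """

    _STARTS = (np.log(0.01), 0.0, np.log(100.0))

    def __init__(self, data, config: SmoothModelConfig, lam: np.ndarray | None = None):
        if config.model_kind != "penalized_gam":
            raise ValueError("GamFit requires model_kind='penalized_gam'")
        X_raw, y = _extract(data)
        self.config = config
        self.y = y
        self.n = len(y)
        self._build_design(X_raw)
        self._binomial = config.family == "binomial_logit"
        if self._binomial and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires a 0/1 outcome")

        if lam is not None:
            self.lam = np.asarray(lam, dtype=float)
            if self.lam.shape != (6,):
                raise ValueError("lam must have one entry per smooth")
        else:
            self.lam = np.exp(self._optimize())
        self._finalize()

    # -- design -------------------------------------------------------------

    def _build_design(self, X_raw: np.ndarray) -> None:
        k = self.config.basis_max
        cols = [np.ones((self.n, 1))]
        self.blocks: list[slice] = []
        self.S_blocks: list[np.ndarray] = []
        self._pen_rank: list[int] = []
        self._pen_logdet: list[float] = []
        start = 1
        for j, name in enumerate(COVARIATE_NAMES):
            x = X_raw[:, j]
            interior = _basis.quantile_knots(x, k - 4, name)
            t = _basis.knot_vector(interior, float(x.min()), float(x.max()))
            B = _basis.bspline_design(x, t)
            S = _basis.second_derivative_penalty(t)
            Z = _basis.centering_transform(B)
            Bz, Sz = B @ Z, Z.T @ S @ Z
            Sz = 0.5 * (Sz + Sz.T)
            cols.append(Bz)
            self.S_blocks.append(Sz)
            ev = np.linalg.eigvalsh(Sz)
            pos = ev[ev > _EIG_TOL * max(ev.max(), 1.0)]
            self._pen_rank.append(len(pos))
            self._pen_logdet.append(float(np.log(pos).sum()))
            self.blocks.append(slice(start, start + Bz.shape[1]))
            start += Bz.shape[1]
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise ValueError(f"n_rows={self.n} must exceed parameter count {self.p}")
        self.null_space_dim = self.p - sum(self._pen_rank)

    def _assemble(self, lam: np.ndarray, P: np.ndarray) -> np.ndarray:
        A = P.copy()
        for lj, blk, S in zip(lam, self.blocks, self.S_blocks):
            A[blk, blk] += lj * S
        return A

    def _log_det_S(self, rho: np.ndarray) -> float:
        return float(np.dot(self._pen_rank, rho) + np.sum(self._pen_logdet))

    # -- gaussian criterion -------------------------------------------------

    def _gaussian_pieces(self, rho: np.ndarray):
        P, q, yy = self._P, self._q, self._yy
        A = self._assemble(np.exp(rho), P)
        try:
            chol = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.trace(A) / self.p * np.eye(self.p)
            chol = cho_factor(A, lower=True)
        beta = cho_solve(chol, q)
        dp = max(yy - q @ beta, 1e-300)  # RSS + penalty
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return A, chol, beta, dp, logdet_a

    def _criterion(self, rho: np.ndarray) -> float:
        if self._binomial:
            beta, chol, dev, pen, logdet_a = self._pirls(np.exp(rho))
            crit = dev + pen + logdet_a - self._log_det_S(rho)
            if self.config.fit_method == "GCV":
                edf = self._edf_total(chol, np.exp(rho))
                crit = self.n * dev / max(self.n - edf, 1e-3) ** 2
            return crit
        _, chol, beta, dp, logdet_a = self._gaussian_pieces(rho)
        if self.config.fit_method == "GCV":
            rss = self._rss_from_beta(beta)
            edf = self._edf_total(chol, np.exp(rho))
            return self.n * rss / max(self.n - edf, 1e-3) ** 2
        N = self.n if self.config.fit_method == "ML" else self.n - self.null_space_dim
        return N * np.log(dp / N) + logdet_a - self._log_det_S(rho)

    def _rss_from_beta(self, beta: np.ndarray) -> float:
        resid = self.y - self.X @ beta
        return float(resid @ resid)

    def _edf_total(self, chol, lam: np.ndarray) -> float:
        F = cho_solve(chol, self._P if not self._binomial else self._XtWX)
        return float(np.trace(F))

    # -- binomial PIRLS -----------------------------------------------------

    def _pirls(self, lam: np.ndarray, max_iter: int = 100, tol: float = 1e-9):
        X, y = self.X, self.y
        beta = self._warm if self._warm is not None else np.zeros(self.p)
        last = np.inf
        for _ in range(max_iter):
            eta = np.clip(X @ beta, -30.0, 30.0)
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-6, None)
            z = eta + (y - mu) / w
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            A = self._assemble(lam, XtWX)
            try:
                chol = cho_factor(A, lower=True)
            except np.linalg.LinAlgError:
                A = A + 1e-8 * np.trace(A) / self.p * np.eye(self.p)
                chol = cho_factor(A, lower=True)
            beta = cho_solve(chol, Xw.T @ z)
            pen = float(sum(lj * beta[blk] @ S @ beta[blk]
                            for lj, blk, S in zip(lam, self.blocks, self.S_blocks)))
            mu_new = expit(np.clip(X @ beta, -30.0, 30.0))
            dev = -2.0 * _binomial_loglik(y, mu_new)
            obj = dev + pen
            if abs(last - obj) < tol * (abs(obj) + 1.0):
                last = obj
                break
            last = obj
        self._warm = beta
        self._XtWX = XtWX
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        self._last_chol = chol
        return beta, chol, dev, pen, logdet_a

    # -- optimization -------------------------------------------------------

    def _optimize(self) -> np.ndarray:
        self._P = self.X.T @ self.X
        self._q = self.X.T @ self.y
        self._yy = float(self.y @ self.y)
        self._warm = None

        best_val, best_rho, traces = np.inf, None, []
        for s in self._STARTS:
            x0 = np.full(6, s)
            try:
                res = minimize(
                    self._criterion, x0, method="L-BFGS-B",
                    bounds=[(-16.0, 16.0)] * 6,
                    options={"maxiter": 80, "ftol": 1e-10},
                )
            except (np.linalg.LinAlgError, FloatingPointError) as exc:
                traces.append(f"start {s:.2f}: {exc}")
                continue
            traces.append(f"start {s:.2f}: fun={res.fun:.6g} nit={res.nit} {res.message}")
            if np.isfinite(res.fun) and res.fun < best_val:
                best_val, best_rho = res.fun, res.x
        if best_rho is None:
            raise RuntimeError(
                "smoothing-parameter optimization failed on every start; trace:\n"
                + "\n".join(traces)
            )
        return best_rho

    # -- final quantities ---------------------------------------------------

    def _finalize(self) -> None:
        if not hasattr(self, "_P"):
            self._P = self.X.T @ self.X
            self._q = self.X.T @ self.y
            self._yy = float(self.y @ self.y)
            self._warm = None
        rho = np.log(np.clip(self.lam, 1e-300, None))
        if self._binomial:
            beta, chol, dev, _, _ = self._pirls(self.lam)
            self.beta = beta
            self.scale = 1.0
            crossprod = self._XtWX
            mu = expit(np.clip(self.X @ beta, -30.0, 30.0))
            self.fitted_values = mu
            self.loglik = _binomial_loglik(self.y, mu)
        else:
            A, chol, beta, dp, _ = self._gaussian_pieces(rho)
            self.beta = beta
            crossprod = self._P
            self.fitted_values = self.X @ beta
            rss = self._rss_from_beta(beta)
            self.rss = rss
            self.loglik = _gaussian_loglik(rss, self.n)

        F = cho_solve(chol, crossprod)
        diag = np.diag(F)
        self.edf_total = float(np.sum(diag))
        self.edf = np.array([float(np.sum(diag[blk])) for blk in self.blocks])
        if not self._binomial:
            self.scale = self.rss / max(self.n - self.edf_total, 1.0)
        Ainv = cho_solve(chol, np.eye(self.p))
        self.Vb = Ainv * self.scale

    # -- inference ----------------------------------------------------------

    def smooth_test(self, j: int) -> CovariateTest:
        """Rank-r Wald-type test of smooth j against a flat function."""
        blk = self.blocks[j]
        beta_j = self.beta[blk]
        V_j = self.Vb[blk, blk]
        dim = blk.stop - blk.start
        edf_j = float(np.clip(self.edf[j], 0.0, dim))
        # rank rule: floor(edf) plus one extra dimension only when the
        # fractional part is non-negligible; ceil() alone over-penalizes a
        # fully shrunk smooth (edf = 1 + eps would be tested on 2 dof)
        frac = edf_j - np.floor(edf_j)
        r = int(min(max(np.floor(edf_j) + (frac > 0.05), 1), dim))

        ev, U = np.linalg.eigh(0.5 * (V_j + V_j.T))
        order = np.argsort(ev)[::-1]
        ev, U = ev[order], U[:, order]
        usable = ev > _EIG_TOL * max(ev[0], 1e-300)
        if usable[:r].sum() < r:
            logger.warning(
                "smooth %s: covariance numerically singular, rank reduced %d -> %d",
                COVARIATE_NAMES[j], r, int(usable[:r].sum()),
            )
            r = max(int(usable[:r].sum()), 1)
        Ur, evr = U[:, :r], ev[:r]
        t_stat = float((Ur.T @ beta_j) @ ((Ur.T @ beta_j) / evr))

        if self._binomial:
            p = float(stats.chi2.sf(t_stat, r))
            return CovariateTest(COVARIATE_NAMES[j], t_stat, edf_j, p)
        fstat = t_stat / r
        p = float(stats.f.sf(fstat, r, max(self.n - self.edf_total, 1.0)))
        return CovariateTest(COVARIATE_NAMES[j], fstat, edf_j, p)

    def test_all(self) -> SmoothTestResult:
        return SmoothTestResult(
            records=[self.smooth_test(j) for j in range(6)],
            model_loglik=float(self.loglik),
            n_params=float(self.edf_total),
            fit_method=self.config.fit_method,
            model_kind="penalized_gam",
            family=self.config.family,
        )


def fit_penalized_gam(data, config: SmoothModelConfig | None = None,
                      lam: np.ndarray | None = None) -> GamFit:
    config = config or SmoothModelConfig(model_kind="penalized_gam")
    return GamFit(data, config, lam=lam)


def gam_smooth_test(fit: GamFit, j: int) -> CovariateTest:
    return fit.smooth_test(j)


def fit_smooth_model(data, config: SmoothModelConfig):
    """Dispatch on ``config.model_kind``."""
    if config.model_kind == "penalized_gam":
        return GamFit(data, config)
    return BSplineFit(data, config)


def smooth_tests(data, config: SmoothModelConfig) -> SmoothTestResult:
    """Fit the configured smooth model and test every covariate."""
    return fit_smooth_model(data, config).test_all()
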
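import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from mipool.friedman import FriedmanConfig, simulate_binary, simulate_normal
from mipool.friedman import _mean_matrix
from mipool.smooth import (
    BSplineFit,
    SmoothModelConfig,
    bspline_lrt,
    fit_bspline,
    fit_penalized_gam,
    smooth_tests,
)

BS = SmoothModelConfig(model_kind="bspline_lrt")
GAM = SmoothModelConfig(model_kind="penalized_gam")


def _noiseless(n, seed=0):
    return simulate_normal(FriedmanConfig(n_rows=n, noise_sd=0.0, seed=seed))


def _r2(fit, ds):
    resid = ds.outcome - fit.fitted_values
    return 1.0 - resid @ resid / np.sum((ds.outcome - ds.outcome.mean()) ** 2)


def _additive_noiseless(n, seed=0):
    """Noiseless outcome with the interaction term removed: an additive
    model can represent this surface exactly (up to spline approximation),
    so near-perfect recovery is the right oracle here.  The full Friedman
    mean contains sin(pi*x1*x2), which no additive fit can reproduce."""
    ds = _noiseless(n, seed=seed)
    X = ds.covariates
    frame = ds.frame.copy()
    frame["y"] = 20 * (X[:, 2] - 0.5) ** 2 + 10 * X[:, 3] + 5 * X[:, 4]
    return frame


# ------------------------------------------------------------------ B-spline


def test_bspline_recovers_additive_noiseless_surface():
    frame = _additive_noiseless(2_000, seed=1)
    fit = fit_bspline(frame, BS)
    resid = frame["y"].to_numpy() - fit.fitted_values
    assert 1 - resid.var() / frame["y"].var() > 0.999


def test_bspline_captures_most_of_friedman_surface():
    ds = _noiseless(2_000, seed=1)
    fit = fit_bspline(ds.frame, BS)
    assert _r2(fit, ds) > 0.9  # the x1*x2 interaction bounds an additive fit


def test_bspline_fit_is_deterministic():
    ds = simulate_normal(FriedmanConfig(n_rows=400, seed=2))
    f1 = fit_bspline(ds.frame, BS)
    f2 = fit_bspline(ds.frame, BS)
    np.testing.assert_array_equal(f1.beta, f2.beta)


def test_bspline_deduplicates_tied_knots(caplog):
    import logging

    ds = simulate_normal(FriedmanConfig(n_rows=400, seed=3))
    frame = ds.frame.copy()
    # x2 collapses onto 4 distinct values: the 7 quantile knots tie heavily
    frame["x2"] = np.round(frame["x2"] * 3) / 3
    with caplog.at_level(logging.WARNING, logger="mipool._basis"):
        fit = fit_bspline(frame, BS)
    assert "deduplicated" in caplog.text or "capped" in caplog.text
    blk = fit.blocks[1]
    assert blk.stop - blk.start < 10  # basis dimension shrank


def test_gaussian_lrt_statistic_matches_closed_form():
    # deviance statistic equals n * log(RSS_reduced / RSS_full)
    for seed in (4, 5, 6):
        ds = simulate_normal(FriedmanConfig(n_rows=300, seed=seed))
        fit = fit_bspline(ds.frame, BS)
        for j in (0, 5):
            rec = fit.lrt(j)
            keep = np.ones(fit.p, bool)
            keep[fit.blocks[j]] = False
            beta_r, *_ = np.linalg.lstsq(fit.X[:, keep], fit.y, rcond=None)
            rss_r = float(np.sum((fit.y - fit.X[:, keep] @ beta_r) ** 2))
            expected = fit.n * np.log(rss_r / fit.rss)
            assert rec.statistic == pytest.approx(expected, abs=1e-8)


def test_bspline_lrt_detects_strong_linear_signal():
    ds = simulate_normal(FriedmanConfig(n_rows=1_000, seed=7))
    rec = bspline_lrt(ds.frame, BS, 3)  # x4 has coefficient 10
    assert rec.p_value < 1e-6
    assert rec.df == 10.0


def test_lrt_degenerate_empty_block_gives_unit_p():
    ds = simulate_normal(FriedmanConfig(n_rows=300, seed=8))
    fit = fit_bspline(ds.frame, BS)
    fit.blocks[5] = slice(fit.p, fit.p)  # covariate's columns already absent
    rec = fit.lrt(5)
    assert rec.statistic == 0.0 and rec.p_value == 1.0


def test_bspline_needs_more_rows_than_parameters():
    ds = simulate_normal(FriedmanConfig(n_rows=50, seed=9))
    with pytest.raises(ValueError, match="exceed"):
        fit_bspline(ds.frame, BS)


def test_binomial_bspline_path():
    ds = simulate_binary(FriedmanConfig(n_rows=900, outcome_kind="binary", seed=10))
    cfg = SmoothModelConfig(model_kind="bspline_lrt", family="binomial_logit")
    res = smooth_tests(ds.frame, cfg)
    assert all(0.0 <= r.p_value <= 1.0 for r in res.records)
    assert res.record("x4").p_value < 1e-3


# ----------------------------------------------------------------------- GAM


def test_gam_recovers_additive_noiseless_surface():
    frame = _additive_noiseless(2_000, seed=11)
    fit = fit_penalized_gam(frame, GAM)
    resid = frame["y"].to_numpy() - fit.fitted_values
    assert 1 - resid.var() / frame["y"].var() > 0.999


def test_gam_captures_most_of_friedman_surface():
    ds = _noiseless(2_000, seed=11)
    fit = fit_penalized_gam(ds.frame, GAM)
    assert _r2(fit, ds) > 0.9


def test_gam_zero_penalty_equals_unpenalized_regression():
    ds = simulate_normal(FriedmanConfig(n_rows=500, seed=12))
    fit = fit_penalized_gam(ds.frame, GAM, lam=np.zeros(6))
    beta_ols, *_ = np.linalg.lstsq(fit.X, fit.y, rcond=None)
    np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
    assert fit.edf_total == pytest.approx(fit.p, abs=1e-6)


def test_null_smooth_shrinks_to_linear_edf():
    ds = simulate_normal(FriedmanConfig(n_rows=4_000, seed=13))
    fit = fit_penalized_gam(ds.frame, GAM)
    assert fit.edf[5] < 2.5  # x6 smooth collapses toward its linear null space
    assert np.all(fit.edf >= 1.0 - 1e-6)
    assert np.all(fit.edf <= 9.0 + 1e-6)


def test_gam_pvalues_invariant_to_row_permutation():
    ds = simulate_normal(FriedmanConfig(n_rows=400, seed=14))
    perm = np.random.default_rng(0).permutation(400)
    shuffled = ds.frame.iloc[perm].reset_index(drop=True)
    for cfg, tol in ((GAM, 0.05), (BS, 1e-6)):
        p1 = np.array([r.p_value for r in smooth_tests(ds.frame, cfg).records])
        p2 = np.array([r.p_value for r in smooth_tests(shuffled, cfg).records])
        # tiny p-values drift in relative terms with summation order;
        # compare on the log scale
        np.testing.assert_allclose(
            np.log10(p1 + 1e-300), np.log10(p2 + 1e-300), rtol=tol, atol=tol
        )


def test_gam_fitted_values_invariant_to_covariate_rescaling():
    ds = simulate_normal(FriedmanConfig(n_rows=500, seed=15))
    frame = ds.frame
    scaled = frame.copy()
    scaled["x1"] = 10.0 * scaled["x1"] - 4.0
    f1 = fit_penalized_gam(frame, GAM)
    f2 = fit_penalized_gam(scaled, GAM)
    sd = frame["y"].std()
    assert np.max(np.abs(f1.fitted_values - f2.fitted_values)) < 0.05 * sd


def test_gam_power_for_strong_linear_signal():
    S, rejections = 60, 0
    for s in range(S):
        ds = simulate_normal(FriedmanConfig(n_rows=1_000, seed=16_000 + s))
        rec = smooth_tests(ds.frame, GAM).record("x4")
        rejections += rec.p_value < 0.05
    assert rejections / S >= 0.95


def test_gam_null_calibration_under_ml():
    """Full-data type-I error for x6 under ML smoothing selection: close to
    nominal, historically a touch liberal, never grossly inflated."""
    S, rejections = 300, 0
    for s in range(S):
        ds = simulate_normal(FriedmanConfig(n_rows=250, seed=17_000 + s))
        rejections += smooth_tests(ds.frame, GAM).record("x6").p_value < 0.05
    rate = rejections / S
    assert 0.02 < rate < 0.15


def test_gam_edf_bounds_and_result_shape():
    ds = simulate_normal(FriedmanConfig(n_rows=300, seed=18))
    res = smooth_tests(ds.frame, GAM)
    assert len(res.records) == 6
    assert all(0.0 <= r.df <= 10.0 for r in res.records)
    assert all(0.0 <= r.p_value <= 1.0 for r in res.records)
    assert res.n_params > 6.0
    rec = res.to_json_record()
    assert {t["covariate"] for t in rec["tests"]} == {f"x{i}" for i in range(1, 7)}


def test_binomial_gam_path():
    ds = simulate_binary(FriedmanConfig(n_rows=900, outcome_kind="binary", seed=19))
    cfg = SmoothModelConfig(model_kind="penalized_gam", family="binomial_logit")
    res = smooth_tests(ds.frame, cfg)
    assert all(0.0 <= r.p_value <= 1.0 for r in res.records)
    assert res.record("x4").p_value < 1e-3


@pytest.mark.parametrize("fit_method", ["REML", "GCV"])
def test_alternative_fit_methods_run(fit_method):
    ds = simulate_normal(FriedmanConfig(n_rows=300, seed=20))
    cfg = SmoothModelConfig(model_kind="penalized_gam", fit_method=fit_method)
    res = smooth_tests(ds.frame, cfg)
    assert res.fit_method == fit_method
    assert all(np.isfinite(r.p_value) for r in res.records)


def test_config_validation():
    with pytest.raises(ValueError):
        SmoothModelConfig(basis_max=2)
    with pytest.raises(ValueError):
        SmoothModelConfig(bspline_df=9)  # breaks the cubic construction
    with pytest.raises(ValueError):
        SmoothModelConfig(fit_method="AIC")


def test_incomplete_data_is_rejected():
    ds = simulate_normal(FriedmanConfig(n_rows=200, seed=21))
    frame = ds.frame.copy()
    frame.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        smooth_tests(frame, BS)


def test_gam_agrees_with_mgcv_reference(tmp_path):
    """Independent cross-check against the mgcv GAM implementation on one
    fixed dataset: fitted curves and per-smooth complexities should agree
    closely even though the smoothing criteria differ in constants."""
    ds = simulate_normal(FriedmanConfig(n_rows=500, seed=42))
    fit = fit_penalized_gam(ds.frame, GAM)
    csv = tmp_path / "d.csv"
    ds.to_csv(csv)
    fitted_file = tmp_path / "mgcv_fitted.txt"
    edf_file = tmp_path / "mgcv_edf.txt"
    script = f"""
    suppressMessages(library(mgcv))
    d <- read.csv("{csv}")
    m <- gam(y ~ s(x1,k=10,bs="bs") + s(x2,k=10,bs="bs") + s(x3,k=10,bs="bs") +
               s(x4,k=10,bs="bs") + s(x5,k=10,bs="bs") + s(x6,k=10,bs="bs"),
             data=d, method="ML")
    write(fitted(m), "{fitted_file}", ncolumns=1)
    write(summary(m)$edf, "{edf_file}", ncolumns=1)
    """
    rscript = shutil.which("Rscript")
    assert rscript is not None, "Rscript not on PATH"
    subprocess.run([rscript, "-e", script], check=True, capture_output=True)
    mgcv_fitted = np.loadtxt(fitted_file)
    mgcv_edf = np.loadtxt(edf_file)
    assert np.corrcoef(fit.fitted_values, mgcv_fitted)[0, 1] > 0.999
    assert np.max(np.abs(fit.edf - mgcv_edf)) < 1.5
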
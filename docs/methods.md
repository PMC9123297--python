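# Methods notes

This note records the models implemented in `mipool`, the defaults and why
they were chosen, the numerical decisions, and what the simulation results
do and do not establish.

## Generating model

The benchmark simulator draws six covariates independently from
Uniform(0, 1) and builds the outcome from the Friedman regression surface

    f(x) = 10 sin(π x1 x2) + 20 (x3 − 0.5)² + 10 x4 + 5 x5 + 0 x6,

normal outcomes as y = f(x) + ε with ε ~ N(0, 9), i.e. `noise_sd = 3`.
The surface mixes a trigonometric interaction, a U-shaped quadratic, and
two linear terms of different strength, and x6 is exactly null — so the
x1…x5 rejection rates of any downstream test estimate power at several
effect shapes while the x6 rate estimates the type-I error.

Binary outcomes standardize the (noisy) signal within the dataset,
z_i = (s_i − mean s)/sd(s), map it through the inverse logit and draw
Bernoulli(p_i).  The empirical standardization keeps the event rate near
0.5 at any n.  Whether the N(0, 9) noise belongs inside s_i before
standardization is genuinely open; including it (the default,
`binary_include_noise=True`) makes the latent scale match the normal-outcome
model, and the switch is exposed for the other reading.

Covariates are drawn column by column x1→x6 before the noise, so a dataset
is a pure function of its seed.

One deliberate consequence of this design: the surface is **not additive**
(the sin(π x1 x2) term), so an additive smooth model can capture at most
~93% of the noiseless variance.  Tests that demand near-perfect recovery
use an additive sub-surface; tests on the full surface bound R² at 0.9.

## Amputation

Missingness is imposed by the weighted-sum-score multivariate amputation
procedure.  Every row is assigned to one of a set of patterns (default:
seven patterns, each blanking exactly one of x1…x6, y, with equal
frequencies — the variables actually amputed in the original study are not
recoverable, so the one-variable-per-pattern convention of the amputation
literature is used).  A row then becomes incomplete with probability

* MCAR — the target proportion itself (default 0.35);
* MAR/MNAR — expit(wᵀz_row + c), a right-tailed logistic in the weighted
  sum of the row's standardized column values, with the intercept c solved
  by Brent's method so the group-mean probability equals the target.

Default weights: MAR puts weight 1 on every column the pattern keeps
observed; MNAR puts weight 1 on the columns it removes.  Standardizing
columns first makes the weights scale-free.  The expected incomplete-row
fraction equals the target exactly by construction; at n = 10,000 the
realized fraction is within ±0.005 of 0.35, leaving ~65% of rows for the
complete-case benchmark.

## Multiple imputation

`mice()` runs m independent chains.  Each chain starts by filling every
missing cell with a uniform draw from its column's observed values, then
performs `n_cycles = 5` left-to-right sweeps over the columns with
missingness, re-imputing each column conditional on the current completed
values of the others.  Defaults (m = 25, 5 cycles, visit order, PMM donors,
RF size) mirror the conventional defaults of the standard chained-equations
software, which is also all the precision at which the original analysis is
recorded ("default options"); congruence is therefore distributional, not
bit-level.

* **PMM (type-1)**: regression of the target on all other columns over the
  observed rows; σ²* drawn as RSS/χ²(n−q) and β* ~ N(β̂, σ²*(XᵀX)⁻¹);
  missing-row predictions use β*, donor predictions use β̂; each missing row
  copies the observed value of one of its 5 nearest-prediction donors.
  Singular designs fall back to a ridge-regularized solve (logged).
* **RF**: a 10-tree bootstrap forest (minimum node size 5, √p candidate
  features) grown on the observed rows; a missing row pools the observed
  values in the terminal node it reaches in every tree and draws one
  uniformly.  Binary targets use classification trees; a constant observed
  column is imputed as that constant with a warning.

Both imputers only ever copy observed values (support containment), and
observed cells are preserved bit-exactly in every completion.

## Smooth models and per-covariate tests

Both model families give every covariate its own smooth term,
simultaneously — mirroring the GAM structure in the B-spline model too,
since a per-covariate alternative is not identifiable from the study
description and the symmetric structure keeps the two families comparable.

**Penalized GAM.**  Each smooth is a cubic B-spline basis of dimension
`basis_max = 10` with interior knots at covariate quantiles, an exact
second-derivative penalty (the integrals are closed-form via 3-point
Gauss–Legendre per knot span, exact for piecewise-quadratic integrands),
and a sum-to-zero centering constraint absorbing the intercept.  One
smoothing parameter per smooth is chosen by minimizing the profiled
marginal-likelihood criterion

    V(ρ) = N log(Dp/N) + log|XᵀWX + S_λ| − log|S_λ|₊,

with Dp the penalized residual sum of squares (penalized deviance for the
binomial family via PIRLS and a Laplace approximation), N = n for ML and
N = n − M_p for REML (M_p = penalty null-space dimension), and GCV as
n·RSS/(n − edf)².  Optimization is quasi-Newton (L-BFGS-B) on ρ = log λ
with finite-difference gradients and multi-starts at λ ∈ {0.01, 1, 100},
guarding against the global-optimization failures that make GCV unreliable.
ML is the default because it produced the lowest (closest to nominal)
type-I error among the three criteria, the same ordering that motivated the
original choice.  This criterion captures the ML/REML scale-bias
distinction without claiming bit-equality with any particular GAM package;
agreement is validated distributionally (calibration and power oracles) and
against an independent reference implementation on a fixed dataset (fitted
values correlate > 0.999, per-smooth edf within ~0.4).

Significance of smooth j uses the rank-r Wald-type construction:
T = β_jᵀ V_j^{r−} β_j with V_j the smooth's block of the Bayesian posterior
covariance (XᵀWX + S_λ)⁻¹φ and V^{r−} its rank-r pseudo-inverse,
r = floor(edf_j) + 1{frac(edf_j) > 0.05} capped to the basis dimension.
T/r is referred to F(r, n − edf_total) for the gaussian family and T to
χ²(r) for the binomial family.  The rounding rule matters: taking
r = ceil(edf_j) unconditionally tests a fully shrunk null smooth
(edf = 1 + ε) against two degrees of freedom and roughly halves its
rejection rate.  With the rule above, the full-data null rejection rate at
n = 250 under ML is ≈ 0.05–0.08 — near nominal and slightly liberal, the
known behavior of this test family when smoothing-parameter uncertainty is
ignored.

**B-spline regression.**  Unpenalized cubic B-splines with
`bspline_df = 10` per covariate (7 interior knots at the equally spaced
quantiles 12.5%, …, 87.5%), least squares for gaussian outcomes and a
logit-link GLM for binary ones.  Covariate j is tested by refitting without
its 10 basis columns.  The recorded statistic is the deviance
2(ℓ_full − ℓ_reduced) = n log(RSS_r/RSS_f), which the D2 rules consume; the
gaussian p-value is taken from the exact nested-model F test
((RSS_r − RSS_f)/df)/(RSS_f/(n − p)) ~ F(df, n−p), because the raw
χ²(10) reference on the deviance is anticonservative at n = 500 (measured
type-I ≈ 0.087 vs the F test's nominal 0.05, which matches the near-nominal
full-data calibration this analysis is reported to have).  The χ² reference
remains available (`lrt_reference="chisq"`) and is the binomial default.
Covariates with too few distinct values get their knots deduplicated and
their basis capped below the number of distinct values (logged).

## Pooling rules

Implemented exactly as printed in the table in the README.  Numerical
decisions:

* Even m uses the conventional sample median (mean of the two central order
  statistics); the study itself always uses odd m = 25.
* The Cauchy combination uses the **unweighted sum** of the tangents.  Note
  this is not the 1/m-weighted average of the ACAT literature: under
  independent uniform p-values the sum is Cauchy with scale m and the rule
  is anticonservative, which is precisely the "overpowered, over-rejecting"
  behavior the simulation study exhibits and which the weighted average
  would not reproduce.  Its stated validity regime is strongly correlated
  tests.  Boundary p-values are clamped to [1e-15, 1 − 1e-15] (logged).
* D2 requires m ≥ 2 (it needs a between-imputation variance; m = 1 raises
  with a pointer to single imputation).  All-identical statistics take the
  r₂ → 0 limit F(k̄, ∞) = χ²(k̄)/k̄.  A negative centred statistic is
  floored at 0, giving pooled p = 1.  The Alt. D2 reference uses k̄ as its
  numerator df — the study leaves this unspecified when the kᵢ vary.
* For GAMs, dᵢ is the per-imputation F statistic and kᵢ the edf, so the D2
  centre divides an already-normalized statistic by k̄ again.  That is the
  formula as printed and applied, and it is the mechanism behind D2's
  distinctly low power in this setting.  For B-splines dᵢ is the LRT
  deviance and kᵢ = 10.

Consequences worth knowing: with zero missingness the order-statistic rules
(MPV, mean-p) and single imputation reduce exactly to the full-data
p-value, but the Cauchy sum and D2 do not — they push m identical p-values
through their own reference distributions.

## Harness, seeds, and scale

The replicate pipeline is simulate → full-data fit → ampute →
complete-case fit → mice → m fits → all pooling rules → compare to
α = 0.05.  Seeding is hierarchical (root → per-replicate → per-stage
substreams for simulation/amputation/imputation chains), so results are
bit-reproducible and independent of the worker count, and changing m never
perturbs upstream draws.  Replicates that fail (rare unlucky penalized
fits) are skipped and counted; more than 5% failures aborts the scenario.

The m-sweep imputes max(m) chains once per replicate and pools prefixes, so
the curves are within-replicate comparable and the m = 1 point equals
single imputation by construction.

Default scale is deliberately desk-sized: S = 500 replicates of n = 250
rows (the study-scale S = 10,000 is one flag away, and n per dataset is a
free choice here — the original row count is not recorded).  The
acceptance-style tests run S = 200–500.  At these sizes the strong signals
(x1, x2, x4, x5) sit at or near power 1.0 under every method, so ordering
assertions between methods are made with a 2-standard-error Monte-Carlo
tie tolerance.

## What the simulations do and do not show

The generator matches the study conditions (independent uniform covariates,
σ² = 9 noise, 35% incomplete rows, m = 25 defaults).  Independence of
covariates is unrealistic and flatters neither imputation method; there are
no correlated predictors, no categorical predictors, no
longitudinal/dropout missingness, and the two clinical case studies the
method was applied to are not redistributable, so nothing here validates
behavior on real registry data.  Conclusions supported at desk scale are
the qualitative ones: the ordering of the pooling rules, MPV's closeness to
the full-data benchmark, D2's conservatism, the Cauchy rule's inflation,
and the improvement-then-plateau in the number of imputations.
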
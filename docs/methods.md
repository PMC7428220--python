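# Methods

This note documents the statistical procedures implemented in `raretrends`,
the assumptions behind them, and the design decisions taken where several
reasonable choices existed.

## Data model

The atomic observation is one species' integer count in one sampling occasion
of one assemblage-year. Rows with non-positive abundance encode absence and
are dropped (logged); non-integer abundances (mixed-provenance databases store
some counts as numeric) are floored rather than rejected, which preserves
count semantics deterministically; duplicated (assemblage, year, occasion,
species) rows are summed. The column mapping is configurable and defaults to
BioTIME-style public export names. Trend fitting requires at least two
distinct years per assemblage; the headline analyses of long monitoring series
use a 10-year minimum (`min_years=10`), applied by `validate_series` and
reported per assemblage rather than raised.

## Sample-based rarefaction

Sampling effort usually varies across years, and every rarity metric here is
effort-sensitive, so yearly summaries are computed on samples equalized to the
same number of *whole* occasions:

* The mean number of occasions per year is computed once, on all years
  originally present. Years with strictly fewer than half that mean are
  excluded; ties are retained. (Whether the mean should be recomputed after
  exclusions is ambiguous in general; computing it once is simpler and
  idempotent.)
* `n_min` is the minimum occasion count among retained years. Each year
  contributes exactly `n_min` occasions drawn uniformly without replacement;
  the year attaining the minimum contributes all of its occasions. Occasions
  are kept intact — all records of a drawn occasion are used — because
  species co-occurrence within an occasion is part of the sampling design.
* Species abundances are then summed within each year. For surveys where
  within-year samples are genuinely distinct units that must not be pooled
  (`is_aggregable=False`), one designated occasion per year is kept instead;
  this path is off by default.
* The draw is repeated 20 times (`n_iterations=20`). The first iteration is
  the headline dataset; iterations 2–20 feed only the robustness summary of
  overall slopes and slope correlations. Iteration k uses the RNG stream
  derived from the seed pair `(base_seed, k)` (numpy `SeedSequence`), so
  iterations are mutually independent and each is reproducible regardless of
  evaluation order.

The trend predictor is the mean-centred year: calendar year minus the mean of
the assemblage's *retained* years. Centering is per assemblage, which makes
every fit invariant to shifting calendar time.

## Yearly metrics

For each rarefied assemblage-year with abundance map {species → count}:

* `n_singletons` — species with count exactly 1;
* `n_rare` — species with count 1 or 2 (singletons + doubletons), the
  headline rarity measure (a doubleton is a species with exactly two
  individuals, the standard usage);
* `richness_S`, `size_N` — number of species and of individuals;
* `fisher_alpha` — the log-series diversity parameter, the unique positive
  root of S = α·ln(1 + N/α). The left side increases from 0 to N in α, so a
  finite root exists iff S < N; it is found by bracketed Brent root-finding
  to relative tolerance below 1e-10 (the returned α reproduces S to ≈
  machine precision, and the acceptance script verifies |S − α·ln(1+N/α)| ≤
  1e-8·S on a random grid). When S = N (every individual its own species) α
  diverges; the metrics table stores NaN for that year and the trend model
  drops the row, rather than silently imputing a value.

## Trend models

Each metric y_ij (assemblage i, year j) is modelled as

    link(μ_ij) = (β0 + b0_i) + (β1 + b1_i)·t_ij,   (b0_i, b1_i) ~ N(0, Σ)

with t the centred year and Σ an unstructured 2×2 covariance. Families:

| response        | family                | link     | dispersion            |
|-----------------|-----------------------|----------|-----------------------|
| n_rare, n_singletons | negative binomial | log      | θ (Var = μ + μ²/θ)    |
| log10_richness, log10_size | Gaussian     | identity | σ                     |
| fisher_alpha    | Gaussian, power variance | identity | σ, δ (Var = σ²·\|μ\|^{2δ}) |

Estimation is maximum likelihood with a Laplace approximation to the
random-effect integral: for each assemblage the 2-D conditional mode is found
by a damped Newton iteration (the conditional log-density is concave for all
three families), and the marginal likelihood is maximized over
(β, dispersion, log-Cholesky factor of Σ) with L-BFGS-B. For Gaussian
responses the Laplace step is exact, so those fits are plain ML; the Gaussian
route is cross-checked against `statsmodels.MixedLM` (ML) in the test suite
and agrees to ~1e-5 on the fixed effects. With the random-effect variances
pinned to zero the fit reproduces pooled GLM slopes, which the tests verify
against `statsmodels` GLMs.

The power-variance model mirrors the estimated-weights scheme of classical
mixed-model software: the variance covariate |μ̂| is held at the previous
iteration's fitted values, the likelihood is maximized (δ and σ jointly with
the other parameters), and the fitted values are refreshed until the fixed
slope stabilizes.

Uncertainty: `interval95` is a Wald interval from a central-difference
Hessian of the marginal log-likelihood. The differencing step is a fixed
relative 1e-4 — large enough to dominate the numerical noise of the inner
Newton solver, which machine-epsilon-scaled differencing does not tolerate.
Per-assemblage slopes are conditional modes β1 + b1_i; their reported
standard error combines the conditional variance of b1_i with the Wald
variance of β1 and is approximate (it ignores the covariance between the
two), which is adequate for the three-way positive / negative /
indeterminate classification it feeds.

**Boundary covariances.** When the slope random effect is weakly identified,
the ML estimate of Σ often lands on the boundary (|correlation| → 1). The
fit is retained and flagged `singular_covariance` rather than refitted with a
diagonal Σ: calibration experiments on data simulated from the model itself
showed that collapsing to a diagonal covariance at the boundary drags the
slope variance to zero and understates the overall-slope standard error by
~40% (interval coverage 75% instead of ~95%), whereas the retained boundary
fit matches an independent mixed-model implementation. A diagonal refit
happens only when the unstructured optimization fails numerically.

**Shrinkage caveat.** Per-assemblage conditional modes are shrunk towards β1
in proportion to how weakly each assemblage identifies its own slope. When
assemblages are near-replicates (as in the synthetic presets, where the only
between-assemblage differences are sampling and immigration randomness), the
shrunk slopes are noise-dominated and their cross-metric correlations are not
meaningful — the directional claims about the scenario presets are therefore
checked on the generator's noise-free trajectories, where the signal is not
shrunk away. Real monitoring data, with genuinely heterogeneous ecosystems,
put far more variance into the random slopes.

## Slope correlations and sensitivity

Per-assemblage slopes from two fits are paired on the common assemblages and
summarized by Pearson's r (≥3 pairs, non-degenerate variance required). The
default pairs are rarity–richness, rarity–size, richness–size, plus
rarity–singletons and rarity–Fisher's α as metric-agreement checks. The
sensitivity analysis removes `round(f·n)` randomly chosen assemblages
(f = 0.05, 0.10, 0.20 by default; `round` semantics are kept, so a fraction
small enough to round to zero removes nothing) and recomputes r, 200 times,
reporting the replicate distribution with its median and 2.5/97.5 percentile
band. Correlations are computed on point estimates of the slopes; no
correction for their estimation error is attempted.

## Rare-population classification

Populations selected are those of species whose rarefied abundance was 1 or 2
in at least one year; the full trajectory is kept (values may exceed 2), and
years in which the assemblage was sampled but the species absent are explicit
zeros. The presence string (abundance > 0) is tested with a two-sided
Wald–Wolfowitz runs test (normal approximation, no continuity correction,
matching the standard reference implementation; verified identical to
`statsmodels`' independent routine):

    E[R] = 1 + 2·n1·n0/n,  Var[R] = 2·n1·n0·(2·n1·n0 − n)/(n²(n−1)),
    z = (R − E[R])/√Var[R],  p = 2·Φ(−|z|)

undefined (NaN) when the string has a single level. Classification rules, in
order: never absent → persistent; runs test undefined or p ≥ α (default
0.05, configurable) → persistent, treating transitions as detection noise;
otherwise one immigration and no extinction → immigration, the reverse →
extinction, and two or more events in total → multiple (this covers strings
such as `1101` that both start and end present). Categories always partition
the selected populations.

The normal approximation is asymptotic. For short strings the run-count
distribution has only a handful of support points, and no tail-probability
comparison with exact enumeration can be uniformly tight: the worst-case
absolute difference between the approximate and enumerated two-sided p over
all strings of length ≤ 12 is ≈ 0.68 (driven by strings with a one-symbol
minority, where the exact two-sided p is 1), and ≈ 0.15 even within the
p ≤ 0.05 decision region. The acceptance suite measures and reports this
discrepancy honestly; the practical consequence is that very short strings
essentially never pass the significance gate, which is conservative — the
gate exists precisely to avoid over-counting turnover events.

## Synthetic scenarios

Each assemblage starts from `n_species_pool` species whose initial expected
abundances are drawn from a log-series distribution with parameter
`sad_alpha` (the implied community size is N = α·(e^{S/α} − 1), and the
log-series shape parameter follows as x = N/(N+α)). Species s follows
λ_s(t) = λ_s(0)·e^{b_s·t} with b_s ~ N(trend_mean, trend_sd²). Immigrants
arrive as a Poisson(immigration_rate) process per year, starting at expected
abundance `arrival_abundance` (1 by default: new arrivals are rare).
Extinction is either absent (λ floored at `lambda_floor` = 0.5 so residents
never vanish) or triggered by `extinction_runs` (default 2) consecutive years
of zero sampled abundance, after which λ = 0 — a mechanism chosen for
controllability, since only the qualitative outcomes are specified by the
scenario logic. The observation layer splits λ evenly over that year's
sampling occasions (a uniform draw from `samples_per_year`) with independent
Poisson counts per occasion, or fixes the yearly total via a multinomial for
size-controlled experiments.

Ground truth records per-species slopes, arrival and extinction years, and
two kinds of per-assemblage noise-free trajectories: *latent* (count of
species with 0 < λ ≤ 2, count with λ > 0, and Σλ) and the *expected sampled
rarity* Σ_s P(Poisson(λ_s) ∈ {1,2}), whose log-scale OLS slope is the exact
estimand of the negative-binomial trend model on these data and is the truth
used in recovery experiments.

Preset conditions: 60 assemblages × 20 years, 150-species pool, sad_alpha 30
(mean initial abundance ≈ 29), trend_sd 0.01, two occasions per year (constant
effort inside the presets, so the standardization step is the identity and
truth stays directly comparable; varying-effort configurations exercise the
rarefaction machinery in the tests). `fig1a`/`fig1b` use trend_mean −0.03
(3% yearly population decline); `fig2` uses trend_mean 0 with
immigration_rate 0.55 per assemblage-year, calibrated analytically so the
global log-scale rarity slope is ≈ +0.01 per year — a gentle, realistic
signal (≈ 1% per year) against a baseline of ≈ 30 expected rare species.

The generator emulates skewed abundance distributions, log-linear population
trends, colonization/extinction and uneven effort. It does not emulate
detection heterogeneity among species, temporal autocorrelation of sampling
conditions, seasonality, or among-assemblage differences in community
structure — so passing recovery tests demonstrate correctness of the
estimators under the stated generative assumptions, not robustness to every
feature of real monitoring data.

## Fixture factory for the classifier

`generate_population_strings` constructs presence strings whose run structure
realizes a requested label (long clean blocks for immigration/extinction,
alternating blocks for multiple), plus a `gate_limited` flag for strings too
short for the runs test to reach significance (e.g. `0011`: p ≈ 0.22, so the
classifier correctly calls it persistent). Accuracy is scored only on strings
whose construction can pass the gate.

## Numerical and reproducibility choices

* All RNG streams are numpy `SeedSequence`-derived from a single base seed;
  identical configuration and seed give byte-identical artifacts.
* The NB mean is computed as exp(clip(η, ±30)) to avoid overflow during
  optimization; θ is log-parameterized and bounded in [e⁻⁵, e¹⁶] (the upper
  bound is the effectively-Poisson regime, reached e.g. for constant counts).
* Inner Newton: convergence at gradient ∞-norm < 1e-8 or step gain < 1e-11,
  with per-group step halving (≤12 halvings).
* Pipeline problem sizes used in tests and the acceptance script (50
  replicates of 60 × 20 for recovery; 25 × 10 for the per-family coverage
  sweeps) were chosen to make the Monte-Carlo acceptance bounds (≥95% sign
  recovery, ≥85% coverage) statistically meaningful at desk scale.

## Known limitations

* Wald intervals, not profile or posterior intervals; for variance
  parameters near boundaries Wald theory is approximate (the slope fixed
  effect, which is what the pipeline reports, is well calibrated in the
  simulation checks: empirical z-scores ≈ N(0,1), coverage 94–96%).
* The Laplace approximation for the negative binomial is standard but not
  exact; agreement with pooled GLMs (random effects pinned) and interval
  coverage on simulated data are the implemented accuracy checks.
* The runs-test gate is conservative for short series (see above).
* No detection-probability modelling, no temporal autocorrelation structures,
  no abundance-distribution model comparison.
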
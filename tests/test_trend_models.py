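import logging

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from raretrends import trend_models as tm

logging.disable(logging.INFO)


def test_spec_assigns_family_by_response():
    assert tm.TrendModelSpec("n_rare").family == "negative_binomial"
    assert tm.TrendModelSpec("log10_size").family == "gaussian"
    assert tm.TrendModelSpec("fisher_alpha").family == "gaussian_power_variance"
    with pytest.raises(ValueError):
        tm.TrendModelSpec("abundance")


def _metrics(resp, values_by_assemblage):
    rows = []
    for aid, vals in values_by_assemblage.items():
        t = np.arange(len(vals), dtype=float)
        t -= t.mean()
        rows += [(aid, tv, v) for tv, v in zip(t, vals)]
    return pd.DataFrame(rows, columns=["assemblage_id", "centered_year", resp])


def test_constant_gaussian_response_gives_zero_slope():
    df = _metrics("log10_richness", {f"A{i}": [1.3] * 8 for i in range(5)})
    fit = tm.fit_trend(df, tm.TrendModelSpec("log10_richness"))
    assert abs(fit.beta1) < 1e-6


def test_constant_counts_slope_interval_covers_zero():
    df = _metrics("n_rare", {f"A{i}": [7] * 10 for i in range(6)})
    fit = tm.fit_trend(df, tm.TrendModelSpec("n_rare"))
    assert abs(fit.beta1) < 1e-4
    lo, hi = fit.interval95
    assert lo <= 0 <= hi


def test_pinned_random_effects_match_pooled_nb_glm():
    """With the random effects pinned at zero, the slope agrees with an
    ordinary pooled negative-binomial GLM to 3 significant figures."""
    spec = tm.TrendModelSpec("n_rare")
    df = tm.simulate_from_spec(spec, 40, 15, beta0=3.0, beta1=0.012,
                               re_sd=(1e-6, 1e-7), theta=8.0, rng=4)
    ours = tm.fit_trend(df, spec, pin_random_effects=True)
    X = sm.add_constant(df["centered_year"].to_numpy())
    glm = sm.NegativeBinomial(df["n_rare"].to_numpy(), X).fit(disp=0)
    assert ours.beta1 == pytest.approx(glm.params[1], rel=2e-3)


def test_pinned_random_effects_match_ols():
    spec = tm.TrendModelSpec("log10_size")
    df = tm.simulate_from_spec(spec, 30, 12, beta0=2.0, beta1=0.004,
                               re_sd=(1e-6, 1e-7), sigma=0.05, rng=5)
    ours = tm.fit_trend(df, spec, pin_random_effects=True)
    slope = np.polyfit(df["centered_year"], df["log10_size"], 1)[0]
    assert ours.beta1 == pytest.approx(slope, rel=1e-3)


def test_gaussian_fit_matches_statsmodels_mixedlm():
    """Dual-route check of the Gaussian mixed model against statsmodels
    MixedLM (ML, random intercept + slope, free covariance)."""
    spec = tm.TrendModelSpec("log10_richness")
    df = tm.simulate_from_spec(spec, 30, 12, beta0=1.5, beta1=0.003,
                               re_sd=(0.2, 0.004), sigma=0.03, rng=6)
    ours = tm.fit_trend(df, spec)
    m = sm.MixedLM.from_formula(
        "log10_richness ~ centered_year", df, groups=df["assemblage_id"],
        re_formula="~centered_year",
    ).fit(reml=False)
    assert ours.beta1 == pytest.approx(m.params["centered_year"], abs=1e-5)
    assert ours.beta0 == pytest.approx(m.params["Intercept"], abs=1e-5)


def test_extract_slopes_is_additive():
    fit = tm.TrendFit(
        response="n_rare", family="negative_binomial", beta0=0.0, beta1=0.005,
        interval95=(0.001, 0.009), dispersion={}, random_effect_sd=(0.1, 0.01, 0.0),
        assemblage_slopes={"A": 0.007, "B": 0.003},
        assemblage_slope_se={"A": 0.001, "B": 0.001}, converged=True,
    )
    assert tm.extract_assemblage_slopes(fit) == {"A": 0.007, "B": 0.003}


def test_predicted_deviations_average_near_zero_and_shrink():
    spec = tm.TrendModelSpec("log10_size")
    rng = np.random.default_rng(8)
    df = tm.simulate_from_spec(spec, 40, 6, beta0=2.0, beta1=0.01,
                               re_sd=(0.1, 0.02), sigma=0.2, rng=rng)
    fit = tm.fit_trend(df, spec)
    devs = np.array(list(fit.assemblage_slopes.values())) - fit.beta1
    assert abs(devs.mean()) < 5e-3
    # shrinkage: predicted slopes are closer to beta1 than per-assemblage OLS
    ols = df.groupby("assemblage_id").apply(
        lambda d: np.polyfit(d["centered_year"], d["log10_size"], 1)[0],
        include_groups=False,
    )
    ols_devs = ols.to_numpy() - fit.beta1
    assert np.mean(np.abs(devs)) < np.mean(np.abs(ols_devs))
    assert np.corrcoef(devs, ols_devs)[0, 1] > 0.8


def test_strong_trend_assemblage_ranks_first():
    spec = tm.TrendModelSpec("log10_richness")
    rng = np.random.default_rng(9)
    rows = []
    t = np.arange(12, dtype=float) - 5.5
    for i in range(12):
        slope = 0.03 if i == 0 else 0.0
        y = 1.5 + slope * t + rng.normal(0, 0.01, 12)
        rows += [(f"A{i:02d}", tv, v) for tv, v in zip(t, y)]
    df = pd.DataFrame(rows, columns=["assemblage_id", "centered_year", "log10_richness"])
    fit = tm.fit_trend(df, spec)
    assert max(fit.assemblage_slopes, key=fit.assemblage_slopes.get) == "A00"


def test_trend_classification_by_interval():
    fit = tm.TrendFit(
        response="n_rare", family="negative_binomial", beta0=0.0, beta1=0.0,
        interval95=(-1, 1), dispersion={}, random_effect_sd=(0, 0, 0),
        assemblage_slopes={"up": 0.0055, "flat": -0.0005, "down": -0.0055},
        assemblage_slope_se={"up": 0.0055 / 3.0, "flat": 0.0018, "down": 0.0055 / 3.0},
        converged=True,
    )
    cls = tm.classify_assemblage_trends(fit)
    assert cls == {"up": "positive", "flat": "indeterminate", "down": "negative"}


def test_fold_change_back_transformation():
    assert tm.fold_change_per_year(0.0) == 1.0
    assert tm.fold_change_per_year(1.0) == 10.0
    assert tm.fold_change_per_year(0.003, digits=None) == pytest.approx(10 ** 0.003)


@pytest.mark.parametrize(
    "resp,kw",
    [
        ("n_rare", dict(beta0=3.0, beta1=0.01, re_sd=(0.3, 0.005), theta=5.0)),
        ("n_singletons", dict(beta0=2.5, beta1=0.008, re_sd=(0.3, 0.005), theta=5.0)),
        ("log10_richness", dict(beta0=1.5, beta1=0.0025, re_sd=(0.2, 0.003), sigma=0.03)),
        ("log10_size", dict(beta0=2.5, beta1=0.003, re_sd=(0.3, 0.004), sigma=0.05)),
        ("fisher_alpha", dict(beta0=10.0, beta1=0.05, re_sd=(2.0, 0.02), sigma=0.15, delta=0.5)),
    ],
)
def test_interval_coverage_on_model_generated_data(resp, kw):
    """Simulating from the model's own generative form, the 95% Wald interval
    for the overall slope covers truth in >= 85% of 50 replicates."""
    spec = tm.TrendModelSpec(resp)
    covered = 0
    for i in range(50):
        df = tm.simulate_from_spec(spec, 25, 10, rng=1000 + i, **kw)
        fit = tm.fit_trend(df, spec)
        lo, hi = fit.interval95
        covered += lo <= kw["beta1"] <= hi
    assert covered >= 0.85 * 50
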
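"""Mixed-effect trend models: one overall slope per biodiversity facet plus
per-assemblage rates of change from the random effects.

Each yearly metric is regressed against mean-centred year with a random
intercept and random slope per assemblage, so a single overall slope (beta1)
summarizes the global trend while each assemblage's own rate of change is
beta1 plus its predicted random-slope deviation (conditional mode / BLUP).

Families per response:

======================  ==========================================
``n_rare``              negative binomial, log link
``n_singletons``        negative binomial, log link
``fisher_alpha``        Gaussian, power-of-fitted-value variance
``log10_richness``      Gaussian
``log10_size``          Gaussian
======================  ==========================================

Slopes on the log10 responses are multiplicative rates:
:func:`fold_change_per_year` back-transforms a slope b to 10**b, the yearly
fold change (e.g. a richness slope of 0.0043/yr is a 1.010-fold yearly
increase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._glmm import FittingError, GLMMResult, fit_glmm, fit_glmm_power_variance

__all__ = [
    "TrendModelSpec", "TrendFit", "FittingError", "RESPONSES",
    "fit_trend", "extract_assemblage_slopes", "classify_assemblage_trends",
    "fold_change_per_year", "simulate_from_spec",
]

RESPONSES = {
    "n_rare": "negative_binomial",
    "n_singletons": "negative_binomial",
    "fisher_alpha": "gaussian_power_variance",
    "log10_richness": "gaussian",
    "log10_size": "gaussian",
}


@dataclass(frozen=True)
class TrendModelSpec:
    """Which yearly metric to model; the error family follows the response."""

    response: str

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}; choose from {sorted(RESPONSES)}")

    @property
    def family(self) -> str:
        return RESPONSES[self.response]


@dataclass
class TrendFit:
    """Fitted trend model for one response."""

    response: str
    family: str
    beta0: float
    beta1: float
    interval95: tuple[float, float]
    dispersion: dict
    random_effect_sd: tuple[float, float, float]  # (sd_int, sd_slope, corr)
    assemblage_slopes: dict[str, float]
    assemblage_slope_se: dict[str, float]
    converged: bool
    singular_covariance: bool = False
    diagonal_fallback: bool = False
    diagnostics: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """One row per assemblage: slope, 95% interval, trend classification."""
        cls = classify_assemblage_trends(self)
        rows = []
        for aid, s in self.assemblage_slopes.items():
            se = self.assemblage_slope_se[aid]
            rows.append((aid, s, s - 1.96 * se, s + 1.96 * se, cls[aid]))
        return pd.DataFrame(rows, columns=["assemblage_id", "slope", "lower95", "upper95", "classification"])

    def report(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "interval95": list(self.interval95),
            "dispersion": self.dispersion,
            "random_effect_sd": list(self.random_effect_sd),
            "converged": self.converged,
            "singular_covariance": self.singular_covariance,
            "diagonal_fallback": self.diagonal_fallback,
            "diagnostics": self.diagnostics,
        }


def _coerce_frame(metrics) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:  # iterable of YearlyMetrics
        df = pd.DataFrame([m.__dict__ for m in metrics])
    if "log10_richness" not in df.columns and "richness_S" in df.columns:
        df["log10_richness"] = np.log10(df["richness_S"])
    if "log10_size" not in df.columns and "size_N" in df.columns:
        df["log10_size"] = np.log10(df["size_N"])
    return df


def fit_trend(metrics, spec: TrendModelSpec, pin_random_effects: bool = False) -> TrendFit:
    """Fit the mixed trend model for one response.

    ``metrics`` is a yearly-metrics table (DataFrame with columns
    ``assemblage_id, centered_year`` and the response, as produced by
    :func:`raretrends.rarity_metrics.metrics_frame`) or an iterable of
    ``YearlyMetrics``. Requires >= 2 assemblages with >= 2 distinct years
    each. Rows with a missing response (e.g. degenerate Fisher's alpha
    years) are dropped.
    """
    df = _coerce_frame(metrics)
    need = {"assemblage_id", "centered_year", spec.response}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    df = df.dropna(subset=[spec.response])
    ok = df.groupby("assemblage_id")["centered_year"].nunique()
    keep = ok[ok >= 2].index
    df = df[df["assemblage_id"].isin(keep)]
    if df["assemblage_id"].nunique() < 2:
        raise ValueError("need >= 2 assemblages with >= 2 distinct years each")
    y = df[spec.response].to_numpy(float)
    if spec.family == "negative_binomial":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError(f"{spec.response} must be non-negative integer counts")
    t = df["centered_year"].to_numpy(float)
    g = df["assemblage_id"].astype(str).to_numpy()

    if spec.family == "negative_binomial":
        res = fit_glmm(y, t, g, "nb", pin_re_zero=pin_random_effects)
    elif spec.family == "gaussian":
        res = fit_glmm(y, t, g, "gaussian", pin_re_zero=pin_random_effects)
    else:
        res = fit_glmm_power_variance(y, t, g)
    return _to_trendfit(res, spec)


def _to_trendfit(res: GLMMResult, spec: TrendModelSpec) -> TrendFit:
    z = norm.ppf(0.975)
    beta1, se1 = float(res.beta[1]), float(res.se_beta[1])
    slopes = {str(gid): beta1 + float(res.blups[i, 1]) for i, gid in enumerate(res.group_ids)}
    # assemblage-level uncertainty: conditional variance of the deviation
    # plus the Wald variance of the overall slope (approximate, documented)
    sl_se = {
        str(gid): float(np.sqrt(res.blup_cond_var[i, 1] + se1 ** 2))
        for i, gid in enumerate(res.group_ids)
    }
    return TrendFit(
        response=spec.response,
        family=spec.family,
        beta0=float(res.beta[0]),
        beta1=beta1,
        interval95=(beta1 - z * se1, beta1 + z * se1),
        dispersion=res.dispersion,
        random_effect_sd=res.re_sd,
        assemblage_slopes=slopes,
        assemblage_slope_se=sl_se,
        converged=res.converged,
        singular_covariance=res.singular_covariance,
        diagonal_fallback=res.diagonal_fallback,
        diagnostics=res.diagnostics,
    )


def extract_assemblage_slopes(fit: TrendFit) -> dict[str, float]:
    """Per-assemblage rate of change: overall slope + predicted deviation."""
    return dict(fit.assemblage_slopes)


def classify_assemblage_trends(fit: TrendFit) -> dict[str, str]:
    """Label each assemblage positive / negative / indeterminate by whether
    its slope's 95% interval excludes zero."""
    out = {}
    for aid, s in fit.assemblage_slopes.items():
        se = fit.assemblage_slope_se[aid]
        lo, hi = s - 1.96 * se, s + 1.96 * se
        out[aid] = "positive" if lo > 0 else ("negative" if hi < 0 else "indeterminate")
    return out


def fold_change_per_year(slope: float, digits: int | None = 3) -> float:
    """Back-transform a log10-scale yearly slope to a yearly fold change.

    A mixed-model slope b on a log10 response means the metric is multiplied
    by 10**b each year; ``fold_change_per_year(0.0043)`` -> 1.010.
    """
    fc = 10.0 ** slope
    return round(fc, digits) if digits is not None else fc


def simulate_from_spec(
    spec: TrendModelSpec,
    n_assemblages: int,
    n_years: int,
    beta0: float,
    beta1: float,
    re_sd: tuple[float, float] = (0.3, 0.005),
    theta: float = 5.0,
    sigma: float = 0.05,
    delta: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Draw a metrics table from the trend model's own generative form.

    Used by parameter-recovery harnesses: the returned frame has columns
    ``assemblage_id, centered_year`` and the response, generated with known
    fixed effects, independent Gaussian random intercepts/slopes and the
    response family of ``spec``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = np.arange(n_years, dtype=float)
    t -= t.mean()
    rows = []
    for i in range(n_assemblages):
        b0 = rng.normal(0.0, re_sd[0])
        b1 = rng.normal(0.0, re_sd[1])
        eta = (beta0 + b0) + (beta1 + b1) * t
        if spec.family == "negative_binomial":
            mu = np.exp(eta)
            y = rng.negative_binomial(theta, theta / (theta + mu))
        elif spec.family == "gaussian":
            y = eta + rng.normal(0.0, sigma, size=n_years)
        else:
            y = eta + rng.normal(0.0, sigma * np.abs(eta) ** delta, size=n_years)
        for j in range(n_years):
            rows.append((f"A{i:03d}", t[j], y[j]))
    return pd.DataFrame(rows, columns=["assemblage_id", "centered_year", spec.response])
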
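"""Maximum-likelihood mixed models with a random intercept and slope per group.

The marginal likelihood integrates a bivariate Gaussian random effect
(intercept, slope) out of the per-group likelihood with a Laplace
approximation: the integrand is maximized over the 2-D random effect by a
damped Newton iteration (the conditional log-density is strictly concave for
the families used here) and the Gaussian curvature correction is applied.
For Gaussian responses the approximation is exact, so those fits are plain
maximum likelihood; for the negative binomial family it is the standard
Laplace GLMM objective.

Families
--------
``nb``        negative binomial, log link, Var = mu + mu^2/theta
``gaussian``  identity link, homoscedastic
``gaussian_power``  identity link, Var(eps_ij) = sigma^2 * |mu_ij|^(2*delta)
              with the variance covariate |mu| held at the previous outer
              iteration's fitted values (estimated-weights scheme)

Parameterization of the random-effect covariance is a log-Cholesky factor
``L = [[exp(a), 0], [c, exp(b)]]``, Sigma = L L'. A ``diagonal=True`` mode
fixes ``c = 0`` and is used as the fallback when the full covariance is
singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

_LOG2PI = np.log(2.0 * np.pi)


class FittingError(RuntimeError):
    """Optimizer failed to converge; carries diagnostics in ``.info``."""

    def __init__(self, msg: str, info: dict | None = None):
        super().__init__(msg)
        self.info = info or {}


@dataclass
class GLMMResult:
    beta: np.ndarray                      # (2,) intercept, slope
    se_beta: np.ndarray                   # (2,) Wald standard errors
    dispersion: dict                      # family-specific: theta / sigma / delta
    re_sd: tuple                          # (sd_intercept, sd_slope, correlation)
    blups: np.ndarray                     # (G, 2) conditional modes
    blup_cond_var: np.ndarray             # (G, 2) conditional variances (diag)
    group_ids: list                       # group labels in blup order
    loglik: float
    converged: bool
    singular_covariance: bool = False     # RE covariance at the boundary (|corr|~1)
    diagonal_fallback: bool = False       # full-covariance fit failed numerically
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# family kernels: loglik, first derivative wrt eta, and curvature weight
# w = -d2 loglik / d eta^2 (>= 0), all vectorized with a validity mask
# ---------------------------------------------------------------------------

def _nb_ll(y, eta, theta):
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu)))


def _nb_d1(y, eta, theta):
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    return y - (y + theta) * mu / (mu + theta)


def _nb_w(y, eta, theta):
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    return (y + theta) * theta * mu / (mu + theta) ** 2


def _gauss_ll(y, eta, v):
    return -0.5 * (_LOG2PI + np.log(v)) - (y - eta) ** 2 / (2.0 * v)


class _Problem:
    """Padded per-group arrays and family evaluation for one model fit."""

    def __init__(self, y, t, groups, family, var_covariate=None, diagonal=False):
        self.family = family
        self.diagonal = diagonal
        labels, inv = np.unique(np.asarray(groups), return_inverse=True)
        self.group_ids = list(labels)
        G = len(labels)
        sizes = np.bincount(inv, minlength=G)
        nmax = int(sizes.max())
        self.Y = np.zeros((G, nmax))
        self.T = np.zeros((G, nmax))
        self.M = np.zeros((G, nmax), dtype=bool)
        self.C = np.ones((G, nmax))  # variance covariate |mu_hat| for gaussian_power
        fill = np.zeros(G, dtype=int)
        cv = np.ones(len(y)) if var_covariate is None else np.asarray(var_covariate, float)
        for j in range(len(y)):
            g = inv[j]
            k = fill[g]
            self.Y[g, k] = y[j]
            self.T[g, k] = t[j]
            self.M[g, k] = True
            self.C[g, k] = max(abs(cv[j]), 1e-6)
            fill[g] += 1
        self.G, self.nmax = G, nmax
        # map from padded cells back to original row order (for fitted values)
        self._orig_index = np.full((G, nmax), -1, dtype=int)
        fill[:] = 0
        for j in range(len(y)):
            g = inv[j]
            self._orig_index[g, fill[g]] = j
            fill[g] += 1
        self.n_obs = len(y)

    # parameter packing: [beta0, beta1, disp..., chol...]
    def n_disp(self):
        return {"nb": 1, "gaussian": 1, "gaussian_power": 2}[self.family]

    def n_chol(self):
        return 2 if self.diagonal else 3

    def unpack(self, x):
        beta = x[:2]
        disp = x[2:2 + self.n_disp()]
        ch = x[2 + self.n_disp():]
        a, b = ch[0], ch[1]
        c = 0.0 if self.diagonal else ch[2]
        L = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
        Sigma = L @ L.T
        return beta, disp, Sigma

    def _variance(self, disp):
        if self.family == "gaussian":
            return np.exp(2.0 * disp[0]) * np.ones_like(self.C)
        # gaussian_power: sigma^2 * c^(2 delta)
        return np.exp(2.0 * disp[0]) * self.C ** (2.0 * disp[1])

    def _eval(self, eta, disp):
        """(loglik, d1, w) arrays, masked cells zeroed."""
        if self.family == "nb":
            theta = np.exp(disp[0])
            ll = _nb_ll(self.Y, eta, theta)
            d1 = _nb_d1(self.Y, eta, theta)
            w = _nb_w(self.Y, eta, theta)
        else:
            v = self._variance(disp)
            ll = _gauss_ll(self.Y, eta, v)
            d1 = (self.Y - eta) / v
            w = 1.0 / v
        z = ~self.M
        ll[z] = 0.0
        d1[z] = 0.0
        w[z] = 0.0
        return ll, d1, w

    def _eta(self, beta, b):
        return (beta[0] + b[:, 0:1]) + (beta[1] + b[:, 1:2]) * self.T

    def _h_of(self, beta, disp, Sinv, bcur):
        if self.family == "nb":
            theta = np.exp(disp[0])
            ll = _nb_ll(self.Y, self._eta(beta, bcur), theta)
        else:
            ll = _gauss_ll(self.Y, self._eta(beta, bcur), self._variance(disp))
        ll[~self.M] = 0.0
        quad = np.einsum("gi,ij,gj->g", bcur, Sinv, bcur)
        return ll.sum(axis=1) - 0.5 * quad

    def inner_mode(self, beta, disp, Sigma, b0=None, tol=1e-8, maxit=40):
        """Damped Newton for the conditional modes of all groups at once.

        Returns (b_hat, h(b_hat) per group, M = Z'WZ + Sigma^-1 per group).
        The conditional log-density h is concave for every family here, so a
        per-group step-halving safeguard suffices.
        """
        Sinv = np.linalg.inv(Sigma)
        b = np.zeros((self.G, 2)) if b0 is None else b0.copy()
        h = self._h_of(beta, disp, Sinv, b)
        for _ in range(maxit):
            eta = self._eta(beta, b)
            _, d1, w = self._eval(eta, disp)
            g0 = d1.sum(axis=1) - (b @ Sinv)[:, 0]
            g1 = (d1 * self.T).sum(axis=1) - (b @ Sinv)[:, 1]
            if max(np.max(np.abs(g0)), np.max(np.abs(g1))) < tol:
                break
            m00 = w.sum(axis=1) + Sinv[0, 0]
            m01 = (w * self.T).sum(axis=1) + Sinv[0, 1]
            m11 = (w * self.T ** 2).sum(axis=1) + Sinv[1, 1]
            det = m00 * m11 - m01 ** 2
            s = np.stack([(m11 * g0 - m01 * g1) / det, (m00 * g1 - m01 * g0) / det], axis=1)
            step = np.ones(self.G)
            for _ in range(12):
                bn = b + step[:, None] * s
                hn = self._h_of(beta, disp, Sinv, bn)
                bad = hn < h - 1e-9
                if not bad.any():
                    break
                step[bad] *= 0.5
            good = hn >= h - 1e-9
            if not good.any():
                break
            gain = np.max(hn[good] - h[good])
            b[good] = bn[good]
            h[good] = hn[good]
            if gain < 1e-11:
                break
        eta = self._eta(beta, b)
        _, _, w = self._eval(eta, disp)
        m00 = w.sum(axis=1) + Sinv[0, 0]
        m01 = (w * self.T).sum(axis=1) + Sinv[0, 1]
        m11 = (w * self.T ** 2).sum(axis=1) + Sinv[1, 1]
        Mmat = np.stack([m00, m01, m01, m11], axis=1).reshape(self.G, 2, 2)
        return b, h, Mmat

    def marginal_negll(self, x, warm):
        beta, disp, Sigma = self.unpack(x)
        # guard against numerically singular Sigma
        sign, logdetS = np.linalg.slogdet(Sigma)
        if sign <= 0 or not np.all(np.isfinite(Sigma)):
            return 1e12
        b, h, Mmat = self.inner_mode(beta, disp, Sigma, b0=warm.get("b"))
        warm["b"] = b
        det = Mmat[:, 0, 0] * Mmat[:, 1, 1] - Mmat[:, 0, 1] ** 2
        if np.any(det <= 0) or not np.all(np.isfinite(h)):
            return 1e12
        ll = np.sum(h - 0.5 * logdetS - 0.5 * np.log(det))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def fitted_eta(self, beta, b):
        eta = self._eta(beta, b)
        out = np.empty(self.n_obs)
        out[self._orig_index[self.M]] = eta[self.M]
        return out


def _num_hess(f, x, eps=1e-4, n_active=None):
    """Central-difference Hessian with per-parameter relative steps."""
    x = np.asarray(x, float)
    n = len(x) if n_active is None else n_active
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.zeros((len(x), len(x)))
    f0 = f(x)

    def fx(dx):
        return f(x + dx)

    for i in range(n):
        ei = np.zeros(len(x))
        ei[i] = h[i]
        H[i, i] = (fx(ei) - 2.0 * f0 + fx(-ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(len(x))
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fx(ei + ej) - fx(ei - ej) - fx(-ei + ej) + fx(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _start_values(y, t, groups, family, diagonal):
    """Data-driven starting point: per-group OLS on a working response."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    work = np.log(y + 0.5) if family == "nb" else y
    labels = np.unique(np.asarray(groups))
    ints, slopes = [], []
    for g in labels:
        m = np.asarray(groups) == g
        if m.sum() >= 2 and np.ptp(t[m]) > 0:
            c = np.polyfit(t[m], work[m], 1)
            ints.append(c[1])
            slopes.append(c[0])
        else:
            ints.append(work[m].mean())
            slopes.append(0.0)
    b0, b1 = float(np.mean(ints)), float(np.mean(slopes))
    sd_i = max(float(np.std(ints)), 1e-3)
    sd_s = max(float(np.std(slopes)) * 0.5, 1e-4)
    x = [b0, b1]
    if family == "nb":
        # crude moment start for theta from pooled residual overdispersion
        mu = np.exp(np.clip(b0 + b1 * t, -30, 30))
        excess = np.mean((y - mu) ** 2 - mu)
        theta0 = np.clip(np.mean(mu) ** 2 / excess if excess > 0 else 50.0, 0.1, 1e4)
        x.append(np.log(theta0))
    elif family == "gaussian":
        x.append(np.log(max(np.std(work), 1e-4)))
    else:
        x += [np.log(max(np.std(work), 1e-4)), 0.0]
    x += [np.log(sd_i), np.log(sd_s)]
    if not diagonal:
        x.append(0.0)
    return np.array(x)


def fit_glmm(
    y,
    t,
    groups,
    family: str,
    var_covariate=None,
    diagonal: bool = False,
    pin_re_zero: bool = False,
) -> GLMMResult:
    """Fit the random-intercept, random-slope mixed model by (Laplace) ML.

    Parameters
    ----------
    y, t, groups
        Response, centered-time predictor and group labels, equal length.
    family
        ``"nb"``, ``"gaussian"`` or ``"gaussian_power"``.
    var_covariate
        Fitted-value magnitudes for the power-variance family (ignored
        otherwise); held fixed during this fit.
    diagonal
        Force independent random intercept and slope.
    pin_re_zero
        Pin both random-effect standard deviations at a negligible value, so
        the fit reduces to an ordinary (pooled) GLM; used for equivalence
        checks against plain GLM fits.

    A random-effect covariance estimated on the boundary (|correlation| ~ 1,
    common when the slope variance is weakly identified) is retained and
    flagged ``singular_covariance`` — collapsing it to a diagonal structure
    systematically shrinks the slope variance toward zero and understates the
    uncertainty of the overall slope. A diagonal refit happens only when the
    unstructured optimization fails numerically (``diagonal_fallback``).

    A near-singular full covariance (|correlation| above
    ``corr_singular_threshold``) triggers an automatic refit with a diagonal
    covariance, recorded as ``diagonal_fallback=True``.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if pin_re_zero:
        diagonal = True
    prob = _Problem(y, t, groups, family, var_covariate=var_covariate, diagonal=diagonal)
    x0 = _start_values(y, t, groups, family, diagonal)
    warm: dict = {}
    bounds = [(None, None), (None, None)]
    bounds += {"nb": [(-5.0, 16.0)],
               "gaussian": [(-13.0, 6.0)],
               "gaussian_power": [(-13.0, 6.0), (-4.0, 4.0)]}[family]
    if pin_re_zero:
        bounds += [(-12.0, -12.0), (-12.0, -12.0)]
        x0[-2:] = -12.0
    else:
        bounds += [(-13.0, 4.0), (-13.0, 4.0)]
    if not diagonal:
        bounds += [(-40.0, 40.0)]

    res = minimize(prob.marginal_negll, x0, args=(warm,), method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        if not diagonal:
            out = fit_glmm(y, t, groups, family, var_covariate=var_covariate, diagonal=True,
                           pin_re_zero=pin_re_zero)
            out.diagonal_fallback = True
            return out
        raise FittingError("marginal likelihood not finite at optimum",
                           {"message": res.message, "x": res.x.tolist()})

    beta, disp, Sigma = prob.unpack(res.x)
    sd_i, sd_s = np.sqrt(Sigma[0, 0]), np.sqrt(Sigma[1, 1])
    corr = Sigma[0, 1] / (sd_i * sd_s) if sd_i > 0 and sd_s > 0 else 0.0
    singular = bool((not diagonal) and (abs(corr) > 0.999 or sd_i < 1e-5 or sd_s < 1e-5))
    if singular:
        import logging

        logging.getLogger(__name__).info(
            "random-effect covariance at the boundary (corr=%.4f); retained and flagged", corr
        )

    # Wald covariance of the packed parameters via a central-difference
    # Hessian. The step must dominate the inner-solver noise in the Laplace
    # objective, so a fixed relative step is used rather than machine-epsilon
    # based differencing.
    def f(x):
        return prob.marginal_negll(x, warm)

    npar = len(res.x)
    nfree = npar - 2 if pin_re_zero else npar
    H = _num_hess(f, res.x, n_active=nfree)
    se = np.full(2, np.nan)
    try:
        cov = np.linalg.inv(H[:nfree, :nfree])
        dvar = np.diag(cov)[:2]
        if np.all(dvar > 0):
            se = np.sqrt(dvar)
    except np.linalg.LinAlgError:
        pass
    if not np.all(np.isfinite(se)):
        # fall back to the beta block with dispersion/covariance held fixed
        Hb = _num_hess(lambda bb: f(np.concatenate([bb, res.x[2:]])), res.x[:2])
        se = np.sqrt(np.diag(np.linalg.inv(Hb)))

    b, _, Mmat = prob.inner_mode(beta, disp, Sigma, b0=warm.get("b"))
    det = Mmat[:, 0, 0] * Mmat[:, 1, 1] - Mmat[:, 0, 1] ** 2
    cond_var = np.stack([Mmat[:, 1, 1] / det, Mmat[:, 0, 0] / det], axis=1)

    if family == "nb":
        dispersion = {"theta": float(np.exp(disp[0]))}
    elif family == "gaussian":
        dispersion = {"sigma": float(np.exp(disp[0]))}
    else:
        dispersion = {"sigma": float(np.exp(disp[0])), "delta": float(disp[1])}

    return GLMMResult(
        beta=beta.copy(),
        se_beta=se,
        dispersion=dispersion,
        re_sd=(float(sd_i), float(sd_s), float(corr)),
        blups=b,
        blup_cond_var=cond_var,
        group_ids=prob.group_ids,
        loglik=float(-res.fun),
        converged=bool(res.success),
        singular_covariance=singular,
        diagonal_fallback=False,
        diagnostics={"message": str(res.message), "n_iter": int(res.nit), "n_params": npar},
    )


def fit_glmm_power_variance(y, t, groups, n_outer: int = 4, tol: float = 1e-7) -> GLMMResult:
    """Gaussian mixed model with residual variance sigma^2 * |mu|^(2 delta).

    The variance covariate is the magnitude of the fitted mean, so the fit
    alternates between (i) maximizing the likelihood with the covariate held
    at the previous fitted values and (ii) refreshing the fitted values,
    until the fixed slope stabilizes.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    fit = fit_glmm(y, t, groups, "gaussian")
    prob = _Problem(y, t, groups, "gaussian")
    mu = prob.fitted_eta(fit.beta, fit.blups)
    prev = fit.beta[1]
    for _ in range(n_outer):
        fit = fit_glmm(y, t, groups, "gaussian_power", var_covariate=mu)
        prob = _Problem(y, t, groups, "gaussian_power", var_covariate=mu)
        mu = prob.fitted_eta(fit.beta, fit.blups)
        if abs(fit.beta[1] - prev) < tol:
            break
        prev = fit.beta[1]
    return fit
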
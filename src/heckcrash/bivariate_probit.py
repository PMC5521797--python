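"""Bivariate probit comparison model.

Two binary severity indicators (slight injury present, KSI present) are
modelled as correlated probits; each observation contributes an orthant
probability of the standard bivariate normal.  This is the benchmark the
selection model is compared against: it captures cross-severity error
correlation but says nothing about severity-specific crash *rates*.

The bivariate normal CDF is computed by Gauss-Legendre quadrature of the
trigonometric form of the Drezner-Wesolowsky correlation integral,

    Phi2(a, b, r) = Phi(a) Phi(b)
        + (1/2pi) \\int_0^{asin r} exp(-(a^2 - 2ab sin t + b^2)
                                        / (2 cos^2 t)) dt,

which is smooth in t and well conditioned up to |r| close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import roots_legendre
from scipy.stats import chi2, norm

from .exceptions import ConvergenceError, InvalidInputError
from .probit_stage import fit_probit

__all__ = ["BiProbitFit", "bvn_cdf", "biprobit_loglik", "fit_biprobit"]

_GL_NODES, _GL_WEIGHTS = roots_legendre(64)
_RHO_CLAMP = 0.999


@dataclass
class BiProbitFit:
    beta_slight: np.ndarray
    beta_ksi: np.ndarray
    rho: float
    rho_clamped: bool
    loglik: float
    covariance: np.ndarray            # over (beta1, beta2, rho)
    wald_independence: tuple          # (statistic, p_value) for rho = 0
    converged: bool
    n_iterations: int
    names_slight: list
    names_ksi: list

    @property
    def se(self):
        return np.sqrt(np.diag(self.covariance))


def bvn_cdf(a, b, r):
    """Standard bivariate normal CDF P(U <= a, V <= b) at correlation r.

    Vectorized over ``a`` and ``b``; absolute accuracy ~1e-14 for moderate
    |r| and better than 1e-10 up to |r| = 0.99.
    """
    if not abs(r) < 1:
        raise InvalidInputError("|r| must be < 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scalar = a.ndim == 0 and b.ndim == 0
    a, b = np.atleast_1d(a), np.atleast_1d(b)
    a, b = np.broadcast_arrays(a, b)

    base = norm.cdf(a) * norm.cdf(b)
    if r == 0.0:
        out = base
    else:
        upper = np.arcsin(r)
        t = 0.5 * upper * (_GL_NODES + 1.0)           # map [-1,1] -> [0,asin r]
        w = 0.5 * upper * _GL_WEIGHTS
        sin_t = np.sin(t)
        cos2_t = np.cos(t) ** 2
        aa = a[..., None]
        bb = b[..., None]
        integrand = np.exp(-(aa**2 - 2.0 * aa * bb * sin_t + bb**2)
                           / (2.0 * cos2_t))
        out = base + (integrand @ w) / (2.0 * np.pi)
    out = np.clip(out, 0.0, 1.0)
    return float(out[()] if out.ndim == 0 else out[0]) if scalar else out


def _bvn_pdf(a, b, r):
    """Standard bivariate normal density."""
    det = 1.0 - r**2
    z = (a**2 - 2.0 * r * a * b + b**2) / det
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(det))


def _orthant_probs(idx1, idx2, rho, s1, s2):
    """Per-row orthant probabilities P(S1=s1, S2=s2) via sign-flipped CDF."""
    q1 = 2.0 * s1 - 1.0
    q2 = 2.0 * s2 - 1.0
    w1 = q1 * idx1
    w2 = q2 * idx2
    qq = q1 * q2
    p = np.empty_like(w1)
    for sign in (1.0, -1.0):
        m = qq == sign
        if m.any():
            p[m] = bvn_cdf(w1[m], w2[m], sign * rho)
    return p, w1, w2, qq


def biprobit_loglik(beta1, beta2, rho, design):
    """Log likelihood of the joint probit.

    ``design`` carries ``(X1, s1, X2, s2)``: the two design matrices and the
    two binary outcomes, row-aligned.
    """
    X1, s1, X2, s2 = design
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if not (np.isin(s1, (0, 1)).all() and np.isin(s2, (0, 1)).all()):
        raise InvalidInputError("outcomes must be binary")
    idx1 = X1 @ np.asarray(beta1, dtype=float)
    idx2 = X2 @ np.asarray(beta2, dtype=float)
    p, *_ = _orthant_probs(idx1, idx2, rho, s1.astype(float), s2.astype(float))
    return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def _negll_grad(theta, X1, s1, X2, s2, k1, k2):
    b1 = theta[:k1]
    b2 = theta[k1:k1 + k2]
    rho = np.tanh(theta[-1])
    idx1 = X1 @ b1
    idx2 = X2 @ b2
    p, w1, w2, qq = _orthant_probs(idx1, idx2, rho, s1, s2)
    p = np.clip(p, 1e-300, None)
    ll = float(np.sum(np.log(p)))

    r = qq * rho
    root = np.sqrt(1.0 - r**2)
    # dPhi2/da = phi(a) Phi((b - r a)/sqrt(1-r^2)); symmetric in b
    g1 = norm.pdf(w1) * norm.cdf((w2 - r * w1) / root) / p
    g2 = norm.pdf(w2) * norm.cdf((w1 - r * w2) / root) / p
    q1 = 2.0 * s1 - 1.0
    q2 = 2.0 * s2 - 1.0
    gb1 = X1.T @ (q1 * g1)
    gb2 = X2.T @ (q2 * g2)
    grho = float(np.sum(qq * _bvn_pdf(w1, w2, r) / p))
    ga = grho * (1.0 - rho**2)            # chain rule to atanh scale
    return -ll, -np.concatenate([gb1, gb2, [ga]])


def fit_biprobit(X1, s1, X2, s2, gtol=1e-6, max_iter=500):
    """Fit the joint probit by BFGS on (beta1, beta2, atanh rho).

    Starts from the two univariate probit fits and rho = 0.  A correlation
    driven to the boundary (perfectly concordant outcomes) is clamped at
    +/-0.999 and flagged rather than raised.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    s1 = np.asarray(s1).astype(float)
    s2 = np.asarray(s2).astype(float)
    m1 = fit_probit(X1, s1)        # raises SeparationError on a bad margin
    m2 = fit_probit(X2, s2)
    k1, k2 = X1.shape[1], X2.shape[1]
    theta0 = np.concatenate([m1.gamma_hat, m2.gamma_hat, [0.0]])

    res = minimize(_negll_grad, theta0, args=(X1, s1, X2, s2, k1, k2),
                   jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": max_iter})
    boundary = abs(np.tanh(res.x[-1])) >= _RHO_CLAMP
    if not res.success and np.max(np.abs(res.jac)) > 1e-3 and not boundary:
        raise ConvergenceError(f"bivariate probit did not converge: "
                               f"{res.message}", last_iterate=res.x)

    theta = res.x
    rho = float(np.tanh(theta[-1]))
    clamped = bool(abs(rho) >= _RHO_CLAMP)
    if clamped:
        rho = float(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP))
    ll = -res.fun

    H = _hessian(theta, X1, s1, X2, s2, k1, k2)
    try:
        cov_int = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_int = np.linalg.pinv(H)
    J = np.eye(len(theta))
    J[-1, -1] = 1.0 - rho**2
    cov = J @ cov_int @ J.T

    v = cov_int[-1, -1]
    if np.isfinite(v) and v > 0:
        stat = float(theta[-1]**2 / v)
        wald = (stat, float(chi2.sf(stat, df=1)))
    else:
        wald = (np.nan, np.nan)

    return BiProbitFit(beta_slight=theta[:k1], beta_ksi=theta[k1:k1 + k2],
                       rho=rho, rho_clamped=clamped, loglik=ll,
                       covariance=cov, wald_independence=wald,
                       converged=True, n_iterations=int(res.nit),
                       names_slight=[f"x{j}" for j in range(k1)],
                       names_ksi=[f"x{j}" for j in range(k2)])


def _hessian(theta, X1, s1, X2, s2, k1, k2, h=1e-5):
    p = len(theta)
    H = np.zeros((p, p))
    for j in range(p):
        step = h * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = _negll_grad(tp, X1, s1, X2, s2, k1, k2)
        _, gm = _negll_grad(tm, X1, s1, X2, s2, k1, k2)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)
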
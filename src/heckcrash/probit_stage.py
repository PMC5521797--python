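"""First step of the two-step selection estimator.

A probit regression models whether a severity-specific crash rate is
observed at an intersection-year; the inverse Mills ratio evaluated at the
fitted linear index is the selection-hazard regressor the second stage
adds to the outcome equation.

All normal-CDF arithmetic runs in log space (``scipy.special.log_ndtr``) so
that extreme linear indices — routine in simulation sweeps — neither
overflow nor collapse to 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm

from .exceptions import (CollinearityError, ConvergenceError,
                         InvalidInputError, SeparationError)

__all__ = ["ProbitFit", "MillsVector", "probit_loglik", "fit_probit",
           "inverse_mills", "mills_from_fit"]

# Beyond this |index| the fitted probabilities are numerically 0/1;
# a Newton iterate out here signals separation.
_SEPARATION_INDEX = 35.0


@dataclass
class ProbitFit:
    """Probit maximum-likelihood fit by Newton-Raphson."""

    gamma_hat: np.ndarray
    covariance: np.ndarray       # inverse observed information
    loglik: float
    n_iterations: int
    converged: bool
    linear_index: np.ndarray     # z_i' gamma_hat per row

    @property
    def se(self):
        return np.sqrt(np.diag(self.covariance))


@dataclass
class MillsVector:
    """Inverse Mills ratios over the selected rows of a fit."""

    lambda_i: np.ndarray
    delta_i: np.ndarray          # lambda_i * (lambda_i + index_i), in (0, 1)
    average_mills: float


def probit_loglik(gamma, Z, s):
    """Probit log likelihood sum(s log Phi(Zg) + (1-s) log(1 - Phi(Zg)))."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    s = np.asarray(s)
    if not np.isin(s, (0, 1)).all():
        raise InvalidInputError("selection indicator must be binary")
    q = 2.0 * s - 1.0                       # +1 selected, -1 censored
    idx = Z @ np.asarray(gamma, dtype=float)
    return float(np.sum(log_ndtr(q * idx)))


def _score_info(gamma, Z, s):
    """Score vector and observed information of the probit log likelihood.

    Uses the identity d2/dc2 log Phi(qc) = -delta(qc) with
    delta(a) = lambda(a)(lambda(a) + a) in (0, 1), so the information matrix
    is always positive semidefinite.
    """
    q = 2.0 * s - 1.0
    idx = Z @ gamma
    lam_q = inverse_mills(q * idx)
    score = Z.T @ (q * lam_q)
    w = lam_q * (lam_q + q * idx)
    info = (Z * w[:, None]).T @ Z
    return score, info, idx


def fit_probit(Z, s, tol=1e-8, max_iter=100):
    """Fit a probit by Newton-Raphson on the observed information.

    Starts from gamma = 0, applies step-halving when a full Newton step does
    not improve the likelihood, and declares convergence when the gradient
    max-norm drops below ``tol``.

    Raises
    ------
    SeparationError
        When the outcome is one-class or the iterates drift to the
        numerically separated region (fitted probabilities of 0/1).
    CollinearityError
        When Z is rank deficient.
    ConvergenceError
        When ``max_iter`` Newton steps do not reach the tolerance; the last
        iterate is attached to the error.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    s = np.asarray(s)
    if not np.isin(s, (0, 1)).all():
        raise InvalidInputError("selection indicator must be binary")
    s = s.astype(float)
    if s.min() == s.max():
        raise SeparationError("selection indicator is one-class; "
                              "probit is degenerate")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError("selection design matrix is rank deficient")

    gamma = np.zeros(Z.shape[1])
    ll = probit_loglik(gamma, Z, s)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, info, idx = _score_info(gamma, Z, s)
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix; data are "
                                  "separated or design is degenerate")
        # step-halving line search
        scale, improved = 1.0, False
        for _ in range(30):
            cand = gamma + scale * step
            ll_cand = probit_loglik(cand, Z, s)
            if ll_cand >= ll - 1e-12:
                gamma, ll, improved = cand, ll_cand, True
                break
            scale *= 0.5
        if not improved or np.max(np.abs(Z @ gamma)) > _SEPARATION_INDEX:
            if np.max(np.abs(Z @ gamma)) > _SEPARATION_INDEX:
                raise SeparationError(
                    "diverging coefficients: outcome appears (quasi-)"
                    "completely separated")
            break
    else:
        raise ConvergenceError(
            f"probit did not converge in {max_iter} iterations",
            last_iterate=gamma)

    score, info, idx = _score_info(gamma, Z, s)
    converged = bool(np.max(np.abs(score)) < tol)
    if not converged:
        raise ConvergenceError("probit stalled before reaching tolerance",
                               last_iterate=gamma)
    # the MLE does not exist when the fitted index classifies every row
    # with the right sign (perfect or quasi-complete separation): the
    # likelihood keeps rising along ||gamma|| -> inf
    q = 2.0 * s - 1.0
    if np.all(q * idx >= 0) and np.any(q * idx > 0):
        raise SeparationError("outcome is (quasi-)completely separated by "
                              "the fitted index; estimates diverge")
    cov = np.linalg.inv(info)
    return ProbitFit(gamma_hat=gamma, covariance=cov,
                     loglik=probit_loglik(gamma, Z, s),
                     n_iterations=n_iter, converged=converged,
                     linear_index=idx)


def inverse_mills(index):
    """Inverse Mills ratio lambda(a) = phi(a) / Phi(a).

    Evaluated as exp(log phi - log Phi) for moderate arguments; below
    a = -25 the asymptotic expansion -a + 1/(-a) - 2/(-a)^3 + 10/(-a)^5 is
    used, avoiding the loss of precision in the difference of two large
    log terms deep in the lower tail.
    """
    a = np.asarray(index, dtype=float)
    if np.any(np.isnan(a)):
        raise InvalidInputError("inverse_mills requires finite input")
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    out = np.empty_like(a)
    deep = a < -25.0
    if deep.any():
        t = -a[deep]
        out[deep] = t + 1.0 / t - 2.0 / t**3 + 10.0 / t**5
    rest = ~deep
    if rest.any():
        ar = a[rest]
        out[rest] = np.exp(norm.logpdf(ar) - log_ndtr(ar))
    return float(out[0]) if scalar else out


def mills_from_fit(fit, selected):
    """Inverse Mills ratios of a probit fit over the selected rows.

    ``delta_i = lambda_i (lambda_i + index_i)`` — the per-row factor in both
    the probit information and the two-step variance correction — lies in
    (0, 1) for every finite index.
    """
    if not fit.converged:
        raise InvalidInputError("first-stage fit did not converge")
    selected = np.asarray(selected).astype(bool)
    if selected.sum() == 0:
        raise InvalidInputError("no selected rows")
    idx = fit.linear_index[selected]
    lam = np.atleast_1d(inverse_mills(idx))
    delta = lam * (lam + idx)
    return MillsVector(lambda_i=lam, delta_i=delta,
                       average_mills=float(lam.mean()))
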
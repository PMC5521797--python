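"""Second step of the Heckman procedure and the truncation-effect summary.

The selected-sample outcome regression is augmented with the inverse Mills
ratio from the first-stage probit:

    E[y | selected] = x'beta + (rho * sigma) * lambda(z'gamma)

Least squares on [X, lambda] over the selected rows gives consistent
estimates of beta and of the selection coefficient rho*sigma.  The outcome
error SD and error correlation are then backed out as

    sigma^2 = e'e / n1 + mean(delta_i) * b_mills^2,
    rho     = b_mills / sigma            (clamped to [-1, 1]),

with e the stage-2 residuals, n1 the selected count and
delta_i = lambda_i (lambda_i + z_i'gamma).  Standard errors use the
two-step asymptotic covariance that accounts both for the induced
heteroskedasticity (the (1 - rho^2 delta_i) weighting) and for the
first-stage estimation of gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SelectionDesign
from .exceptions import CollinearityError, InvalidInputError
from .probit_stage import MillsVector, ProbitFit, fit_probit, inverse_mills, \
    mills_from_fit

__all__ = ["TwoStepFit", "TruncationEffect", "fit_two_step",
           "truncation_effect", "predict_outcome"]


@dataclass
class TwoStepFit:
    beta_hat: np.ndarray         # outcome coefficients (incl. intercept)
    beta_mills: float            # coefficient on the inverse-Mills regressor
    sigma_hat: float
    rho_hat: float
    lambda_hat: float            # rho_hat * sigma_hat, by construction
    rho_clamped: bool
    covariance: np.ndarray       # corrected, over (beta, beta_mills)
    first_stage: ProbitFit
    mills: MillsVector
    n_selected: int
    residuals: np.ndarray
    x_names: list
    z_names: list

    @property
    def se(self):
        return np.sqrt(np.diag(self.covariance))


@dataclass
class TruncationEffect:
    """Average shift of the conditional outcome attributable to selection."""

    effect: float
    percent_shift: float         # 100 * (exp(effect) - 1)


def fit_two_step(design: SelectionDesign, tol=1e-8, max_iter=100):
    """Two-step (limited-information) estimate of the selection model.

    Steps: probit of s on Z; inverse Mills ratios on the selected rows;
    least squares of y on [X, lambda]; recovery of sigma, rho and the
    selection coefficient; corrected covariance.

    When nothing is censored (s identically 1) the selection stage carries
    no information and the Mills coefficient is unidentified: the fit
    degenerates, by construction, to plain least squares of y on X with
    rho = lambda = 0 and ``first_stage``/``mills`` set to None.
    """
    if np.all(design.s == 1):
        return _uncensored_fit(design)
    first = fit_probit(design.Z, design.s, tol=tol, max_iter=max_iter)
    sel = design.s == 1
    n1 = int(sel.sum())
    k = design.X.shape[1]
    if n1 < k + 2:
        raise InvalidInputError(
            f"need at least {k + 2} selected rows, have {n1}")

    mills = mills_from_fit(first, sel)
    y1 = design.y[sel]
    X1 = design.X[sel]
    Z1 = design.Z[sel]
    W = np.column_stack([X1, mills.lambda_i])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise CollinearityError(
            "outcome design plus Mills regressor is rank deficient")

    coef, *_ = np.linalg.lstsq(W, y1, rcond=None)
    beta, b_mills = coef[:-1], float(coef[-1])
    resid = y1 - W @ coef

    delta = mills.delta_i
    sigma2 = float(resid @ resid) / n1 + float(delta.mean()) * b_mills**2
    sigma = float(np.sqrt(sigma2))
    rho_raw = b_mills / sigma if sigma > 0 else 0.0
    clamped = abs(rho_raw) > 1.0
    rho = float(np.clip(rho_raw, -1.0, 1.0))

    # Heckman (1979) two-step covariance:
    # sigma^2 (W'W)^-1 [W'(I - rho^2 D)W + Q] (W'W)^-1,
    # Q = rho^2 (W'DZ) Vgamma (Z'DW) propagating first-stage noise in gamma.
    WtW_inv = np.linalg.inv(W.T @ W)
    WD = W * delta[:, None]
    middle = W.T @ W - rho**2 * (WD.T @ W)
    A = WD.T @ Z1
    Q = rho**2 * (A @ first.covariance @ A.T)
    cov = sigma2 * WtW_inv @ (middle + Q) @ WtW_inv

    return TwoStepFit(beta_hat=beta, beta_mills=b_mills, sigma_hat=sigma,
                      rho_hat=rho, lambda_hat=rho * sigma,
                      rho_clamped=bool(clamped), covariance=cov,
                      first_stage=first, mills=mills, n_selected=n1,
                      residuals=resid,
                      x_names=list(design.x_names),
                      z_names=list(design.z_names))


def _uncensored_fit(design: SelectionDesign):
    """Degenerate two-step fit for a sample with no censoring: plain OLS."""
    n, k = design.X.shape
    if n < k + 2:
        raise InvalidInputError(f"need at least {k + 2} rows, have {n}")
    if np.linalg.matrix_rank(design.X) < k:
        raise CollinearityError("outcome design is rank deficient")
    beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta
    sigma2 = float(resid @ resid) / n
    cov = np.zeros((k + 1, k + 1))
    cov[:k, :k] = sigma2 * np.linalg.inv(design.X.T @ design.X)
    return TwoStepFit(beta_hat=beta, beta_mills=0.0,
                      sigma_hat=float(np.sqrt(sigma2)), rho_hat=0.0,
                      lambda_hat=0.0, rho_clamped=False, covariance=cov,
                      first_stage=None, mills=None, n_selected=n,
                      residuals=resid, x_names=list(design.x_names),
                      z_names=list(design.z_names))


def truncation_effect(selection_corr, average_mills):
    """Average truncation effect and its percent interpretation.

    ``effect = selection_corr * average_mills``; the conditional outcome for
    the selected sample sits ``100 (exp(effect) - 1)`` percent above (or
    below) the population value at average characteristics.  The multiplier
    is an explicit argument so callers can pass the error correlation rho
    (the default used by the pipeline) or the selection coefficient
    rho*sigma.
    """
    if not (np.isfinite(selection_corr) and np.isfinite(average_mills)):
        raise InvalidInputError("inputs must be finite")
    effect = float(selection_corr * average_mills)
    return TruncationEffect(effect=effect,
                            percent_shift=float(100.0 * np.expm1(effect)))


def predict_outcome(fit: TwoStepFit, design: SelectionDesign):
    """Conditional-on-selection fitted values for the selected rows.

    yhat_i = x_i'beta + b_mills * lambda(z_i'gamma) — the mean the two-step
    regression actually targets.
    """
    if design.X.shape[1] != fit.beta_hat.shape[0]:
        raise InvalidInputError("design/coefficient dimension mismatch")
    sel = design.s == 1
    X1 = design.X[sel]
    if fit.first_stage is None:        # uncensored limit: plain prediction
        return X1 @ fit.beta_hat
    if design.Z.shape[1] != fit.first_stage.gamma_hat.shape[0]:
        raise InvalidInputError("selection design dimension mismatch")
    idx = design.Z[sel] @ fit.first_stage.gamma_hat
    lam = np.atleast_1d(inverse_mills(idx))
    return X1 @ fit.beta_hat + fit.beta_mills * lam
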
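"""Pipeline orchestration: run both severity analyses and render tables.

`run_pipeline` takes a tidy intersection-year table, builds the selection
system for each severity level (the severity-specific crash rate as the
outcome, a severity-present flag as the selection indicator), screens for
collinear covariates, fits the two-step and/or FIML estimators, computes
the truncation effect and MAD/RMSE, and optionally fits the bivariate
probit comparison.  `render_tables` prints the result in the
coefficient-table layout used for published severity models.

Predictions for MAD/RMSE are the conditional-on-selection means
``x'beta + b_mills lambda(z'gamma)`` scored on the selected rows — the
object the estimator actually fits.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bivariate_probit import BiProbitFit, fit_biprobit
from .data_model import (build_design, compute_crash_rate, compute_exposure,
                         correlation_screen, load_records)
from .exceptions import ConfigError, InvalidInputError
from .fiml import FIMLFit, fit_fiml, wald_independence
from .probit_stage import inverse_mills
from .two_step import (TwoStepFit, fit_two_step, predict_outcome,
                       truncation_effect)

__all__ = ["GoodnessOfFit", "SeverityResult", "AnalysisReport",
           "DEFAULT_SPECS", "goodness_of_fit", "run_pipeline",
           "render_tables"]

#: Default per-severity model specifications (outcome regressors, selection
#: regressors).  Fully overridable through the pipeline config.
DEFAULT_SPECS = {
    "slight": {
        "x_cols": ["reciprad", "cycletime", "tramstop", "kln"],
        "z_cols": ["aadt", "reciprad", "tramstop", "kln", "speed"],
    },
    "ksi": {
        "x_cols": ["lanewidth", "cycletime", "kln"],
        "z_cols": ["comveh", "tramstop", "speed"],
    },
}


@dataclass
class GoodnessOfFit:
    mad: float
    rmse: float
    n: int


@dataclass
class SeverityResult:
    severity: str
    two_step: TwoStepFit | None
    fiml: FIMLFit | None
    truncation: object
    gof: GoodnessOfFit
    wald: tuple | None            # (statistic, p) from FIML, if fitted
    flagged_pairs: list


@dataclass
class AnalysisReport:
    severities: dict              # name -> SeverityResult
    comparison: BiProbitFit | None
    provenance: dict = field(default_factory=dict)


def goodness_of_fit(observed, predicted):
    """MAD = mean |Y - Yhat|; RMSE = sqrt(mean (Y - Yhat)^2)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise InvalidInputError("observed and predicted lengths differ")
    if observed.size < 1:
        raise InvalidInputError("need at least one observation")
    err = observed - predicted
    return GoodnessOfFit(mad=float(np.mean(np.abs(err))),
                         rmse=float(np.sqrt(np.mean(err**2))),
                         n=int(observed.size))


def _severity_columns(df, severity, spec):
    """Outcome and selection vectors for one severity level.

    If the spec names explicit ``outcome``/``selection`` columns those are
    used; otherwise they are derived from ``{severity}_count`` and the AADT
    exposure.
    """
    out = df.copy()
    if "outcome" in spec and "selection" in spec:
        return out, spec["outcome"], spec["selection"]
    count_col = f"{severity}_count"
    if count_col not in df.columns:
        raise ConfigError(
            f"severity {severity!r}: no outcome/selection columns given and "
            f"no {count_col!r} column to derive them from")
    exposure = compute_exposure(df["aadt"].to_numpy())
    counts = df[count_col].to_numpy()
    out[f"{severity}_rate"] = compute_crash_rate(counts, exposure)
    out[f"{severity}_obs"] = (counts > 0).astype(int)
    return out, f"{severity}_rate", f"{severity}_obs"


def run_pipeline(config):
    """Run the full analysis described by a config mapping.

    Config keys (all but ``data`` optional):

    - ``data``: CSV path or DataFrame of intersection-year rows
    - ``method``: ``"two-step"`` (default), ``"fiml"`` or ``"both"``
    - ``severities``: mapping name -> {x_cols, z_cols[, outcome, selection]}
      (default: the built-in slight/KSI specifications, restricted to the
      columns present in the data)
    - ``correlation_threshold``: |r| cutoff for the pre-fit screen (0.6)
    - ``truncation_multiplier``: ``"rho"`` (default) or ``"lambda"`` —
      which estimate multiplies the average Mills value
    - ``comparison``: false to skip the bivariate probit; otherwise fitted
      whenever two severities are analysed
    - ``seed``: recorded in provenance (the pipeline itself is
      deterministic given the input data)
    """
    if isinstance(config, (str,)):
        with open(config) as fh:
            config = json.load(fh)
    config = dict(config)
    data = config.get("data")
    if data is None:
        raise ConfigError("config must name an input dataset under 'data'")
    df = data.copy() if isinstance(data, pd.DataFrame) else load_records(data)

    method = config.get("method", "two-step")
    if method not in ("two-step", "fiml", "both"):
        raise ConfigError(f"unknown method {method!r}")
    threshold = float(config.get("correlation_threshold", 0.6))
    mult_kind = config.get("truncation_multiplier", "rho")
    if mult_kind not in ("rho", "lambda"):
        raise ConfigError("truncation_multiplier must be 'rho' or 'lambda'")

    severities = config.get("severities")
    if severities is None:
        severities = {name: dict(spec) for name, spec in DEFAULT_SPECS.items()
                      if all(c in df.columns
                             for c in spec["x_cols"] + spec["z_cols"])
                      and f"{name}_count" in df.columns}
        if not severities:
            raise ConfigError("no default severity specification matches the "
                              "data; pass 'severities' explicitly")

    results = {}
    for name, spec in severities.items():
        frame, outcome, selection = _severity_columns(df, name, spec)
        for col in (outcome, selection, *spec["x_cols"], *spec["z_cols"]):
            if col not in frame.columns:
                raise ConfigError(f"severity {name!r}: unknown column {col!r}")
        screen_cols = list(dict.fromkeys(spec["x_cols"] + spec["z_cols"]))
        flagged = correlation_screen(frame[screen_cols], threshold=threshold)

        design = build_design(frame, outcome, selection,
                              spec["x_cols"], spec["z_cols"])
        ts = fit_two_step(design) if method in ("two-step", "both") else None
        fm = None
        wald = None
        if method in ("fiml", "both"):
            fm = fit_fiml(design, start=ts)
            wald = wald_independence(fm)

        primary = ts if ts is not None else fm
        if ts is not None:
            avg_mills = ts.mills.average_mills
            rho, lam = ts.rho_hat, ts.lambda_hat
            yhat = predict_outcome(ts, design)
        else:
            idx = design.Z @ fm.gamma_hat
            sel = design.s == 1
            lam_i = np.atleast_1d(inverse_mills(idx[sel]))
            avg_mills = float(lam_i.mean())
            rho, lam = fm.rho_hat, fm.rho_hat * fm.sigma_hat
            yhat = design.X[sel] @ fm.beta_hat + lam * lam_i
        mult = rho if mult_kind == "rho" else lam
        trunc = truncation_effect(mult, avg_mills)
        y_sel = design.y[design.s == 1]
        gof = goodness_of_fit(y_sel, yhat)

        results[name] = SeverityResult(severity=name, two_step=ts, fiml=fm,
                                       truncation=trunc, gof=gof, wald=wald,
                                       flagged_pairs=flagged)

    comparison = None
    if config.get("comparison", True) and len(severities) >= 2:
        names = list(severities)[:2]
        frames = {}
        for name in names:
            frame, _, selection = _severity_columns(df, name,
                                                    severities[name])
            frames[name] = (frame, selection)
        n = len(df)
        Xs, ss = [], []
        for name in names:
            frame, selection = frames[name]
            cols = severities[name]["z_cols"]
            X = np.column_stack([np.ones(n)] +
                                [frame[c].to_numpy(float) for c in cols])
            Xs.append(X)
            ss.append(frame[selection].to_numpy())
        try:
            comparison = fit_biprobit(Xs[0], ss[0], Xs[1], ss[1])
            comparison.names_slight = ["const", *severities[names[0]]["z_cols"]]
            comparison.names_ksi = ["const", *severities[names[1]]["z_cols"]]
        except Exception:
            comparison = None     # comparison is optional; never fatal

    provenance = {
        "input": data if isinstance(data, str) else "<in-memory frame>",
        "method": method,
        "seed": config.get("seed"),
        "correlation_threshold": threshold,
        "truncation_multiplier": mult_kind,
        "package_version": __version__,
        "n_rows": int(len(df)),
    }
    return AnalysisReport(severities=results, comparison=comparison,
                          provenance=provenance)


def _coef_block(out, title, names, coefs, ses):
    out.write(f"{title}\n")
    out.write("Variable\tCoefficient\tStd. Err.\tZ-statistic\n")
    for name, c, se in zip(names, coefs, ses):
        z = c / se if se > 0 else np.nan
        out.write(f"{name}\t{c:.3f}\t{se:.3f}\t{z:.2f}\n")


def render_tables(report: AnalysisReport):
    """Tab-delimited coefficient tables plus goodness-of-fit blocks."""
    out = io.StringIO()
    for name, res in report.severities.items():
        fit = res.two_step if res.two_step is not None else res.fiml
        out.write(f"== Heckman selection model: {name} ==\n")
        if isinstance(fit, TwoStepFit):
            se = fit.se
            _coef_block(out, f"Crash rate of {name}", fit.x_names,
                        fit.beta_hat, se[:len(fit.x_names)])
            _coef_block(out, f"{name} selection model", fit.z_names,
                        fit.first_stage.gamma_hat, fit.first_stage.se)
            rho, sigma, lam = fit.rho_hat, fit.sigma_hat, fit.lambda_hat
            n = fit.first_stage.linear_index.shape[0]
        else:
            se = fit.se
            kx = len(fit.x_names)
            kz = len(fit.z_names)
            _coef_block(out, f"Crash rate of {name}", fit.x_names,
                        fit.beta_hat, se[kz:kz + kx])
            _coef_block(out, f"{name} selection model", fit.z_names,
                        fit.gamma_hat, se[:kz])
            rho, sigma, lam = fit.rho_hat, fit.sigma_hat, \
                fit.rho_hat * fit.sigma_hat
            n = report.provenance["n_rows"]
        out.write("Goodness-of-fit assessment\n")
        out.write(f"Rho\t{rho:.3f}\n")
        out.write(f"Sigma\t{sigma:.3f}\n")
        out.write(f"Lambda\t{lam:.3f}\n")
        out.write(f"Number of observations\t{n}\n")
        if res.wald is not None:
            out.write(f"Wald Chi-square\t{res.wald[0]:.2f}\n")
        out.write(f"MAD\t{res.gof.mad:.3f}\n")
        out.write(f"RMSE\t{res.gof.rmse:.3f}\n")
        out.write(f"Truncation effect\t{res.truncation.effect:.3f}\n")
        out.write(f"Percent shift\t{res.truncation.percent_shift:.2f}\n")
        if res.flagged_pairs:
            out.write("Collinearity warnings\n")
            for a, b, r in res.flagged_pairs:
                out.write(f"{a}~{b}\tr={r:.3f}\n")
        out.write("\n")

    if report.comparison is not None:
        cmp_fit = report.comparison
        out.write("== Bivariate probit comparison ==\n")
        se = cmp_fit.se
        k1 = len(cmp_fit.beta_slight)
        _coef_block(out, "Slight injury model", cmp_fit.names_slight,
                    cmp_fit.beta_slight, se[:k1])
        _coef_block(out, "KSI model", cmp_fit.names_ksi,
                    cmp_fit.beta_ksi, se[k1:k1 + len(cmp_fit.beta_ksi)])
        out.write("Goodness-of-fit assessment\n")
        out.write(f"Rho\t{cmp_fit.rho:.3f}\n")
        out.write(f"Log likelihood at convergence\t{cmp_fit.loglik:.2f}\n")
        if np.isfinite(cmp_fit.wald_independence[0]):
            out.write(f"Wald Chi-square\t{cmp_fit.wald_independence[0]:.2f}\n")
        out.write("\n")
    return out.getvalue()
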
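"""Observation records, exposure/crash-rate arithmetic, design matrices.

An *observation* is one intersection-year, optionally expanded per injury
severity level (slight injury vs. KSI, killed-or-seriously-injured).  The
outcome analysed downstream is the severity-specific crash rate: crashes of
that severity per million vehicles passing through the intersection in a
year.  Exposure is annual traffic volume, AADT x 365.

The module also provides the Table-1-style sample summary, the collinearity
pre-screen applied before any model is specified, and the
:class:`SelectionDesign` container consumed by every estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, ConfigError, InvalidInputError

__all__ = [
    "RATE_SCALE",
    "IntersectionYearRecord",
    "SelectionDesign",
    "SampleSummary",
    "compute_exposure",
    "compute_crash_rate",
    "count_observations",
    "summarize",
    "correlation_screen",
    "build_design",
    "load_records",
]

#: Crash rates are expressed per this many vehicles of exposure (one million).
RATE_SCALE = 1e6

#: Binary indicator covariates carried by an intersection-year record.
INDICATOR_FIELDS = (
    "appr2", "appr3", "appr4", "tramstop", "lrtstop", "hki", "kln",
    "turningpock",
)

#: Continuous / count covariates.
CONTINUOUS_FIELDS = (
    "aadt", "nolanes", "noconflict", "notrnstream", "lanewidth", "reciprad",
    "comveh", "speed", "nostages", "cycletime", "pedcrossing",
)


@dataclass
class IntersectionYearRecord:
    """One signalized-intersection-year: covariates plus severity counts."""

    intersection_id: str
    year: int
    aadt: float
    slight_count: int = 0
    ksi_count: int = 0
    nolanes: float = 0.0
    noconflict: float = 0.0
    notrnstream: float = 0.0
    lanewidth: float = 0.0
    reciprad: float = 0.0
    comveh: float = 0.0
    speed: float = 0.0
    nostages: float = 0.0
    cycletime: float = 0.0
    pedcrossing: float = 0.0
    appr2: int = 0
    appr3: int = 0
    appr4: int = 0
    tramstop: int = 0
    lrtstop: int = 0
    hki: int = 0
    kln: int = 0
    turningpock: int = 0

    def __post_init__(self):
        if self.aadt <= 0:
            raise InvalidInputError(f"aadt must be positive, got {self.aadt}")
        if self.slight_count < 0 or self.ksi_count < 0:
            raise InvalidInputError("crash counts must be non-negative")
        if not 0.0 <= self.comveh <= 1.0:
            raise InvalidInputError(f"comveh must lie in [0, 1], got {self.comveh}")
        for name in INDICATOR_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise InvalidInputError(f"{name} must be 0 or 1, got {v}")
        # The approach-count flags are stored as independent indicators on
        # purpose: observed samples report proportions summing above 1.


@dataclass
class SelectionDesign:
    """The aligned (y, X, Z, s) system for one severity level.

    ``y`` is the severity-specific crash rate and is meaningful only where
    the selection flag ``s`` is 1 (the severity level was observed).  Both
    design matrices carry exactly one leading intercept column.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    s: np.ndarray
    x_names: list = field(default_factory=list)
    z_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.s = np.asarray(self.s)
        n = self.y.shape[0]
        if not (self.X.shape[0] == self.Z.shape[0] == self.s.shape[0] == n):
            raise InvalidInputError("y, X, Z, s must have aligned rows")
        if not np.isin(self.s, (0, 1)).all():
            raise InvalidInputError("selection indicator s must be binary")
        self.s = self.s.astype(int)
        for M, names, label in ((self.X, self.x_names, "X"),
                                (self.Z, self.z_names, "Z")):
            if names and len(names) != M.shape[1]:
                raise ConfigError(f"{label} has {M.shape[1]} columns but "
                                  f"{len(names)} names")
            n_const = sum(np.ptp(col) == 0 and col[0] == 1.0 for col in M.T)
            if n_const != 1:
                raise InvalidInputError(
                    f"{label} must contain exactly one intercept column "
                    f"(found {n_const})")

    @property
    def n(self):
        return self.y.shape[0]

    @property
    def n_selected(self):
        return int(self.s.sum())

    def selected(self):
        """Return (y, X, Z) restricted to rows with s = 1."""
        m = self.s == 1
        return self.y[m], self.X[m], self.Z[m]


@dataclass
class SampleSummary:
    """Table-1-style description of an expanded observation sample."""

    stats: pd.DataFrame              # mean / sd / min / max per variable
    percentages: dict                # category -> integer percent of n
    n_observations: int
    n_zero_crash: int
    n_slight: int
    n_ksi: int


def compute_exposure(aadt):
    """Annual traffic exposure in vehicles/year: AADT x 365.

    Parameters
    ----------
    aadt : float or array
        Annual average daily traffic, vehicles/day.  Must be positive.
    """
    aadt = np.asarray(aadt, dtype=float)
    if np.any(aadt <= 0) or not np.all(np.isfinite(aadt)):
        raise InvalidInputError("aadt must be positive and finite")
    out = aadt * 365.0
    return float(out) if out.ndim == 0 else out


def compute_crash_rate(count, exposure, scale=RATE_SCALE):
    """Severity-specific crash rate: crashes per `scale` vehicles of exposure.

    ``count * scale / exposure`` with the default scale of one million
    vehicles, which puts observed-network rates on the order of 0.5-1.
    """
    count = np.asarray(count, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure <= 0):
        raise InvalidInputError("exposure must be positive")
    if np.any(count < 0):
        raise InvalidInputError("count must be non-negative")
    out = count * scale / exposure
    return float(out) if out.ndim == 0 else out


def count_observations(df, scale=RATE_SCALE):
    """Expand intersection-year rows into severity-level observations.

    The bookkeeping rule: an intersection-year with zero crashes contributes
    a single observation with no severity level (both severity analyses see
    it as censored).  An intersection-year with one or more crashes
    contributes one observation per severity category — the category's row
    carries a selection flag of 1 and the category crash rate when that
    category saw at least one crash, and a flag of 0 otherwise.

    Parameters
    ----------
    df : DataFrame
        One row per intersection-year with ``slight_count``, ``ksi_count``,
        ``aadt`` and covariate columns.

    Returns
    -------
    DataFrame with added columns ``severity`` (``'slight'``/``'ksi'``/
    ``None``), ``selected`` and ``crash_rate``.
    """
    for col in ("slight_count", "ksi_count", "aadt"):
        if col not in df.columns:
            raise InvalidInputError(f"missing required column {col!r}")
    if (df["slight_count"] < 0).any() or (df["ksi_count"] < 0).any():
        raise InvalidInputError("crash counts must be non-negative")

    exposure = compute_exposure(df["aadt"].to_numpy())
    rows = []
    for i, (_, row) in enumerate(df.iterrows()):
        total = row["slight_count"] + row["ksi_count"]
        if total == 0:
            out = row.copy()
            out["severity"] = None
            out["selected"] = 0
            out["crash_rate"] = 0.0
            rows.append(out)
            continue
        for sev, col in (("slight", "slight_count"), ("ksi", "ksi_count")):
            out = row.copy()
            out["severity"] = sev
            out["selected"] = int(row[col] > 0)
            out["crash_rate"] = compute_crash_rate(row[col], exposure[i],
                                                   scale=scale)
            rows.append(out)
    return pd.DataFrame(rows).reset_index(drop=True)


def summarize(records):
    """Describe an expanded observation sample (means/SDs/ranges, shares).

    Category shares are 100*count/n rounded to integer percent, matching the
    convention used for published network summaries.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise InvalidInputError("cannot summarize an empty sample")

    n = len(df)
    numeric = df.select_dtypes(include=[np.number])
    drop = [c for c in ("selected", "year") if c in numeric.columns]
    numeric = numeric.drop(columns=drop)
    stats = pd.DataFrame({
        "mean": numeric.mean(),
        "sd": numeric.std(ddof=1).fillna(0.0) if n > 1
              else pd.Series(0.0, index=numeric.columns),
        "min": numeric.min(),
        "max": numeric.max(),
    })

    if "severity" in df.columns:
        n_slight = int((df["severity"] == "slight").sum())
        n_ksi = int((df["severity"] == "ksi").sum())
        n_zero = int(df["severity"].isna().sum())
    else:
        zero = pd.Series(0, index=df.index)
        slight = df["slight_count"] if "slight_count" in df.columns else zero
        ksi = df["ksi_count"] if "ksi_count" in df.columns else zero
        n_zero = int(((slight + ksi) == 0).sum())
        n_slight = int((slight > 0).sum())
        n_ksi = int((ksi > 0).sum())

    percentages = {
        "zero_crash": round(100.0 * n_zero / n),
        "slight": round(100.0 * n_slight / n),
        "ksi": round(100.0 * n_ksi / n),
    }
    for name in INDICATOR_FIELDS:
        if name in df.columns:
            percentages[name] = round(100.0 * df[name].sum() / n)

    return SampleSummary(stats=stats, percentages=percentages,
                         n_observations=n, n_zero_crash=n_zero,
                         n_slight=n_slight, n_ksi=n_ksi)


def correlation_screen(X, threshold=0.6, names=None):
    """Flag covariate pairs whose |Pearson r| meets the threshold.

    Run before model specification so that near-duplicate regressors (e.g.
    approach lanes vs. conflict points vs. turning movements) are not entered
    together.  Zero-variance columns are excluded with a warning rather than
    an error.

    Returns a list of ``(name_i, name_j, r)`` sorted by ``|r|`` descending.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidInputError("need at least two covariate columns")
    if X.shape[0] < 3:
        raise InvalidInputError("need at least three rows")

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"zero-variance columns excluded from screen: {dropped}")
    X = X[:, keep]
    kept = [names[j] for j in np.flatnonzero(keep)]
    if X.shape[1] < 2:
        return []

    R = np.corrcoef(X, rowvar=False)
    flagged = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            r = R[i, j]
            if abs(r) >= threshold:
                flagged.append((kept[i], kept[j], float(r)))
    flagged.sort(key=lambda t: abs(t[2]), reverse=True)
    return flagged


def build_design(df, outcome, selection, x_cols, z_cols):
    """Assemble a :class:`SelectionDesign` from a tidy observation table.

    Rows with a missing value in any model column are dropped (no
    imputation); the dropped count is reported via a warning.
    """
    for col in [outcome, selection, *x_cols, *z_cols]:
        if col not in df.columns:
            raise ConfigError(f"unknown column {col!r}")
    model_cols = list(dict.fromkeys([outcome, selection, *x_cols, *z_cols]))
    sub = df[model_cols]
    complete = sub.notna().all(axis=1)
    # outcome may legitimately be missing where the row is censored
    complete |= (df[selection] == 0) & sub.drop(columns=[outcome]).notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} rows with missing model variables")
    d = df[complete]

    s = d[selection].to_numpy()
    y = d[outcome].to_numpy(dtype=float)
    y = np.where(np.isnan(y), 0.0, y)
    n = len(d)
    X = np.column_stack([np.ones(n)] + [d[c].to_numpy(dtype=float) for c in x_cols])
    Z = np.column_stack([np.ones(n)] + [d[c].to_numpy(dtype=float) for c in z_cols])
    design = SelectionDesign(y=y, X=X, Z=Z, s=s,
                             x_names=["const", *x_cols],
                             z_names=["const", *z_cols])
    for M, label in ((design.X, "X"), (design.Z, "Z")):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise CollinearityError(f"{label} design matrix is rank deficient")
    return design


def load_records(path):
    """Read an intersection-year CSV (UTF-8, '.' decimal) into a DataFrame."""
    df = pd.read_csv(path)
    if "aadt" not in df.columns:
        raise InvalidInputError("input CSV lacks an 'aadt' column")
    return df
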
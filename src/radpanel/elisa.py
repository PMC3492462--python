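"""ELISA quantification: standard curves, inversion, and group tests.

Absorbance readings are mapped to concentrations through a fitted
four-parameter logistic (4PL) standard curve — the universal immunoassay
calibration model — or through a log-linear fallback.  Markers measured
without a standard curve (the pCHK2-thr68 phosphoprotein) are expressed
relative to the mean absorbance of unirradiated (sham) samples.  Raw
values are log_e-transformed and mean-zero standardized before two-sample
t-tests per experimental group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .stats import safe_ttest

__all__ = [
    "FourPLParams",
    "four_pl",
    "FourPLCurve",
    "LogLinearCurve",
    "fit_standard_curve",
    "interpolate",
    "fold_vs_sham",
    "standardize",
    "group_test",
    "average_duplicates",
]


def _four_pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of ``y = d + (a - d) / (1 + (x/c)^b)``.

    ``a`` is the response at zero analyte, ``d`` the saturating response,
    ``c`` the midpoint concentration (y = (a+d)/2 at x = c) and ``b`` the
    Hill slope.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("midpoint c must be > 0")
        if self.b == 0:
            raise ValueError("hill slope b must be nonzero")


def four_pl(x, p: FourPLParams):
    """Evaluate the 4PL response at concentration ``x``."""
    return _four_pl(np.asarray(x, dtype=float), p.a, p.b, p.c, p.d)


class FourPLCurve(BaseEstimator, RegressorMixin):
    """Four-parameter logistic standard curve.

    Model: ``y = d + (a - d) / (1 + (x/c)^b)`` where ``a`` is the response
    at zero analyte, ``d`` the saturating response, ``c`` the midpoint
    concentration (y = (a+d)/2 at x = c) and ``b`` the Hill slope.

    ``fit`` takes known standard concentrations and their absorbances;
    ``predict`` evaluates the curve; ``inverse`` algebraically inverts it,
    returning NaN (flagged, never extrapolated) for absorbances outside the
    open asymptote interval.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, concentration, absorbance):
        x = np.asarray(concentration, dtype=float).ravel()
        y = np.asarray(absorbance, dtype=float).ravel()
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct standard concentrations")
        if np.ptp(y) == 0:
            raise ValueError("degenerate standards: constant absorbance")
        if (x <= 0).any():
            raise ValueError("standard concentrations must be > 0")
        span = np.ptp(y)
        p0 = [y.min() - 0.05 * span, 1.0, float(np.exp(np.mean(np.log(x)))),
              y.max() + 0.05 * span]
        popt, _ = curve_fit(_four_pl, x, y, p0=p0, maxfev=self.maxfev)
        self.a_, self.b_, self.c_, self.d_ = (float(v) for v in popt)
        if self.c_ <= 0 or self.b_ == 0:
            raise ValueError("fit converged to an invalid curve")
        self.residual_ss_ = float(np.sum((self.predict(x) - y) ** 2))
        return self

    def predict(self, concentration):
        x = np.asarray(concentration, dtype=float)
        return _four_pl(x, self.a_, self.b_, self.c_, self.d_)

    def inverse(self, absorbance):
        """Concentration for each absorbance; NaN where out of range."""
        y = np.asarray(absorbance, dtype=float)
        lo, hi = sorted((self.a_, self.d_))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = (self.a_ - self.d_) / (y - self.d_) - 1.0
            x = self.c_ * np.power(ratio, 1.0 / self.b_)
        return np.where((y > lo) & (y < hi), x, np.nan)

    def in_range(self, absorbance):
        y = np.asarray(absorbance, dtype=float)
        lo, hi = sorted((self.a_, self.d_))
        return (y > lo) & (y < hi)


class LogLinearCurve(BaseEstimator, RegressorMixin):
    """Fallback calibration: absorbance linear in log concentration."""

    def fit(self, concentration, absorbance):
        x = np.log(np.asarray(concentration, dtype=float))
        y = np.asarray(absorbance, dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        self.slope_, self.intercept_ = np.polyfit(x, y, 1)
        if self.slope_ == 0:
            raise ValueError("degenerate standards: flat response")
        resid = y - self.predict(np.exp(x))
        self.residual_ss_ = float(np.sum(resid ** 2))
        return self

    def predict(self, concentration):
        return self.slope_ * np.log(np.asarray(concentration, float)) + self.intercept_

    def inverse(self, absorbance):
        y = np.asarray(absorbance, dtype=float)
        return np.exp((y - self.intercept_) / self.slope_)


def fit_standard_curve(standards: pd.DataFrame, kind: str = "4pl"):
    """Fit a calibration curve to standards rows (concentration, absorbance)."""
    curve = {"4pl": FourPLCurve, "loglinear": LogLinearCurve}[kind]()
    return curve.fit(standards["concentration"], standards["absorbance"])


def interpolate(curve, absorbance):
    """Read concentrations off a fitted standard curve (NaN = out of range)."""
    return curve.inverse(absorbance)


def average_duplicates(ds: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells on the absorbance scale before interpolation."""
    keys = ["marker", "sample_id", "group", "role"]
    return (
        ds.groupby(keys, sort=False, dropna=False)
        .agg(concentration=("concentration", "mean"),
             absorbance=("absorbance", "mean"))
        .reset_index()
    )


def fold_vs_sham(values: pd.Series, sham_ids, paired_difference: bool = False) -> pd.Series:
    """Express each value relative to the mean of the sham (unirradiated) group.

    Default is the ratio to the sham mean (sham averages to exactly 1); with
    ``paired_difference`` the sham mean is subtracted instead.
    """
    sham = values.loc[list(sham_ids)]
    if len(sham) == 0:
        raise ValueError("sham group is empty")
    m = float(sham.mean())
    if paired_difference:
        return values - m
    if m == 0:
        raise ValueError("sham mean is zero; ratio undefined")
    return values / m


def standardize(values) -> np.ndarray:
    """log_e transform then mean-center, yielding mean-zero values."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("values must be strictly positive for log transform")
    logged = np.log(v)
    return logged - logged.mean()


def group_test(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test between two groups of (standardized) values."""
    return safe_ttest(values_a, values_b, equal_var=equal_var)
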
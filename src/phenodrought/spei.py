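"""Standardized Precipitation-Evapotranspiration Index (SPEI), 1-month scale.

The monthly climatic water balance D = precipitation - PET is fitted, per
calendar month over a calibration window, with a three-parameter
log-logistic distribution estimated by unbiased probability-weighted
moments (PWMs); each D value is then mapped through the fitted CDF and
the exact standard-normal quantile.  Negative SPEI means drier than the
calibration climatology for that calendar month, positive wetter.

The per-month fit-then-transform step is exposed as a scikit-learn-style
transformer, :class:`LogLogisticSpei`; ``compute_spei`` applies one
transformer per calendar month across a full series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: Probability clamp for d-values outside the fitted support / deep tails.
PROB_FLOOR = 1e-6

#: Minimum calibration sample size per calendar month.
MIN_CALIBRATION = 20


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: shape beta, scale alpha, origin gamma.

    CDF: F(x) = [1 + (alpha / (x - gamma))**beta]**-1  for x > gamma.
    """

    shape: float  # beta
    scale: float  # alpha, mm
    origin: float  # gamma, mm
    calibration_n: int

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must be positive")


class FitRejectedError(ValueError):
    """A PWM fit produced an invalid shape or violated the support."""


def fit_spei_distribution(values) -> tuple[LogLogisticParams, bool]:
    """Fit the water-balance distribution, mirroring if necessary.

    The log-logistic parameterized here carries positive L-skewness only.
    Calendar months whose water balance is left-skewed (or so close to
    symmetric that sampling noise flips the sign) are fitted on the
    negated sample -- the opposite-skew member of the same generalized-
    logistic family -- and flagged ``mirrored``; the transform then maps
    d through 1 - F(-d), preserving monotonicity and standardization.

    Returns (params, mirrored).
    """
    x = np.asarray(values, dtype=float)
    try:
        return fit_loglogistic_pwm(x), False
    except FitRejectedError:
        return fit_loglogistic_pwm(-x), True


def _unbiased_pwms(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased PWMs w0, w1, w2 with (1-F)^s weights, from the ordered sample.

    For the ascending order statistics x_(1..n):
        w_s = (1/n) * sum_i x_(i) * C(n-i, s) / C(n-1, s)
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum(x * (n - i)) / (n * (n - 1))
    w2 = np.sum(x * (n - i) * (n - i - 1)) / (n * (n - 1) * (n - 2))
    return float(w0), float(w1), float(w2)


def fit_loglogistic_pwm(values) -> LogLogisticParams:
    """Fit the 3-parameter log-logistic by unbiased PWMs.

    beta  = (2*w1 - w0) / (6*w1 - w0 - 6*w2)
    alpha = (w0 - 2*w1) * beta / (G(1+1/b) * G(1-1/b))
    gamma = w0 - alpha * G(1+1/b) * G(1-1/b)

    Raises ``ValueError`` for samples below the calibration floor, with
    zero variance, with a non-positive or near-zero fitted shape, or
    whose minimum violates the fitted support (min <= gamma).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < MIN_CALIBRATION:
        raise ValueError(
            f"need >= {MIN_CALIBRATION} calibration values, got {len(x)}"
        )
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample: zero variance")
    w0, w1, w2 = _unbiased_pwms(x)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0.0:
        raise ValueError("degenerate PWMs: undefined shape")
    beta = (2.0 * w1 - w0) / denom
    if beta <= 1e-6:
        raise FitRejectedError(f"rejected fit: shape {beta} <= 1e-6")
    if beta <= 1.0:
        # gamma(1 - 1/beta) undefined or negative-mean regime
        raise FitRejectedError(f"rejected fit: shape {beta} <= 1 (infinite mean)")
    g = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    origin = w0 - alpha * g
    if alpha <= 0:
        raise FitRejectedError(f"rejected fit: scale {alpha} <= 0")
    if x.min() <= origin:
        raise FitRejectedError(
            f"support violation: sample minimum {x.min()} <= origin {origin}"
        )
    return LogLogisticParams(
        shape=beta, scale=alpha, origin=origin, calibration_n=len(x)
    )


def loglogistic_cdf(d, params: LogLogisticParams) -> np.ndarray:
    """F(d) for the fitted log-logistic, clamped to [PROB_FLOOR, 1-PROB_FLOOR]."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - params.origin) / params.scale
        p = np.where(z > 0, 1.0 / (1.0 + z ** (-params.shape)), 0.0)
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def spei_transform(d, params: LogLogisticParams) -> float | np.ndarray:
    """Map water-balance value(s) to SPEI via the exact normal quantile."""
    z = norm.ppf(loglogistic_cdf(d, params))
    z = np.asarray(z)
    return float(z) if z.ndim == 0 else z


class LogLogisticSpei(TransformerMixin, BaseEstimator):
    """Standardize a water-balance series to SPEI units.

    scikit-learn-style transformer for a single calendar month: ``fit``
    estimates the 3-parameter log-logistic from the calibration sample by
    unbiased PWMs; ``transform`` maps values through the fitted CDF and
    the standard-normal quantile.  Negative output = drier than the
    calibration climatology.

    Parameters
    ----------
    min_calibration : minimum calibration sample size (default 20).

    Attributes
    ----------
    params_ : fitted :class:`LogLogisticParams`.
    mirrored_ : True when the fit used the negated sample (left-skewed
        months); see :func:`fit_spei_distribution`.
    """

    def __init__(self, min_calibration: int = MIN_CALIBRATION):
        self.min_calibration = min_calibration

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if len(x) < self.min_calibration:
            raise ValueError(
                f"need >= {self.min_calibration} calibration values, got {len(x)}"
            )
        self.params_, self.mirrored_ = fit_spei_distribution(x)
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=float)
        shape = x.shape
        flat = x.reshape(-1)
        if self.mirrored_:
            out = -np.asarray(spei_transform(-flat, self.params_))
        else:
            out = np.asarray(spei_transform(flat, self.params_))
        return out.reshape(shape)


def water_balance(monthly: pd.DataFrame, pet: pd.DataFrame) -> pd.DataFrame:
    """Monthly climatic water balance D = prcp_total - pet_total.

    Inputs are aligned on (year, month); a mismatch in keys is an error.
    Returns columns ``year, month, d_value``.
    """
    m = monthly[["year", "month", "prcp_total"]]
    p = pet[["year", "month", "pet_total"]]
    merged = m.merge(p, on=["year", "month"], how="outer", indicator=True)
    bad = merged["_merge"] != "both"
    if bad.any():
        missing = merged.loc[bad, ["year", "month"]].head(5).to_dict("records")
        raise ValueError(f"(year, month) key mismatch between inputs: {missing}")
    out = pd.DataFrame(
        {
            "year": merged["year"].astype(int),
            "month": merged["month"].astype(int),
            "d_value": merged["prcp_total"] - merged["pet_total"],
        }
    )
    return out.sort_values(["year", "month"]).reset_index(drop=True)


def compute_spei(
    wb: pd.DataFrame,
    calibration: tuple[int, int] | None = None,
    min_calibration: int = MIN_CALIBRATION,
) -> pd.DataFrame:
    """1-month SPEI for a water-balance table, one independent fit per month.

    ``calibration`` is an inclusive (first_year, last_year) window; the
    default (None) calibrates on the full series.  Every calendar month
    present must supply at least ``min_calibration`` calibration values.
    Returns columns ``year, month, spei``.
    """
    if calibration is None:
        calibration = (int(wb["year"].min()), int(wb["year"].max()))
    lo, hi = calibration
    parts = []
    for month, grp in wb.groupby("month", sort=True):
        calib = grp[(grp["year"] >= lo) & (grp["year"] <= hi)]["d_value"]
        if len(calib) < min_calibration:
            raise ValueError(
                f"month {int(month)}: only {len(calib)} calibration values "
                f"(need {min_calibration})"
            )
        est = LogLogisticSpei(min_calibration=min_calibration).fit(calib.to_numpy())
        parts.append(
            pd.DataFrame(
                {
                    "year": grp["year"].to_numpy(),
                    "month": int(month),
                    "spei": est.transform(grp["d_value"].to_numpy()),
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["year", "month"]).reset_index(drop=True)
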
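"""Rifampicin-chase mRNA half-life estimation.

After transcription shut-off, the target signal at each time point is divided
by a stable reference RNA (16S rRNA) signal and scaled so time 0 is 100%.
When the decay is first order, ``ln(percent)`` is linear in time and the
half-life is ``t1/2 = ln 2 / k_decay`` with ``k_decay`` the negative slope of
the log-linear least-squares trendline.  When it is not, a linear trendline on
the percent scale gives ``k*_decay`` (%/min) and the fallback half-life
``t1/2 = 50 / k*_decay`` — the time to reach 50% by straight-line decline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .models import DecaySeries

__all__ = [
    "HalfLifeResult",
    "normalize_to_reference",
    "fit_first_order",
    "fit_linear",
    "choose_method",
]

LN2 = math.log(2.0)


@dataclass
class HalfLifeResult:
    """An estimated decay rate and half-life.

    ``rate`` is ``k_decay`` (1/min) for the first-order method or ``k*_decay``
    (%/min) for the linear method.  ``goodness`` is the R-squared of the
    trendline on the method's native scale (log-percent or percent).
    ``no_decay`` marks a non-negative fitted slope, in which case ``rate`` and
    ``half_life`` are NaN.
    """

    method: str
    rate: float
    half_life: float
    goodness: float
    n_points: int
    no_decay: bool = False
    alternative: "HalfLifeResult | None" = None

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "rate": self.rate,
            "half_life": self.half_life,
            "goodness": self.goodness,
            "n_points": self.n_points,
            "no_decay": self.no_decay,
        }
        if self.alternative is not None:
            alt = self.alternative.as_dict()
            alt.pop("alternative", None)
            d["alternative"] = alt
        return d


def normalize_to_reference(series: DecaySeries) -> DecaySeries:
    """Divide target by reference signal and set the time-0 ratio to 100%.

    ``percent[i] = 100 * (target[i]/reference[i]) / (target[0]/reference[0])``.
    Invariant to rescaling either channel by a positive constant.  The series
    constructor already rejects non-positive reference signals.
    """
    ratio = series.target_signal / series.reference_signal
    percent = 100.0 * ratio / ratio[0]
    return DecaySeries(
        times=series.times,
        target_signal=series.target_signal,
        reference_signal=series.reference_signal,
        percent_remaining=percent,
        label=series.label,
    )


def _require_normalized(series: DecaySeries, min_points: int = 3) -> np.ndarray:
    if series.percent_remaining is None:
        series = normalize_to_reference(series)
    if series.n_points < min_points:
        raise ValueError(
            f"insufficient points: need at least {min_points}, got {series.n_points}"
        )
    return series.percent_remaining


def fit_first_order(series: DecaySeries, nonlinear: bool = False) -> HalfLifeResult:
    """Exponential-trendline half-life: OLS of ``ln(percent)`` on time.

    ``k_decay`` is the negative slope (1/min) and ``t1/2 = ln 2 / k_decay``.
    R-squared is reported on the log scale.  With ``nonlinear=True`` the
    exponential ``A exp(-k t)`` is instead fit directly on the percent scale
    by least squares (R-squared then on the percent scale).
    """
    percent = _require_normalized(series)
    bad = np.flatnonzero(percent <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive percent-remaining at time(s) {series.times[bad].tolist()}: "
            "cannot take the log; use the linear method"
        )
    t = series.times
    if nonlinear:
        def resid(p):
            return p[0] * np.exp(-p[1] * t) - percent

        guess = np.array([percent[0], LN2 / max(t[-1], 1.0)])
        sol = optimize.least_squares(resid, guess, method="lm")
        amp, k = sol.x
        ss_res = float(np.sum(resid(sol.x) ** 2))
        ss_tot = float(np.sum((percent - percent.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        reg = stats.linregress(t, np.log(percent))
        k = -reg.slope
        r2 = float(reg.rvalue**2)
    if k <= 0:
        return HalfLifeResult("first_order", math.nan, math.nan,
                              max(0.0, min(1.0, r2)), series.n_points, no_decay=True)
    return HalfLifeResult(
        "first_order", float(k), LN2 / float(k), max(0.0, min(1.0, r2)), series.n_points
    )


def fit_linear(series: DecaySeries) -> HalfLifeResult:
    """Linear-trendline half-life: OLS of percent on time, ``t1/2 = 50 / k*``.

    ``k*_decay`` is the negative slope in %/min.  A non-negative slope yields a
    no-decay result with NaN rate and half-life.
    """
    percent = _require_normalized(series)
    reg = stats.linregress(series.times, percent)
    k_star = -reg.slope
    r2 = float(reg.rvalue**2)
    if k_star <= 0:
        return HalfLifeResult("linear", math.nan, math.nan,
                              max(0.0, min(1.0, r2)), series.n_points, no_decay=True)
    return HalfLifeResult(
        "linear", float(k_star), 50.0 / float(k_star), max(0.0, min(1.0, r2)),
        series.n_points
    )


def choose_method(series: DecaySeries, r2_threshold: float = 0.90) -> HalfLifeResult:
    """Pick the first-order estimator when it fits, the linear one otherwise.

    First-order is adequate when its log-scale R-squared reaches
    ``r2_threshold`` (and the series actually decays); the rejected
    candidate is attached as ``alternative`` either way.
    """
    _require_normalized(series)  # fail early on short series
    try:
        first = fit_first_order(series)
    except ValueError:
        first = None  # zero-crossing percent: exponential model inapplicable
    linear = fit_linear(series)
    if first is not None and not first.no_decay and first.goodness >= r2_threshold:
        first.alternative = linear
        return first
    linear.alternative = first
    return linear
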
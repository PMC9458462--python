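"""Mass-spec nucleoside level <-> per-base inosine rate conversions.

LC-MS/MS of digested RNA reports inosine as IMP nucleosides per 10^6 AMP
nucleosides. Because AMP makes up only a fraction f_A of all bases, the
per-base inosine frequency is

    freq = (IMP per 10^6 AMP) / 10^6 * f_A,

and the familiar '1 in N bases' denominator is the nearest integer to
1/freq. f_A can be taken from a reference sequence (:func:`a_fraction`) or
calibrated from a paired (level, denominator) measurement
(:func:`calibrate_f_A`) when the transcriptome composition is unknown.

Calibration curves for the instrument response use 1/x-weighted linear
regression (weighted least squares with w_i = 1/x_i), the standard choice
when the response SD grows with concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .io import TranscriptRef


@dataclass(frozen=True)
class MsLevel:
    """An IMP-per-10^6-AMP measurement with replicate spread."""

    imp_per_1e6_amp: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.imp_per_1e6_amp < 0 or self.sd < 0:
            raise ValueError("MS level and SD must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class IncorporationRate:
    """Per-base inosine frequency with its '1 in N bases' denominator."""

    freq_per_base: float
    denominator: int | None

    def __post_init__(self):
        if not 0 <= self.freq_per_base <= 1:
            raise ValueError("freq_per_base must lie in [0,1]")
        if self.denominator is not None:
            if abs(self.denominator - 1 / self.freq_per_base) > 0.5 + 1e-9:
                raise ValueError("denominator is not the nearest integer to 1/freq")


def a_fraction(ref: TranscriptRef) -> float:
    """Fraction of A among all bases of a reference transcript."""
    return ref.base_fractions["A"]


def rate_from_level(level: MsLevel | float, f_A: float) -> IncorporationRate:
    """Convert an IMP-per-10^6-AMP level into a per-base frequency.

    A level of 0 maps to frequency 0 with an undefined (None) denominator.
    """
    if not 0 < f_A < 1:
        raise ValueError("f_A must lie in (0,1)")
    value = level.imp_per_1e6_amp if isinstance(level, MsLevel) else float(level)
    freq = value / 1e6 * f_A
    if freq == 0:
        return IncorporationRate(0.0, None)
    return IncorporationRate(freq, round(1 / freq))


def level_from_rate(rate: IncorporationRate | float, f_A: float) -> MsLevel:
    """Inverse of :func:`rate_from_level` (exact before rounding)."""
    if not 0 < f_A < 1:
        raise ValueError("f_A must lie in (0,1)")
    freq = rate.freq_per_base if isinstance(rate, IncorporationRate) else float(rate)
    return MsLevel(freq * 1e6 / f_A)


def calibrate_f_A(level: float, denominator: float) -> float:
    """A-base fraction implied by a paired (level, '1 in N') measurement.

    Inverts freq = level/10^6 * f_A with freq = 1/denominator, giving
    f_A = 10^6 / (level * denominator). Used when the sample's base
    composition is not known from a reference sequence.
    """
    if level <= 0 or denominator <= 0:
        raise ValueError("level and denominator must be positive")
    return 1e6 / (level * denominator)


@dataclass(frozen=True)
class CalibrationCurve:
    """A 1/x-weighted linear calibration fit (response = a + b * x)."""

    slope: float
    intercept: float
    r_squared: float
    resid_sd: float
    weighting: str = "1/x"

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def weighted_linear_fit(x, y) -> CalibrationCurve:
    """Fit response = intercept + slope * x minimising sum (1/x_i)(resid_i)^2.

    Requires at least two distinct positive x (1/x weights are undefined at
    or below zero; constant x makes the design singular).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any():
        raise ValueError("1/x weighting requires strictly positive x")
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct x values")
    model = sm.WLS(y, sm.add_constant(x), weights=1.0 / x)
    fit = model.fit()
    resid = y - fit.fittedvalues
    dof = max(len(x) - 2, 1)
    return CalibrationCurve(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        resid_sd=float(np.sqrt(np.sum((1.0 / x) * resid**2) / dof)),
    )


def quantify_unknown(curve: CalibrationCurve, response: float) -> float:
    """Inverse prediction: concentration giving the observed response."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; inverse prediction undefined")
    return (response - curve.intercept) / curve.slope


def fold_ratio(level_a: float, level_b: float) -> float:
    """Ratio of two MS levels (e.g. the between-construct disparity)."""
    if level_b == 0:
        return math.nan
    return level_a / level_b
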
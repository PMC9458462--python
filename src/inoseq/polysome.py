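"""Translation quantification from polysome-profile absorbance traces.

A sucrose-gradient A254 trace resolves the 40S and 60S ribosomal subunits,
an (often unresolved) 80S-monosome-plus-disome peak, and the polysome
region. Quantification follows a landmark-guided geometric procedure:

1. normalize: subtract the minimum absorbance found between the 40S and 60S
   apexes from the whole trace (baseline subtraction);
2. peak boundaries at the lowest abutting points (argmin between adjacent
   apexes; leftmost on ties);
3. the polysome region starts at the trailing boundary of the 80S&disome
   peak and extends 1.42x the 60S-to-80S&disome apex distance (the factor
   is configurable);
4. areas by the composite trapezoid rule with linear interpolation at
   region endpoints;
5. the translation proxy is the polysome:(80S&disome) AUC ratio, compared
   between groups with a two-tailed Student's t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ProfileTrace

log = logging.getLogger(__name__)

DEFAULT_POLYSOME_FACTOR = 1.42


@dataclass(frozen=True)
class PeakLandmarks:
    """Approximate apex positions for 40S, 60S and 80S&disome peaks."""

    forty_s: float
    sixty_s: float
    eighty_s_disome: float

    def __post_init__(self):
        if not self.forty_s < self.sixty_s < self.eighty_s_disome:
            raise ValueError("landmark apexes must be strictly increasing")

    def validate_range(self, trace: ProfileTrace) -> None:
        lo, hi = trace.positions[0], trace.positions[-1]
        if not (lo <= self.forty_s and self.eighty_s_disome <= hi):
            raise ValueError("landmarks fall outside the trace range")


@dataclass(frozen=True)
class PeakBoundaries:
    """Lowest-abutting-point intervals for each labelled region."""

    forty_s: tuple[float, float]
    sixty_s: tuple[float, float]
    eighty_s_disome: tuple[float, float]
    polysome: tuple[float, float]
    normalization_point: float


@dataclass(frozen=True)
class TranslationMetrics:
    auc_polysome: float
    auc_80s_disome: float
    ratio: float | None


def _argmin_between(trace: ProfileTrace, lo: float, hi: float) -> float:
    """Position of the minimum absorbance in [lo, hi]; leftmost on ties."""
    sel = (trace.positions >= lo) & (trace.positions <= hi)
    if not sel.any():
        raise ValueError(f"no trace samples in [{lo}, {hi}]")
    idx = np.flatnonzero(sel)
    local = trace.absorbance[idx]
    ties = np.flatnonzero(local == local.min())
    if len(ties) > 1:
        log.debug("flat minimum in [%g, %g]; taking leftmost", lo, hi)
    return float(trace.positions[idx[ties[0]]])


def normalize_trace(trace: ProfileTrace, landmarks: PeakLandmarks) -> ProfileTrace:
    """Subtract the lowest point between the 40S and 60S apexes.

    Idempotent: the subtracted minimum of a normalized trace is 0.
    """
    landmarks.validate_range(trace)
    sel = (trace.positions >= landmarks.forty_s) & (trace.positions <= landmarks.sixty_s)
    baseline = float(trace.absorbance[sel].min())
    return ProfileTrace(trace.positions, trace.absorbance - baseline)


def find_boundaries(trace: ProfileTrace, landmarks: PeakLandmarks,
                    polysome_factor: float = DEFAULT_POLYSOME_FACTOR) -> PeakBoundaries:
    """Peak intervals defined by the lowest abutting points.

    The boundary between adjacent labelled peaks is the argmin between their
    apexes; the leading 40S boundary is the minimum before its apex; the
    trailing 80S&disome boundary is the minimum within a symmetric search
    span mirroring the 60S-to-apex distance (the procedure itself leaves
    this edge unstated; see the methods note).
    """
    landmarks.validate_range(trace)
    lead_40s = _argmin_between(trace, trace.positions[0], landmarks.forty_s)
    b_40_60 = _argmin_between(trace, landmarks.forty_s, landmarks.sixty_s)
    b_60_80 = _argmin_between(trace, landmarks.sixty_s, landmarks.eighty_s_disome)
    span = landmarks.eighty_s_disome - landmarks.sixty_s
    trail_hi = min(landmarks.eighty_s_disome + span, float(trace.positions[-1]))
    trail_80 = _argmin_between(trace, landmarks.eighty_s_disome, trail_hi)
    for name, (lo, hi) in {
        "40S": (lead_40s, b_40_60), "60S": (b_40_60, b_60_80),
        "80S&disome": (b_60_80, trail_80),
    }.items():
        if not lo < hi:
            raise ValueError(
                f"landmarks inconsistent with trace: degenerate {name} interval "
                f"[{lo}, {hi}] (no valley found)"
            )
    # an abutting point must be a genuine valley: strictly below both apexes
    y = lambda p: float(np.interp(p, trace.positions, trace.absorbance))
    for boundary, apexes in (
        (b_40_60, (landmarks.forty_s, landmarks.sixty_s)),
        (b_60_80, (landmarks.sixty_s, landmarks.eighty_s_disome)),
    ):
        if not all(y(boundary) < y(a) for a in apexes):
            raise ValueError(
                "landmarks inconsistent with trace: no valley between apexes "
                f"{apexes} (trace monotone there?)"
            )
    poly = polysome_region_from(
        landmarks, trail_80, float(trace.positions[-1]), polysome_factor
    )
    return PeakBoundaries(
        forty_s=(lead_40s, b_40_60),
        sixty_s=(b_40_60, b_60_80),
        eighty_s_disome=(b_60_80, trail_80),
        polysome=poly,
        normalization_point=b_40_60,
    )


def polysome_region_from(landmarks: PeakLandmarks, region_start: float,
                         trace_end: float,
                         factor: float = DEFAULT_POLYSOME_FACTOR) -> tuple[float, float]:
    """Polysome interval: starts at the 80S&disome trailing boundary and
    spans ``factor`` times the 60S-to-80S&disome apex distance, clipped to
    the trace end with a warning."""
    dist = landmarks.eighty_s_disome - landmarks.sixty_s
    if dist <= 0:
        raise ValueError("zero 60S-to-80S&disome distance")
    end = region_start + factor * dist
    if end > trace_end:
        warnings.warn(
            f"polysome region end {end:g} beyond trace end {trace_end:g}; truncated",
            stacklevel=2,
        )
        end = trace_end
    return (region_start, end)


def auc(trace: ProfileTrace, interval: tuple[float, float]) -> float:
    """Composite trapezoid-rule area over an interval.

    Interval endpoints falling between samples are handled by linear
    interpolation; an empty interval has area 0.
    """
    lo, hi = interval
    if hi <= lo:
        return 0.0
    x, y = trace.positions, trace.absorbance
    if lo < x[0] or hi > x[-1]:
        raise ValueError(f"interval {interval} outside trace range")
    inside = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inside], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))


def translation_ratio(trace: ProfileTrace, landmarks: PeakLandmarks,
                      polysome_factor: float = DEFAULT_POLYSOME_FACTOR,
                      *, normalize: bool = True) -> TranslationMetrics:
    """Full pipeline: normalize, find boundaries, integrate, form the ratio."""
    work = normalize_trace(trace, landmarks) if normalize else trace
    bounds = find_boundaries(work, landmarks, polysome_factor)
    a_poly = auc(work, bounds.polysome)
    a_mono = auc(work, bounds.eighty_s_disome)
    ratio = a_poly / a_mono if a_mono > 0 else None
    return TranslationMetrics(a_poly, a_mono, ratio)


@dataclass(frozen=True)
class GroupTest:
    t: float | None
    df: float | None
    p: float | None
    exact_separation: bool = False


def compare_groups(ratios_a, ratios_b, *, welch: bool = False) -> GroupTest:
    """Unpaired two-tailed t-test on translation ratios (Student's by
    default; Welch behind the flag)."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return GroupTest(0.0, float(len(a) + len(b) - 2), 1.0)
        return GroupTest(None, None, None, exact_separation=True)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = stats.ttest_ind(a, b, equal_var=False).df
    else:
        df = float(len(a) + len(b) - 2)
    return GroupTest(float(t), float(df), float(p))
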
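"""Calibration curves, limit of detection, and cohort statistics.

The calibration relates the fitted conductance-decline slope (min^-1) to
the NH3 concentration (ppm) with an ordinary least-squares line; its
inverse turns a measured slope into a concentration estimate.  The limit
of detection uses the classic blank-plus-three-sigma rule evaluated at the
tested concentrations.  Cohort comparisons use the one-tailed (right)
paired-samples t test, with the Student-t upper tail computed through the
regularized incomplete beta function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .errors import DegenerateFitError, InsufficientBlanksError, ParameterError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CohortResult",
    "linear_fit",
    "build_calibration",
    "invert_calibration",
    "estimate_lod",
    "student_t_sf",
    "paired_t_one_tailed",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration_ppm: float
    mean_slope: float  # min^-1
    sd_slope: float
    n: int


@dataclass(frozen=True)
class CalibrationCurve:
    points: tuple[CalibrationPoint, ...]
    fit_slope: float  # (min^-1) per ppm
    fit_intercept: float
    r_squared: float


@dataclass(frozen=True)
class CohortResult:
    """One-tailed (right) paired-samples t test of b > a."""

    pairs: tuple[tuple[float, float], ...]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r_squared).

    R^2 = 1 - SS_res/SS_tot, with the convention R^2 = 0 for flat y
    (SS_tot = 0).  All-identical x is a degenerate fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ParameterError("x and y must be equal-length 1-D with >= 2 points")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise DegenerateFitError("all x identical")
    slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
    intercept = float(ybar - slope * xbar)
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def build_calibration(runs) -> CalibrationCurve:
    """Per-concentration mean/SD of replicate slopes, then a line fit of
    mean slope on concentration.

    ``runs`` is an iterable of (concentration_ppm, slopes) with at least
    one replicate slope each; at least two distinct concentrations are
    required.
    """
    by_conc: dict[float, list[float]] = {}
    for conc, slopes in runs:
        if conc < 0:
            raise ParameterError("concentration must be nonnegative")
        vals = [float(s) for s in np.atleast_1d(slopes)]
        if not vals:
            raise ParameterError(f"no replicate slopes for {conc} ppm")
        by_conc.setdefault(float(conc), []).extend(vals)
    if len(by_conc) < 2:
        raise DegenerateFitError("need >= 2 distinct concentrations")
    points = tuple(
        CalibrationPoint(
            concentration_ppm=c,
            mean_slope=float(np.mean(v)),
            sd_slope=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            n=len(v),
        )
        for c, v in sorted(by_conc.items())
    )
    slope, intercept, r2 = linear_fit(
        [p.concentration_ppm for p in points], [p.mean_slope for p in points]
    )
    return CalibrationCurve(points=points, fit_slope=slope, fit_intercept=intercept, r_squared=r2)


def invert_calibration(curve: CalibrationCurve, slope: float) -> float:
    """Concentration (ppm, clipped at 0) whose fitted slope equals
    ``slope``."""
    if curve.fit_slope == 0:
        raise DegenerateFitError("calibration has zero slope; cannot invert")
    return max(0.0, (slope - curve.fit_intercept) / curve.fit_slope)


def estimate_lod(curve: CalibrationCurve, blank_slopes) -> float:
    """Smallest tested concentration whose mean |slope| exceeds
    mean|blank| + 3 * SD(|blank|); ``math.inf`` if none does.

    Requires at least three blank (0 ppm) replicate slopes.  Ties and
    scanning proceed from the lowest concentration upward.
    """
    blanks = np.abs(np.asarray(list(blank_slopes), float))
    if len(blanks) < 3:
        raise InsufficientBlanksError(f"need >= 3 blank slopes, got {len(blanks)}")
    threshold = blanks.mean() + 3.0 * blanks.std(ddof=1)
    for p in curve.points:  # points are sorted by concentration
        if p.concentration_ppm <= 0:
            continue
        if abs(p.mean_slope) > threshold:
            return p.concentration_ppm
    return math.inf


def student_t_sf(t: float, df: int) -> float:
    """Upper-tail probability of Student's t via the regularized
    incomplete beta function: sf(t) = I_{df/(df+t^2)}(df/2, 1/2) / 2 for
    t >= 0, and 1 - sf(-t) for t < 0."""
    if df < 1:
        raise ParameterError("df must be >= 1")
    if math.isinf(t):
        return 0.0 if t > 0 else 1.0
    half = 0.5 * float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return half if t >= 0 else 1.0 - half


def paired_t_one_tailed(a, b) -> CohortResult:
    """One-tailed (right) paired-samples t test of mean(b - a) > 0.

    Pairing is by index.  With a zero-variance nonzero difference the
    p-value is reported as 0 (or 1 for a negative difference); identical
    samples give t = 0, p = 0.5.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("a and b must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    d = b - a
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0:
        t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
    else:
        t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = student_t_sf(t, df)
    return CohortResult(
        pairs=tuple(zip(a.tolist(), b.tolist())),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
    )
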
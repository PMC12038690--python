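"""Signal processing: raw multi-channel traces -> one differential slope.

Two analysis chains are provided, matching the two experiment styles.

Chamber runs (constant RH): each acid-treated channel is normalized to its
pre-exposure baseline (dG/G0) and the post-peak decline is fitted with an
ordinary least-squares line; the slope, in min^-1, indicates the NH3
concentration.

Breathing / human runs: each channel is smoothed with a 1,000-point
centered moving average (100 s at 10 Hz, ~8 breathing cycles), divided by
its value at the 15-min endpoint, replicate channels of the same
functionalization are averaged, and the untreated-array signal is
subtracted from the acid-array signal:

    S_NH3(t) = S_A(t) - S_U(t).

Both arrays respond identically to humidity, so the difference isolates
acid neutralization.  The slope of the differential decline is extracted
either as a post-peak line fit or, for human recordings, on the interval
from 90% of peak height down to 20% after rescaling the differential to
its own maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .breath_simulator import ArrayRecording
from .errors import (
    DataError,
    DegenerateIntervalError,
    IncompatibleTracesError,
    MissingChannelError,
    NoDeclineError,
    ParameterError,
)

__all__ = [
    "Trace",
    "SlopeResult",
    "trace_from_channel",
    "moving_average",
    "normalize_baseline",
    "normalize_endpoint",
    "rescale_to_max",
    "differential",
    "channel_aggregate",
    "post_peak_slope",
    "peak_fraction_slope",
    "analyze_chamber",
    "analyze_breathing",
]


@dataclass(frozen=True)
class Trace:
    """A single time series on a uniform grid."""

    time: np.ndarray
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        if len(self.time) != len(self.values):
            raise ParameterError("time and values must have equal length")
        if len(self.time) < 2:
            raise ParameterError("trace needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("trace time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise DataError("trace time grid must be uniform")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SlopeResult:
    """A fitted decline slope with its interval and goodness of fit."""

    slope: float  # per minute
    t_start: float
    t_end: float
    r_squared: float
    method: str  # "post_peak" | "peak_fraction"

    @property
    def interval(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


def trace_from_channel(recording: ArrayRecording, channel_id: str) -> Trace:
    for ch in recording.channels:
        if ch.id == channel_id:
            return Trace(time=recording.time, values=np.asarray(ch.trace, float), kind="raw")
    raise MissingChannelError(channel_id)


def moving_average(trace: Trace, window_points: int = 1000) -> Trace:
    """Centered running mean with shrunken windows at the edges.

    Output has the same length as the input, so the recording endpoint
    stays defined for endpoint normalization.
    """
    if window_points < 1:
        raise ParameterError("window_points must be >= 1")
    if window_points > len(trace):
        raise ParameterError(
            f"window ({window_points}) longer than trace ({len(trace)})"
        )
    smoothed = (
        pd.Series(trace.values)
        .rolling(window_points, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(trace, values=smoothed, kind="smoothed")


def normalize_baseline(trace: Trace, baseline_window_s: tuple[float, float]) -> Trace:
    """(G - G0)/G0 with G0 the mean over the pre-exposure window."""
    lo, hi = baseline_window_s
    mask = (trace.time >= lo) & (trace.time <= hi)
    if not mask.any():
        raise ParameterError("baseline window contains no samples")
    g0 = float(trace.values[mask].mean())
    if g0 <= 0:
        raise DataError(f"baseline conductance must be positive, got {g0}")
    return replace(trace, values=(trace.values - g0) / g0, kind="baseline_norm")


def normalize_endpoint(trace: Trace, t_end: float | None = None) -> Trace:
    """Divide by the value at ``t_end`` (default: last sample); output is
    exactly 1 there."""
    idx = len(trace) - 1 if t_end is None else int(np.argmin(np.abs(trace.time - t_end)))
    ref = float(trace.values[idx])
    if ref <= 0:
        raise DataError(f"endpoint value must be positive, got {ref}")
    return replace(trace, values=trace.values / ref, kind="endpoint_norm")


def rescale_to_max(trace: Trace) -> Trace:
    """Divide by the trace maximum (used to compare differentials across
    subjects); requires a positive maximum."""
    peak = float(trace.values.max())
    if peak <= 0:
        raise DataError(f"trace maximum must be positive, got {peak}")
    return replace(trace, values=trace.values / peak)


def differential(s_a: Trace, s_u: Trace) -> Trace:
    """Pointwise S_A - S_U; inputs must share grid and kind."""
    if s_a.kind != s_u.kind:
        raise IncompatibleTracesError(f"kinds differ: {s_a.kind} vs {s_u.kind}")
    if len(s_a) != len(s_u) or not np.allclose(s_a.time, s_u.time, rtol=1e-9, atol=1e-9):
        raise IncompatibleTracesError("time grids differ")
    return Trace(time=s_a.time, values=s_a.values - s_u.values, kind="differential")


def channel_aggregate(
    recording: ArrayRecording,
    functionalization: str,
    prepare=None,
) -> Trace:
    """Pointwise mean over the channels of one functionalization.

    ``prepare`` optionally maps each raw channel :class:`Trace` (e.g.
    smoothing + normalization) before averaging.
    """
    matching = [ch for ch in recording.channels if ch.functionalization == functionalization]
    if not matching:
        raise MissingChannelError(f"no channel with functionalization {functionalization!r}")
    traces = []
    for ch in matching:
        t = Trace(time=recording.time, values=np.asarray(ch.trace, float), kind="raw")
        traces.append(prepare(t) if prepare is not None else t)
    kinds = {t.kind for t in traces}
    if len(kinds) > 1:
        raise IncompatibleTracesError(f"prepared traces have mixed kinds: {kinds}")
    values = np.mean([t.values for t in traces], axis=0)
    return Trace(time=recording.time, values=values, kind=traces[0].kind)


def _ols(t_min: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, r_squared)."""
    tbar, ybar = t_min.mean(), y.mean()
    sxx = float(((t_min - tbar) ** 2).sum())
    sxy = float(((t_min - tbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_res = float(((y - slope * t_min - intercept) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def post_peak_slope(
    trace: Trace, skip_after_peak_s: float = 30.0, search_until_s: float | None = None
) -> SlopeResult:
    """OLS line fit from (peak + skip) to the end of the trace.

    The peak is the global maximum; a peak at the very last sample means
    the trace never declines and is an error.  ``search_until_s`` limits
    the peak search to the early part of the trace, which stabilizes the
    fit on near-flat traces whose nominal maximum is a late noise
    excursion (the physical neutralization peak always comes early).
    """
    if search_until_s is None:
        peak_idx = int(np.argmax(trace.values))
    else:
        mask = trace.time <= search_until_s
        if not mask.any():
            raise ParameterError("search_until_s excludes every sample")
        peak_idx = int(np.argmax(trace.values[mask]))
    if peak_idx == len(trace) - 1:
        raise NoDeclineError("global maximum at final sample; no decline to fit")
    t_start = trace.time[peak_idx] + skip_after_peak_s
    mask = trace.time >= t_start
    if mask.sum() < 2:
        mask = trace.time >= trace.time[peak_idx]  # skip overshoots: fit from peak
    t_fit = trace.time[mask]
    slope, _, r2 = _ols(t_fit / 60.0, trace.values[mask])
    return SlopeResult(
        slope=slope,
        t_start=float(t_fit[0]),
        t_end=float(t_fit[-1]),
        r_squared=r2,
        method="post_peak",
    )


def peak_fraction_slope(trace: Trace, hi: float = 0.90, lo: float = 0.20) -> SlopeResult:
    """OLS slope between the 90%- and 20%-of-peak crossings after the peak.

    ``t_start`` is the first time after the peak at which the trace falls
    to ``hi * peak``; ``t_end`` the first subsequent time it falls to
    ``lo * peak`` (trace end if never reached).
    """
    if not 0 < lo < hi <= 1:
        raise ParameterError("require 0 < lo < hi <= 1")
    peak_idx = int(np.argmax(trace.values))
    peak = float(trace.values[peak_idx])
    if peak <= 0:
        raise DataError(f"peak must be positive, got {peak}")
    after = trace.values[peak_idx:]
    hi_rel = np.nonzero(after <= hi * peak)[0]
    if hi_rel.size == 0:
        raise DegenerateIntervalError(f"trace never declines to {hi:.0%} of its peak")
    i_start = peak_idx + int(hi_rel[0])
    lo_rel = np.nonzero(trace.values[i_start:] <= lo * peak)[0]
    i_end = i_start + int(lo_rel[0]) if lo_rel.size else len(trace) - 1
    if i_end <= i_start:
        i_end = min(i_start + 1, len(trace) - 1)
    if i_end == i_start:
        raise DegenerateIntervalError("slope interval is a single sample")
    sl = slice(i_start, i_end + 1)
    slope, _, r2 = _ols(trace.time[sl] / 60.0, trace.values[sl])
    return SlopeResult(
        slope=slope,
        t_start=float(trace.time[i_start]),
        t_end=float(trace.time[i_end]),
        r_squared=r2,
        method="peak_fraction",
    )


def analyze_chamber(
    recording: ArrayRecording,
    baseline_s: float = 120.0,
    skip_after_peak_s: float = 30.0,
    functionalization: str = "A",
) -> dict:
    """Chamber chain: baseline-normalize each matching channel, fit the
    post-peak decline, and average the per-channel slopes.

    Returns a report dict with per-channel G0, slopes and intervals.
    """
    per_channel = {}
    slopes = []
    for ch in recording.channels:
        if ch.functionalization != functionalization:
            continue
        raw = Trace(time=recording.time, values=np.asarray(ch.trace, float), kind="raw")
        g0 = float(raw.values[raw.time <= baseline_s].mean())
        norm = normalize_baseline(raw, (0.0, baseline_s))
        res = post_peak_slope(norm, skip_after_peak_s)
        per_channel[ch.id] = {"g0_S": g0, "slope_per_min": res.slope,
                              "interval_s": res.interval, "r_squared": res.r_squared}
        slopes.append(res.slope)
    if not slopes:
        raise MissingChannelError(f"no {functionalization!r} channel in recording")
    return {
        "mode": "chamber",
        "mean_slope_per_min": float(np.mean(slopes)),
        "channels": per_channel,
    }


def analyze_breathing(
    recording: ArrayRecording,
    method: str = "post_peak",
    window_points: int = 1000,
    skip_after_peak_s: float = 30.0,
    hi: float = 0.90,
    lo: float = 0.20,
) -> dict:
    """Breathing/human chain: smooth, endpoint-normalize, aggregate the A
    and U arrays, subtract, then extract the differential decline slope.

    ``method="post_peak"`` fits the decline directly (bench respiratory
    runs); ``method="peak_fraction"`` first rescales the differential to
    its own maximum and fits between the 90% and 20% crossings (human
    recordings, comparable across subjects).
    """
    if method not in ("post_peak", "peak_fraction"):
        raise ParameterError(f"unknown method {method!r}")

    def prepare(tr: Trace) -> Trace:
        return normalize_endpoint(moving_average(tr, window_points))

    s_a = channel_aggregate(recording, "A", prepare)
    s_u = channel_aggregate(recording, "U", prepare)
    diff = differential(s_a, s_u)
    if method == "post_peak":
        # The neutralization peak occurs while the water film still
        # equilibrates (first half of the recording); restricting the peak
        # search there keeps blank runs, whose nominal maximum is noise,
        # from yielding arbitrarily short fit windows.
        res = post_peak_slope(diff, skip_after_peak_s, search_until_s=float(diff.time[-1]) / 2.0)
    else:
        res = peak_fraction_slope(rescale_to_max(diff), hi, lo)
    return {
        "mode": "breath",
        "method": method,
        "slope_per_min": res.slope,
        "interval_s": res.interval,
        "r_squared": res.r_squared,
        "differential": diff,
    }
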
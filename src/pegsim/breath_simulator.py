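"""Exposure protocols and the array simulator.

A protocol is a piecewise-constant schedule of relative humidity, gas
concentrations and flow.  Two constructors cover the study designs:

* :func:`chamber_protocol` — constant-RH characterization runs with a
  pre-exposure baseline, a gas step, and a recovery phase;
* :func:`breathing_protocol` — simulated tidal breathing: 8 s of humid
  "exhale" (90% RH, 2,000 mL/min, NH3 mixed in) alternating with 4 s of
  room-air "inhale" (50% RH), i.e. five 12-s cycles per minute and an
  exhaled volume of ~267 mL per cycle.

:func:`run_simulation` advances an array of sensors through a protocol at a
fixed step (one step per sample) using operator splitting: water film ->
gas uptake -> slow desorption chemistry -> conductance readout.  All
sub-steps use exactly integrated updates, so halving the step barely
changes the result.  Optional measurement noise is applied multiplicatively
after the clean traces are computed, leaving the chemistry deterministic.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .sensor_physics import (
    DEFAULT_PARAMS,
    PhysicsParams,
    SensorState,
    _absorb_co2_inplace,
    _nh3_uptake_inplace,
    _desorb_inplace,
    _update_water_film_inplace,
    conductance,
    gas_molar_rate,
    water_film_equilibrium,
)

__all__ = [
    "ProtocolSegment",
    "ExposureProtocol",
    "NoiseParams",
    "ChannelRecording",
    "ArrayRecording",
    "chamber_protocol",
    "breathing_protocol",
    "run_simulation",
]

BREATH_EXHALE_S = 8.0
BREATH_INHALE_S = 4.0
BREATH_FLOW_ML_MIN = 2000.0
BREATH_EXHALE_RH = 90.0
BREATH_INHALE_RH = 50.0


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-condition stretch of an exposure schedule."""

    duration: float  # s
    rh: float  # %
    nh3_ppm: float = 0.0
    co2_pct: float = 0.0  # % v/v
    flow_mL_min: float = BREATH_FLOW_ML_MIN

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("segment duration must be positive")
        if not 0 <= self.rh <= 100:
            raise ParameterError("segment rh must be in [0, 100]")
        if self.nh3_ppm < 0 or self.co2_pct < 0 or self.flow_mL_min < 0:
            raise ParameterError("gas levels and flow must be nonnegative")


@dataclass(frozen=True)
class ExposureProtocol:
    """Ordered segments, optionally repeated, plus the starting humidity.

    ``initial_rh`` sets the water film at t=0: chamber runs start
    pre-equilibrated at the chamber humidity (the sensors sit in the
    chamber before logging starts), breathing runs start at room humidity.
    """

    segments: tuple[ProtocolSegment, ...]
    repeat_count: int = 1
    initial_rh: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("protocol needs at least one segment")
        if self.repeat_count < 1:
            raise ParameterError("repeat_count must be >= 1")

    @property
    def cycle_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def total_duration(self) -> float:
        return self.repeat_count * self.cycle_duration

    def segment_at(self, t: float) -> ProtocolSegment:
        """Segment active at time ``t`` (seconds from protocol start)."""
        tc = t % self.cycle_duration if t < self.total_duration else self.cycle_duration
        acc = 0.0
        for seg in self.segments:
            acc += seg.duration
            if tc < acc:
                return seg
        return self.segments[-1]

    def digest(self) -> str:
        """Short stable hash of the schedule, recorded in metadata."""
        text = f"{self.repeat_count}|" + "|".join(
            f"{s.duration},{s.rh},{s.nh3_ppm},{s.co2_pct},{s.flow_mL_min}" for s in self.segments
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative measurement-noise model for recorded traces.

    baseline_cv
        Lognormal coefficient of variation of the per-channel baseline
        multiplier (paper microstructure varies sensor to sensor).
    white_frac
        Standard deviation of per-sample white noise, as a fraction of the
        clean value.
    drift_frac
        Half-width of the uniform per-channel linear drift over the whole
        recording (instrument/contact drift).
    oscillation_frac
        Amplitude of an extra sinusoid at the breathing period (flow
        buffeting of the film beyond the modelled RH cycling).
    channel_multipliers
        Optional explicit baseline multipliers (one per channel); when
        given they override the lognormal draw — the cohort generator uses
        this to keep a subject's sensors identical across sessions.
    """

    baseline_cv: float = 0.15
    white_frac: float = 0.005
    drift_frac: float = 0.001
    oscillation_frac: float = 0.0
    oscillation_period_s: float = BREATH_EXHALE_S + BREATH_INHALE_S
    channel_multipliers: tuple[float, ...] | None = None


@dataclass
class ChannelRecording:
    id: str
    functionalization: str
    molarity: float
    trace: np.ndarray  # siemens


@dataclass
class ArrayRecording:
    """Timestamped multi-channel conductance traces plus metadata."""

    time: np.ndarray  # s, uniform grid
    channels: list[ChannelRecording]
    sample_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch in self.channels:
            if len(ch.trace) != len(self.time):
                raise ParameterError(f"channel {ch.id}: trace length != time length")

    def channel_ids(self) -> list[str]:
        return [ch.id for ch in self.channels]


def chamber_protocol(
    gas: str,
    conc: float,
    exposure_min: float,
    rh: float = 65.0,
    baseline_min: float = 2.0,
    recovery_min: float = 5.0,
    flow_mL_min: float = BREATH_FLOW_ML_MIN,
) -> ExposureProtocol:
    """Constant-RH characterization run: baseline, gas step, recovery.

    ``conc`` is ppm for NH3 and % v/v for CO2 (the conventions of the two
    exposure series).
    """
    if gas not in ("NH3", "CO2"):
        raise ParameterError(f"gas must be 'NH3' or 'CO2', got {gas!r}")
    if conc < 0:
        raise ParameterError("conc must be nonnegative")
    if exposure_min <= 0:
        raise ParameterError("exposure_min must be positive")
    nh3 = conc if gas == "NH3" else 0.0
    co2 = conc if gas == "CO2" else 0.0
    segs = (
        ProtocolSegment(baseline_min * 60.0, rh, 0.0, 0.0, flow_mL_min),
        ProtocolSegment(exposure_min * 60.0, rh, nh3, co2, flow_mL_min),
        ProtocolSegment(recovery_min * 60.0, rh, 0.0, 0.0, flow_mL_min),
    )
    return ExposureProtocol(
        segments=segs,
        repeat_count=1,
        initial_rh=rh,
        description=f"chamber {gas} {conc} for {exposure_min} min at {rh}% RH",
    )


def breathing_protocol(
    nh3_ppm: float,
    minutes: float,
    ambient_rh: float = DEFAULT_PARAMS.ambient_rh,
) -> ExposureProtocol:
    """Simulated tidal breathing with NH3 in the exhale stream only."""
    if nh3_ppm < 0:
        raise ParameterError("nh3_ppm must be nonnegative")
    if minutes <= 0:
        raise ParameterError("minutes must be positive")
    cycles = math.ceil(minutes * 60.0 / (BREATH_EXHALE_S + BREATH_INHALE_S))
    segs = (
        ProtocolSegment(BREATH_EXHALE_S, BREATH_EXHALE_RH, nh3_ppm, 0.0, BREATH_FLOW_ML_MIN),
        ProtocolSegment(BREATH_INHALE_S, BREATH_INHALE_RH, 0.0, 0.0, BREATH_FLOW_ML_MIN),
    )
    return ExposureProtocol(
        segments=segs,
        repeat_count=cycles,
        initial_rh=ambient_rh,
        description=f"breathing {nh3_ppm} ppm NH3 for {minutes} min",
    )


def run_simulation(
    sensors: list[SensorState],
    protocol: ExposureProtocol,
    sample_rate: float = 10.0,
    noise: NoiseParams | None = None,
    seed: int | None = None,
    params: PhysicsParams = DEFAULT_PARAMS,
    channel_ids: list[str] | None = None,
) -> ArrayRecording:
    """Run an array of sensors through a protocol and record conductance.

    One integration step per sample (default 0.1 s at 10 Hz).  Input sensor
    states are not modified.  Identical (sensors, protocol, seed) yield an
    identical recording.
    """
    if not sensors:
        raise ParameterError("need at least one sensor")
    if sample_rate <= 0:
        raise ParameterError("sample_rate must be positive")

    dt = 1.0 / sample_rate
    n_steps = int(round(protocol.total_duration * sample_rate))
    time = np.arange(n_steps) * dt

    states = [s.copy() for s in sensors]
    w0 = water_film_equilibrium(
        params.ambient_rh if protocol.initial_rh is None else protocol.initial_rh, params
    )
    for s in states:
        s.water_film = w0

    # Per-step schedule, precomputed once.
    rh_arr = np.empty(n_steps)
    nh3_rate = np.empty(n_steps)
    co2_rate = np.empty(n_steps)
    for seg_idx, (start, seg) in enumerate(_segment_spans(protocol)):
        i0 = int(round(start * sample_rate))
        i1 = int(round((start + seg.duration) * sample_rate))
        rh_arr[i0:i1] = seg.rh
        nh3_rate[i0:i1] = (
            gas_molar_rate(seg.nh3_ppm, seg.flow_mL_min, params, "NH3") if seg.nh3_ppm > 0 else 0.0
        )
        co2_rate[i0:i1] = (
            gas_molar_rate(seg.co2_pct * 1e4, seg.flow_mL_min, params, "CO2")
            if seg.co2_pct > 0
            else 0.0
        )

    traces = np.empty((len(states), n_steps))
    for i in range(n_steps):
        rh = rh_arr[i]
        d_nh3 = nh3_rate[i] * dt
        d_co2 = co2_rate[i] * dt
        for j, s in enumerate(states):
            _update_water_film_inplace(s, rh, dt, params)
            if d_nh3 > 0:
                _nh3_uptake_inplace(s, d_nh3, params)
            if d_co2 > 0:
                _absorb_co2_inplace(s, d_co2, params)
            _desorb_inplace(s, dt, params)
            traces[j, i] = conductance(s)

    if channel_ids is None:
        channel_ids = [
            f"ch{j + 1}_{s.functionalization}{s.deposit_molarity:g}" for j, s in enumerate(sensors)
        ]

    if noise is not None:
        traces = _apply_noise(traces, time, noise, np.random.default_rng(seed))

    channels = [
        ChannelRecording(
            id=channel_ids[j],
            functionalization=sensors[j].functionalization,
            molarity=sensors[j].deposit_molarity,
            trace=traces[j],
        )
        for j in range(len(sensors))
    ]
    meta = {
        "sample_rate": sample_rate,
        "seed": seed,
        "protocol": protocol.description,
        "protocol_hash": protocol.digest(),
        "noise": "on" if noise is not None else "off",
    }
    return ArrayRecording(time=time, channels=channels, sample_rate=sample_rate, meta=meta)


def _segment_spans(protocol: ExposureProtocol):
    """Yield (start_time, segment) pairs across all repeats."""
    t = 0.0
    for _ in range(protocol.repeat_count):
        for seg in protocol.segments:
            yield t, seg
            t += seg.duration


def _apply_noise(
    traces: np.ndarray, time: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    n_ch, n = traces.shape
    if noise.channel_multipliers is not None:
        if len(noise.channel_multipliers) != n_ch:
            raise ParameterError("channel_multipliers length must match channel count")
        mult = np.asarray(noise.channel_multipliers, dtype=float)
    else:
        sigma = math.sqrt(math.log(1.0 + noise.baseline_cv**2))
        mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_ch)
    out = traces * mult[:, None]
    span = time[-1] - time[0] if n > 1 else 1.0
    for j in range(n_ch):
        factor = np.ones(n)
        if noise.drift_frac > 0:
            slope = rng.uniform(-noise.drift_frac, noise.drift_frac)
            factor *= 1.0 + slope * (time - time[0]) / span
        if noise.oscillation_frac > 0:
            phase = rng.uniform(0, 2 * math.pi)
            factor *= 1.0 + noise.oscillation_frac * np.sin(
                2 * math.pi * time / noise.oscillation_period_s + phase
            )
        if noise.white_frac > 0:
            factor *= 1.0 + noise.white_frac * rng.standard_normal(n)
        out[j] *= factor
    np.maximum(out, 1e-15, out=out)
    return out
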
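"""Synthetic human-cohort generator.

Emulates the two-session human experiment: each subject wears the
mask-mounted sensor array for 15 minutes breathing normally (control) and
again while consuming NH4Cl-containing salty-licorice candy, which raises
breath NH3 to levels comparable with end-stage kidney disease.

Latent breath-NH3 concentrations are drawn from lognormal distributions
truncated to the published clinical ranges — healthy 425-1,800 ppb with
mean 960 ppb, diseased 820-14,700 ppb with mean 4,880 ppb — with the
location parameter solved so the truncated mean matches exactly.  A full
candy reproduces the disease distribution; half and quarter candies scale
the draw by the dose fraction with extra between-dose noise (consumption
style varies), which makes neighbouring doses overlap.

Each subject keeps a fixed per-channel baseline multiplier set and a fixed
personal room humidity across both sessions, so within-subject slope pairs
are positively correlated — the structure a paired t test exploits.
Recordings use a mask-chamber capture efficiency larger than the open
characterization chamber's: exhaled flow is ducted straight over the
sensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .breath_simulator import ArrayRecording, NoiseParams, breathing_protocol, run_simulation
from .errors import ParameterError
from .sensor_physics import DEFAULT_PARAMS, make_sensor
from .signal_pipeline import analyze_breathing

__all__ = [
    "CONDITIONS",
    "SubjectProfile",
    "CohortSpec",
    "sample_breath_nh3",
    "make_subject_profiles",
    "simulate_subject_recording",
    "cohort_slopes",
    "generate_cohort",
]

#: Published breath-NH3 ranges (ppb) and their means.
_HEALTHY = (425.0, 1800.0, 960.0)
_DISEASE = (820.0, 14700.0, 4880.0)

CONDITIONS = ("control", "candy_quarter", "candy_half", "candy_full", "disease")

#: Dose fraction of a full candy per condition.
_DOSE_FRACTION = {"candy_full": 1.0, "candy_half": 0.5, "candy_quarter": 0.25}

#: Between-dose lognormal noise (sigma of log) for partial candies; wide
#: enough that quarter and half doses overlap, as observed.
_DOSE_NOISE_SIGMA = 0.25

#: Capture efficiency of the mask sensor chamber, where exhaled flow is
#: ducted directly over the array (vs. the open characterization chamber).
MASK_CAPTURE_EFFICIENCY = 0.26

#: Rank correlation driver between a subject's two sessions.
_SESSION_RHO = 0.9

#: Between-subject spread of room humidity during a session (%RH).
_INHALE_RH_SD = 1.5

#: Default measurement noise for human recordings (noisier than the bench:
#: mask fit, motion, condensation).
HUMAN_NOISE = NoiseParams(
    baseline_cv=0.15, white_frac=0.005, drift_frac=0.05, oscillation_frac=0.02
)


class _TruncatedLognormal:
    """Lognormal truncated to [a, b] with its mean solved to a target.

    The log-scale sigma spans the range over eight standard deviations
    (concentrating mass around the clinical mean while keeping the stated
    extremes reachable); the location mu is then the unique root of
    E[X | a <= X <= b] = mean.
    """

    def __init__(self, a: float, b: float, mean: float):
        self.a, self.b, self.mean = a, b, mean
        self.sigma = (math.log(b) - math.log(a)) / 8.0
        self.mu = brentq(lambda m: self._truncated_mean(m) - mean, math.log(a), math.log(b))

    def _truncated_mean(self, mu: float) -> float:
        s = self.sigma
        alpha = (math.log(self.a) - mu) / s
        beta = (math.log(self.b) - mu) / s
        z = norm.cdf(beta) - norm.cdf(alpha)
        return math.exp(mu + 0.5 * s * s) * (norm.cdf(beta - s) - norm.cdf(alpha - s)) / z

    def ppf(self, u):
        """Inverse CDF of the truncated law for u in (0, 1)."""
        s = self.sigma
        alpha = (math.log(self.a) - self.mu) / s
        beta = (math.log(self.b) - self.mu) / s
        fa, fb = norm.cdf(alpha), norm.cdf(beta)
        return np.exp(self.mu + s * norm.ppf(fa + np.asarray(u) * (fb - fa)))

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))


_LATENT = {
    "control": _TruncatedLognormal(*_HEALTHY),
    "disease": _TruncatedLognormal(*_DISEASE),
}


def sample_breath_nh3(condition: str, rng: np.random.Generator, size=None):
    """Draw latent breath-NH3 level(s) in ppb for a condition.

    control / disease: truncated lognormal with the published range and
    mean.  candy_full draws from the disease law (a full candy simulates
    the diseased state); candy_half and candy_quarter scale a disease draw
    by the dose fraction with extra lognormal between-dose noise.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    if condition == "control":
        return _LATENT["control"].sample(rng, size)
    base = _LATENT["disease"].sample(rng, size)
    if condition in ("disease", "candy_full"):
        return base
    frac = _DOSE_FRACTION[condition]
    noise = np.exp(_DOSE_NOISE_SIGMA * rng.standard_normal(np.shape(base) or None))
    return base * frac * noise


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort experiment."""

    n_subjects: int = 8
    conditions: tuple[str, ...] = ("control", "candy_full")
    seed: int = 0
    recording_min: float = 15.0
    sample_rate: float = 10.0
    n_acid: int = 3
    acid_molarity: float = 0.01
    n_untreated: int = 3
    mask_capture_efficiency: float = MASK_CAPTURE_EFFICIENCY
    noise: NoiseParams = HUMAN_NOISE

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("paired designs need n_subjects >= 2")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ParameterError(f"unknown condition {c!r}")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject latent state shared across that subject's sessions."""

    subject_id: str
    condition: str
    breath_nh3_ppb: float
    channel_multipliers: tuple[float, ...]
    inhale_rh: float  # subject's room humidity, %RH
    seed: int
    oscillation_frac: float = 0.02
    drift_frac: float = 0.05
    white_frac: float = 0.005

    def __post_init__(self) -> None:
        if self.breath_nh3_ppb < 0:
            raise ParameterError("breath_nh3_ppb must be nonnegative")


def make_subject_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw the cohort: one profile per (subject, condition).

    A subject's channel multipliers and room humidity are drawn once and
    shared across conditions; latent NH3 levels across conditions share a
    correlated normal score (rank correlation), so a subject who runs high
    in one session tends to run high in the other.
    """
    rng = np.random.default_rng(spec.seed)
    n_ch = spec.n_acid + spec.n_untreated
    sigma = math.sqrt(math.log(1.0 + spec.noise.baseline_cv**2))
    profiles: list[SubjectProfile] = []
    for i in range(spec.n_subjects):
        multipliers = tuple(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_ch))
        inhale_rh = float(np.clip(rng.normal(50.0, _INHALE_RH_SD), 44.0, 56.0))
        z_subj = rng.standard_normal()
        for cond in spec.conditions:
            z = _SESSION_RHO * z_subj + math.sqrt(1 - _SESSION_RHO**2) * rng.standard_normal()
            u = norm.cdf(z)
            if cond == "control":
                latent = float(_LATENT["control"].ppf(u))
            else:
                base = float(_LATENT["disease"].ppf(u))
                frac = _DOSE_FRACTION.get(cond, 1.0)
                dose_noise = (
                    math.exp(_DOSE_NOISE_SIGMA * rng.standard_normal()) if frac < 1.0 else 1.0
                )
                latent = base * frac * dose_noise
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{i + 1:02d}",
                    condition=cond,
                    breath_nh3_ppb=latent,
                    channel_multipliers=multipliers,
                    inhale_rh=inhale_rh,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    oscillation_frac=spec.noise.oscillation_frac,
                    drift_frac=spec.noise.drift_frac,
                    white_frac=spec.noise.white_frac,
                )
            )
    return profiles


def simulate_subject_recording(
    profile: SubjectProfile,
    spec: CohortSpec,
    noise_override: NoiseParams | None = None,
) -> ArrayRecording:
    """Simulate one 15-min mask session for a subject.

    The subject's latent breath NH3 (ppb -> ppm) rides the exhale stream;
    the array is the human layout (three 0.01 M acid-treated plus three
    untreated sensors).  Pass ``noise_override`` (e.g. a zero-noise
    :class:`NoiseParams`) to strip measurement noise for parameter
    recovery checks.
    """
    params = replace(DEFAULT_PARAMS, capture_efficiency=spec.mask_capture_efficiency)
    sensors = [
        make_sensor("A", spec.acid_molarity, params=params) for _ in range(spec.n_acid)
    ] + [make_sensor("U", 0.0, params=params) for _ in range(spec.n_untreated)]
    protocol = breathing_protocol(
        profile.breath_nh3_ppb / 1000.0, spec.recording_min, ambient_rh=profile.inhale_rh
    )
    # The subject's inhale RH replaces the generic 50% room air.
    segs = list(protocol.segments)
    segs[1] = replace(segs[1], rh=profile.inhale_rh)
    protocol = replace(protocol, segments=tuple(segs))
    if noise_override is not None:
        noise = noise_override
    else:
        noise = NoiseParams(
            white_frac=profile.white_frac,
            drift_frac=profile.drift_frac,
            oscillation_frac=profile.oscillation_frac,
            channel_multipliers=profile.channel_multipliers,
        )
    rec = run_simulation(
        sensors,
        protocol,
        sample_rate=spec.sample_rate,
        noise=noise,
        seed=profile.seed,
        params=params,
    )
    rec.meta.update(
        subject=profile.subject_id,
        condition=profile.condition,
        breath_nh3_ppb=profile.breath_nh3_ppb,
    )
    return rec


def cohort_slopes(spec: CohortSpec, noise_override: NoiseParams | None = None):
    """Simulate the whole cohort and run the human pipeline on each
    recording.

    Returns a list of dicts (subject, condition, breath_nh3_ppb, slope)
    where ``slope`` is the magnitude of the 90%-to-20% differential
    decline in min^-1.
    """
    rows = []
    for profile in make_subject_profiles(spec):
        rec = simulate_subject_recording(profile, spec, noise_override)
        report = analyze_breathing(rec, method="peak_fraction")
        rows.append(
            {
                "subject": profile.subject_id,
                "condition": profile.condition,
                "breath_nh3_ppb": profile.breath_nh3_ppb,
                "slope": abs(report["slope_per_min"]),
            }
        )
    return rows


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write the cohort dataset: one recording CSV per (subject,
    condition), a shared channels.csv, and manifest.csv.

    Returns the output directory path.
    """
    from .recording_io import write_recording  # deferred: io imports this module's types

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = ["subject,condition,breath_nh3_ppb,seed,file"]
    channels_written = False
    for profile in make_subject_profiles(spec):
        rec = simulate_subject_recording(profile, spec)
        name = f"{profile.subject_id}_{profile.condition}.csv"
        write_recording(rec, out / name, channels_path=None if channels_written else out / "channels.csv")
        channels_written = True
        manifest_rows.append(
            f"{profile.subject_id},{profile.condition},"
            f"{profile.breath_nh3_ppb:.6g},{profile.seed},{name}"
        )
    (out / "manifest.csv").write_text("\n".join(manifest_rows) + "\n")
    return out
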
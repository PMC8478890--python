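"""Synthetic walking-exposure cohort generator.

Generates volunteer cohorts, street-level PM2.5/PM10 exposure trajectories,
1 Hz heart-rate responses, and per-interval subjective safe/risk labels with
the statistical structure the downstream threshold and logit analyses
assume, so that the whole pipeline is runnable and testable without any
field data.

The cohort is stratified into four (gender, age) groups.  Each volunteer
carries a latent PM2.5 risk threshold (μg/m³): walking intervals whose
PM2.5 reading exceeds it are subjectively reported as "risk" (optionally
flipped by label noise).  Heart rate during the walk is the volunteer's
resting baseline plus a group-specific elevation that rises monotonically
with PM2.5 — affine for young males, a double-logistic S-curve with
inflections near 100 and 180 μg/m³ for the other groups — plus Gaussian
noise.  PM10 is an affine function of PM2.5 plus noise, floored at PM2.5.

All randomness derives from one root seed; each volunteer owns an
independent substream keyed by a CRC32 of their identifier, so results are
reproducible regardless of iteration order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GENDERS",
    "AGE_GROUPS",
    "GROUP_ORDER",
    "ConfigError",
    "HeartRateResponse",
    "SimulationConfig",
    "VolunteerProfile",
    "WalkRecording",
    "generate_cohort",
    "simulate_walk",
    "simulate_cohort",
    "cohort_summary",
]

GENDERS = ("male", "female")
AGE_GROUPS = ("youth", "middle_aged")

#: canonical group iteration order: (gender, age_group)
GROUP_ORDER = (
    ("male", "youth"),
    ("female", "youth"),
    ("male", "middle_aged"),
    ("female", "middle_aged"),
)

_BMI_HEALTHY_LO, _BMI_HEALTHY_HI = 18.5, 24.0


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class HeartRateResponse:
    """Expected heart-rate elevation above resting baseline vs PM2.5.

    ``kind="linear"``  : elevation = intercept + slope·pm25
    ``kind="scurve"``  : elevation = offset + amplitude·(σ((pm−x₁)/w) + σ((pm−x₂)/w))
    where σ is the standard logistic; the two logistic components place the
    S-curve's bends near the inflection concentrations x₁ and x₂.
    Both forms are monotone increasing in PM2.5.
    """

    kind: str = "linear"
    intercept: float = 0.0
    slope: float = 0.0
    offset: float = 0.0
    amplitude: float = 0.0
    inflections: tuple[float, float] = (100.0, 180.0)
    width: float = 25.0

    def elevation(self, pm25):
        pm25 = np.asarray(pm25, dtype=float)
        if self.kind == "linear":
            return self.intercept + self.slope * pm25
        if self.kind == "scurve":
            x1, x2 = self.inflections
            s = _expit((pm25 - x1) / self.width) + _expit((pm25 - x2) / self.width)
            return self.offset + self.amplitude * s
        raise ConfigError(f"hr_response.kind: unknown kind {self.kind!r}")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _default_group_sizes() -> dict:
    return {
        ("male", "youth"): 112,
        ("female", "youth"): 97,
        ("male", "middle_aged"): 85,
        ("female", "middle_aged"): 74,
    }


def _default_latent_params() -> dict:
    # Per-group latent PM2.5 threshold mean/SD (μg/m³).  The group means are
    # the additive-model solution whose cohort-weighted marginals give
    # male 136, female 127, youth 145, middle-aged 114 μg/m³ at the default
    # group sizes; see docs/methods.md.
    return {
        ("male", "youth"): (149.4, 20.0),
        ("female", "youth"): (140.5, 20.0),
        ("male", "middle_aged"): (118.5, 20.0),
        ("female", "middle_aged"): (109.5, 20.0),
    }


def _default_hr_responses() -> dict:
    # Calibrated so pooled walking heart rates per group approximate the
    # published summary statistics (means 80.69 / 84.14 / 85.29 / 88.25 bpm)
    # with a ~64 bpm mean resting baseline and PM2.5 ~ uniform on 0–300.
    return {
        ("male", "youth"): HeartRateResponse(kind="linear", intercept=1.7, slope=0.10),
        ("female", "youth"): HeartRateResponse(kind="scurve", offset=9.5, amplitude=10.0),
        ("male", "middle_aged"): HeartRateResponse(kind="scurve", offset=11.7, amplitude=9.0),
        ("female", "middle_aged"): HeartRateResponse(kind="scurve", offset=15.2, amplitude=8.5),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults reproduce the study design.

    Units: durations s, concentrations μg/m³, heart rate bpm, height m,
    weight kg.
    """

    group_sizes: dict = field(default_factory=_default_group_sizes)
    seed: int = 0
    walk_duration: float = 3600.0
    pm_range: tuple[float, float] = (0.0, 300.0)
    pm_sample_interval: float = 60.0
    pm_step_noise_sd: float = 8.0
    latent_threshold_params: dict = field(default_factory=_default_latent_params)
    bmi_threshold_effect: float = 12.0
    label_noise: float = 0.05
    hr_noise_sd: float = 3.0
    pm10_ratio_params: tuple[float, float, float] = (1.5, 20.0, 10.0)  # slope, intercept, noise SD
    baseline_hr_mean: float = 64.0
    baseline_hr_sd: float = 5.0
    hr_responses: dict = field(default_factory=_default_hr_responses)

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if group not in GROUP_ORDER:
                raise ConfigError(f"group_sizes: unknown group {group!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ConfigError(f"group_sizes[{group}]: count must be a non-negative integer")
        lo, hi = self.pm_range
        if not (0.0 <= lo < hi <= 1000.0):
            raise ConfigError("pm_range: need 0 <= min < max <= 1000 μg/m³")
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigError("label_noise: must lie in [0, 0.5)")
        if self.hr_noise_sd < 0:
            raise ConfigError("hr_noise_sd: must be >= 0")
        if self.pm_step_noise_sd < 0:
            raise ConfigError("pm_step_noise_sd: must be >= 0")
        if self.walk_duration <= 0:
            raise ConfigError("walk_duration: must be > 0 s")
        if self.pm_sample_interval <= 0:
            raise ConfigError("pm_sample_interval: must be > 0 s")
        if self.walk_duration < self.pm_sample_interval:
            raise ConfigError("walk_duration: shorter than one pm_sample_interval")
        for group in GROUP_ORDER:
            if self.group_sizes.get(group, 0) > 0 and group not in self.latent_threshold_params:
                raise ConfigError(f"latent_threshold_params: missing group {group!r}")
            if self.group_sizes.get(group, 0) > 0 and group not in self.hr_responses:
                raise ConfigError(f"hr_responses: missing group {group!r}")
        for group, (mean, sd) in self.latent_threshold_params.items():
            if sd < 0:
                raise ConfigError(f"latent_threshold_params[{group}]: SD must be >= 0")
        if self.baseline_hr_mean <= 0:
            raise ConfigError("baseline_hr_mean: must be > 0 bpm")

    # -- flat-key serialisation (YAML config files) --------------------

    @staticmethod
    def _group_key(group: tuple[str, str]) -> str:
        return f"{group[0]}_{group[1]}"

    @staticmethod
    def _parse_group_key(key: str) -> tuple[str, str]:
        for gender in GENDERS:
            prefix = gender + "_"
            if key.startswith(prefix):
                age = key[len(prefix):]
                if age in AGE_GROUPS:
                    return (gender, age)
        raise ConfigError(f"group key {key!r} not of the form <gender>_<age_group>")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "walk_duration": self.walk_duration,
            "pm_range": list(self.pm_range),
            "pm_sample_interval": self.pm_sample_interval,
            "pm_step_noise_sd": self.pm_step_noise_sd,
            "bmi_threshold_effect": self.bmi_threshold_effect,
            "label_noise": self.label_noise,
            "hr_noise_sd": self.hr_noise_sd,
            "pm10_ratio_params": list(self.pm10_ratio_params),
            "baseline_hr_mean": self.baseline_hr_mean,
            "baseline_hr_sd": self.baseline_hr_sd,
            "group_sizes": {self._group_key(g): int(n) for g, n in self.group_sizes.items()},
            "latent_threshold_params": {
                self._group_key(g): list(map(float, v))
                for g, v in self.latent_threshold_params.items()
            },
            "hr_responses": {
                self._group_key(g): {
                    "kind": r.kind,
                    "intercept": r.intercept,
                    "slope": r.slope,
                    "offset": r.offset,
                    "amplitude": r.amplitude,
                    "inflections": list(r.inflections),
                    "width": r.width,
                }
                for g, r in self.hr_responses.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls()
        d = dict(d)
        if "group_sizes" in d:
            cfg.group_sizes = {
                cls._parse_group_key(k): int(v) for k, v in d.pop("group_sizes").items()
            }
        if "latent_threshold_params" in d:
            cfg.latent_threshold_params = {
                cls._parse_group_key(k): tuple(map(float, v))
                for k, v in d.pop("latent_threshold_params").items()
            }
        if "hr_responses" in d:
            cfg.hr_responses = {}
            for k, r in d.pop("hr_responses").items():
                r = dict(r)
                if "inflections" in r:
                    r["inflections"] = tuple(r["inflections"])
                cfg.hr_responses[cls._parse_group_key(k)] = HeartRateResponse(**r)
        if "pm_range" in d:
            cfg.pm_range = tuple(d.pop("pm_range"))
        if "pm10_ratio_params" in d:
            cfg.pm10_ratio_params = tuple(d.pop("pm10_ratio_params"))
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown configuration field {k!r}")
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def copy(self, **updates) -> "SimulationConfig":
        return replace(self, **updates)


@dataclass(frozen=True)
class VolunteerProfile:
    """Demographics and resting physiology of one subject."""

    volunteer_id: str
    gender: str  # "male" | "female"
    age_group: str  # "youth" | "middle_aged"
    height: float  # m
    weight: float  # kg
    baseline_hr: float  # bpm, mean of the 10-min resting measurement

    @property
    def group(self) -> tuple[str, str]:
        return (self.gender, self.age_group)

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @property
    def bmi_healthy(self) -> bool:
        return _BMI_HEALTHY_LO <= self.bmi <= _BMI_HEALTHY_HI


@dataclass
class WalkRecording:
    """One simulated (or ingested) walking trip.

    ``hr_time``/``hr_bpm``: 1 Hz heart-rate series. ``pm_time``/``pm25``/
    ``pm10``: 1-min particulate series. ``labels`` holds one subjective
    safe(0)/risk(1) judgment per PM sampling interval, indexed implicitly
    0..n-1.  ``latent_threshold`` is the simulation ground truth (NaN for
    ingested real data).
    """

    volunteer_id: str
    hr_time: np.ndarray
    hr_bpm: np.ndarray
    pm_time: np.ndarray
    pm25: np.ndarray
    pm10: np.ndarray
    labels: np.ndarray
    latent_threshold: float = float("nan")

    def label_pairs(self):
        """Labels as (interval_index, state) pairs."""
        return list(enumerate(int(s) for s in self.labels))


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _volunteer_key(volunteer_id: str) -> int:
    return zlib.crc32(volunteer_id.encode("utf-8"))


def generate_cohort(config: SimulationConfig) -> list[VolunteerProfile]:
    """Draw the stratified cohort of volunteer profiles.

    Heights are gender-specific, weights derive from a BMI draw spanning
    both the healthy band [18.5, 24] and outside it, resting baselines are
    ~N(mean, sd) clipped to a physiological range.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    profiles: list[VolunteerProfile] = []
    idx = 0
    for group in GROUP_ORDER:
        n = int(config.group_sizes.get(group, 0))
        gender, age_group = group
        for _ in range(n):
            rng = _substream(config.seed, 0, idx)
            if gender == "male":
                height = float(np.clip(rng.normal(1.72, 0.07), 1.45, 2.05))
            else:
                height = float(np.clip(rng.normal(1.60, 0.06), 1.45, 2.05))
            bmi = float(np.clip(rng.normal(22.5, 3.5), 16.0, 35.0))
            weight = float(np.clip(bmi * height**2, 35.0, 160.0))
            baseline = float(
                np.clip(rng.normal(config.baseline_hr_mean, config.baseline_hr_sd), 45.0, 110.0)
            )
            profiles.append(
                VolunteerProfile(
                    volunteer_id=f"V{idx:04d}",
                    gender=gender,
                    age_group=age_group,
                    height=round(height, 3),
                    weight=round(weight, 2),
                    baseline_hr=round(baseline, 2),
                )
            )
            idx += 1
    return profiles


def latent_threshold(profile: VolunteerProfile, config: SimulationConfig) -> float:
    """The volunteer's latent PM2.5 risk threshold (simulation ground truth).

    Group mean shifted by ±bmi_threshold_effect for healthy/non-healthy BMI
    plus a Gaussian perturbation; identical to the draw ``simulate_walk``
    uses, so tests can recover it independently.
    """
    rng = _substream(config.seed, 1, _volunteer_key(profile.volunteer_id))
    return _draw_latent(profile, config, rng)


def _draw_latent(profile, config, rng) -> float:
    mean, sd = config.latent_threshold_params[profile.group]
    mean = mean + (config.bmi_threshold_effect if profile.bmi_healthy else -config.bmi_threshold_effect)
    lo, hi = config.pm_range
    value = mean + rng.normal(0.0, sd)
    # keep the threshold inside the observable band so labels are defined
    return float(np.clip(value, lo + 1.0, hi - 1.0))


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [lo, hi] (triangle fold)."""
    span = hi - lo
    m = np.mod(u - lo, 2.0 * span)
    return lo + (span - np.abs(span - m))


def simulate_walk(profile: VolunteerProfile, config: SimulationConfig) -> WalkRecording:
    """Simulate one walking trip for ``profile``.

    The PM2.5 trajectory is a reflected random walk at the PM sampling
    interval with a deterministic drift whose total travel is twice the
    configured range, so the walk sweeps the whole range (and therefore
    crosses the volunteer's latent threshold) in every realisation; noise
    perturbs each step.  Heart rate at 1 Hz is baseline + group response to
    the zero-order-held PM2.5 + N(0, hr_noise_sd).  Labels flag intervals
    whose PM2.5 reading exceeds the latent threshold, then flip
    independently with probability ``label_noise``.
    """
    config.validate()
    rng = _substream(config.seed, 1, _volunteer_key(profile.volunteer_id))
    latent = _draw_latent(profile, config, rng)

    lo, hi = config.pm_range
    dt = config.pm_sample_interval
    n_pm = int(config.walk_duration // dt)
    if n_pm < 1:
        raise ConfigError("walk_duration: shorter than one pm_sample_interval")

    direction = 1.0 if rng.random() < 0.5 else -1.0
    u0 = rng.uniform(lo, hi)
    if n_pm > 1:
        drift = direction * 2.0 * (hi - lo) / (n_pm - 1)
        steps = drift + rng.normal(0.0, config.pm_step_noise_sd, size=n_pm - 1)
        u = np.concatenate([[u0], u0 + np.cumsum(steps)])
    else:
        u = np.array([u0])
    pm25 = _fold(u, lo, hi)
    pm_time = np.arange(n_pm, dtype=float) * dt

    slope, intercept, pm10_noise = config.pm10_ratio_params
    pm10 = intercept + slope * pm25 + rng.normal(0.0, pm10_noise, size=n_pm)
    pm10 = np.maximum(pm10, pm25)  # mass-fraction consistency

    n_hr = int(config.walk_duration)
    hr_time = np.arange(n_hr, dtype=float)
    pm_1hz = pm25[np.minimum((hr_time // dt).astype(int), n_pm - 1)]
    response = config.hr_responses[profile.group]
    hr = profile.baseline_hr + response.elevation(pm_1hz)
    if config.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, config.hr_noise_sd, size=n_hr)

    labels = (pm25 > latent).astype(np.int64)
    if config.label_noise > 0:
        flips = rng.random(n_pm) < config.label_noise
        labels = labels ^ flips.astype(np.int64)

    return WalkRecording(
        volunteer_id=profile.volunteer_id,
        hr_time=hr_time,
        hr_bpm=hr,
        pm_time=pm_time,
        pm25=pm25,
        pm10=pm10,
        labels=labels,
        latent_threshold=latent,
    )


def simulate_cohort(config: SimulationConfig):
    """Generate the cohort and one walk per volunteer.

    Returns ``(profiles, recordings)`` in matched order.
    """
    profiles = generate_cohort(config)
    recordings = [simulate_walk(p, config) for p in profiles]
    return profiles, recordings


def cohort_summary(
    recordings: list[WalkRecording], profiles: list[VolunteerProfile]
) -> pd.DataFrame:
    """Pooled walking heart-rate statistics per (gender, age) group.

    One row per non-empty group with mean/SD/max/min over all 1 Hz samples;
    empty groups are omitted with a warning.
    """
    by_id = {p.volunteer_id: p for p in profiles}
    pooled: dict[tuple[str, str], list[np.ndarray]] = {g: [] for g in GROUP_ORDER}
    for rec in recordings:
        prof = by_id.get(rec.volunteer_id)
        if prof is None:
            warnings.warn(f"recording {rec.volunteer_id} has no profile; skipped")
            continue
        pooled[prof.group].append(rec.hr_bpm)
    rows = []
    for group in GROUP_ORDER:
        chunks = pooled[group]
        if not chunks:
            warnings.warn(f"group {group} has no recordings; row omitted")
            continue
        hr = np.concatenate(chunks)
        rows.append(
            {
                "gender": group[0],
                "age_group": group[1],
                "mean": float(hr.mean()),
                "sd": float(hr.std(ddof=1)) if hr.size > 1 else 0.0,
                "max": float(hr.max()),
                "min": float(hr.min()),
                "n_samples": int(hr.size),
                "n_volunteers": len(chunks),
            }
        )
    return pd.DataFrame(rows)
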
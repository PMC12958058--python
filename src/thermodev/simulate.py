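"""Synthetic rearing data with known ground truth.

The generators emulate a constant-temperature rearing experiment on a
cold-adapted blow fly, with the statistical structure the downstream
analysis assumes, so that every fitting routine can be tested against a
known truth:

* **stage durations** follow the degree-day hyperbola
  D = K / (T - D0) with multiplicative lognormal noise — durations are
  positive and their spread grows with the mean, as rearing data show
  (SDs at 15 degC are an order of magnitude above those at 25 degC);
* **larval length** follows a logistic ("S-shaped") trajectory in
  physiological time tau = t * (T - D0_larval) degree-hours:
  L(tau) = L_max / (1 + exp(-rho * (tau - tau0))), plus Normal
  measurement noise. The logistic is deliberately a different family from
  the cubic the analysis fits, keeping the fit validation honest, and
  physiological time makes warmer larvae reach every length earlier —
  the monotonicity the isomegalen diagram encodes;
* **pupal weight** declines with accelerating loss,
  W(t) = W0 * (1 - f * (t / t_eclosion)^p) with p > 1, while length and
  width stay near-constant (the puparium constrains external dimensions);
* **temperature logs** are constant or sinusoidal hourly records for
  exercising the PMI engine.

All generators are pure functions of (arguments, seed); per-(stage,
temperature) substreams mean adding replicates extends, never perturbs,
existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import STAGES, validate_duration_table, validate_measurement_series, \
    validate_temperature_log, TEMPERATURE_RANGE
from .exceptions import ValidationError

__all__ = [
    "SyntheticTruth",
    "ConstantProfile",
    "SinusoidProfile",
    "generate_cohort",
    "generate_length_series",
    "generate_pupal_series",
    "generate_temperature_log",
]

#: Default per-stage ground truth (K degree-hours, D0 degC), patterned on
#: published estimates for this species so the synthetic study runs at a
#: realistic operating point.
DEFAULT_STAGE_PARAMS: dict[str, tuple[float, float]] = {
    "hatching": (292.59, 11.81),
    "instar2": (792.19, 7.62),
    "instar3": (632.74, 12.11),
    "wandering": (525.71, 8.33),
    "pupation": (3086.54, 3.59),
    "eclosion": (506.50, 12.88),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind all synthetic outputs.

    Units: K degree-hours, D0 degC, lengths mm, weights g, times hours,
    rho 1/(degC*h), tau0 degC*h.
    """

    stage_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PARAMS))
    # larval logistic growth (physiological time)
    L_max: float = 17.0
    rho: float = 0.006
    tau0: float = 700.0
    D0_larval: float = 11.81
    # pupal weight loss
    W0: float = 0.080
    loss_fraction: float = 0.30
    accel_exponent: float = 2.0
    K_pupal: float = 4070.0
    D0_pupal: float = 3.59
    pupal_length: float = 9.0
    pupal_width: float = 3.5
    # noise model
    sigma_duration: float = 0.1        # lognormal sigma on durations
    sd_length: float = 0.2             # mm, additive
    sd_width: float = 0.1              # mm, additive
    sd_weight: float = 0.002           # g, additive
    eclosion_fraction: float = 0.8     # completion fraction emitted in manifests

    def __post_init__(self) -> None:
        for stage, (K, D0) in self.stage_params.items():
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}")
            if K <= 0:
                raise ValidationError(f"{stage}: K must be > 0")
        for name in ("sigma_duration", "sd_length", "sd_width", "sd_weight"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.accel_exponent > 1:
            raise ValidationError("accel_exponent must be > 1 (accelerating loss)")

    @property
    def max_D0(self) -> float:
        return max(D0 for _, D0 in self.stage_params.values())

    def expected_duration(self, stage: str, temperature: float) -> float:
        """Median (noiseless) duration K / (T - D0) for one stage."""
        K, D0 = self.stage_params[stage]
        if temperature <= D0:
            raise ValidationError(
                f"{stage}: temperature {temperature} degC at or below the "
                f"threshold D0 = {D0} degC — development undefined")
        return K / (temperature - D0)

    def larval_midpoint(self, temperature: float) -> float:
        """Clock time (h after hatching) of half-maximal length."""
        return self.tau0 / (temperature - self.D0_larval)

    def larval_length(self, t, temperature: float) -> np.ndarray:
        """Noiseless logistic length (mm) at time t hours after hatching."""
        tau = np.asarray(t, dtype=float) * (temperature - self.D0_larval)
        return self.L_max / (1.0 + np.exp(-self.rho * (tau - self.tau0)))

    def pupal_duration(self, temperature: float) -> float:
        """Pupariation-to-eclosion span (h) at a constant temperature."""
        if temperature <= self.D0_pupal:
            raise ValidationError(
                f"temperature {temperature} degC at or below the pupal "
                f"threshold {self.D0_pupal} degC")
        return self.K_pupal / (temperature - self.D0_pupal)

    def pupal_weight(self, t, temperature: float) -> np.ndarray:
        """Noiseless pupal weight (g) at t hours after pupariation."""
        t_ecl = self.pupal_duration(temperature)
        frac = np.clip(np.asarray(t, dtype=float) / t_ecl, 0.0, 1.0)
        return self.W0 * (1.0 - self.loss_fraction * frac ** self.accel_exponent)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_params"] = {k: list(v) for k, v in self.stage_params.items()}
        return d


def _rng(seed: int, *key: int) -> np.random.Generator:
    # independent substream per structural key; stable under added replicates
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_cohort(truth: SyntheticTruth, temperatures=(15.0, 20.0, 25.0),
                    n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Replicate-level stage durations at constant temperatures.

    Each duration is K / (T - D0) * exp(eps) with
    eps ~ Normal(0, sigma_duration^2), drawn from a substream keyed by
    (stage, temperature index) so the first k replicates are identical
    for any n_replicates >= k.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    for T in temperatures:
        if T <= truth.max_D0 + 1.0:
            raise ValidationError(
                f"temperature {T} degC too close to the highest stage "
                f"threshold ({truth.max_D0} degC); need T > D0 + 1")
    rows = []
    for si, stage in enumerate(STAGES):
        if stage not in truth.stage_params:
            continue
        for ti, T in enumerate(temperatures):
            base = truth.expected_duration(stage, T)
            eps = _rng(seed, si, ti).normal(0.0, truth.sigma_duration,
                                            size=n_replicates)
            for ri, e in enumerate(eps):
                rows.append((float(T), f"r{ri + 1}", stage,
                             base * math.exp(e)))
    df = pd.DataFrame(rows, columns=["temperature", "replicate", "stage",
                                     "duration"])
    return validate_duration_table(df, source="generate_cohort")


def generate_length_series(truth: SyntheticTruth, temperature: float,
                           sampling_interval: float = 12.0,
                           seed: int = 0) -> pd.DataFrame:
    """Larval length time series at one temperature, from hatching.

    Samples every ``sampling_interval`` hours from 0 until the logistic
    reaches 99% of L_max, adding Normal(0, sd_length) measurement noise
    (clipped at 0 mm). Strictly S-shaped and monotone in the noiseless
    limit (sd_length = 0).
    """
    if sampling_interval <= 0:
        raise ValidationError("sampling_interval must be > 0")
    if temperature <= truth.D0_larval:
        raise ValidationError(
            f"temperature {temperature} degC at or below the larval "
            f"threshold {truth.D0_larval} degC")
    tau_end = truth.tau0 + math.log(99.0) / truth.rho
    t_end = tau_end / (temperature - truth.D0_larval)
    times = np.arange(0.0, t_end + sampling_interval, sampling_interval)
    L = truth.larval_length(times, temperature)
    noise = _rng(seed, 101, int(round(temperature * 100))).normal(
        0.0, truth.sd_length, size=len(times)) if truth.sd_length > 0 else 0.0
    df = pd.DataFrame({
        "temperature": temperature,
        "time": times,
        "length": np.clip(L + noise, 0.0, None),
        "width": np.nan,
        "weight": np.nan,
        "reference_event": "hatching",
    })
    return validate_measurement_series(df, source="generate_length_series")


def generate_pupal_series(truth: SyntheticTruth, temperature: float,
                          sampling_interval: float = 24.0,
                          seed: int = 0) -> pd.DataFrame:
    """Pupal length/width/weight series at one temperature, from pupariation.

    Weight declines as W0 * (1 - f * (t/t_ecl)^p) with p > 1 (accelerating
    loss toward eclosion); length and width stay at their pupariation
    values up to measurement noise, emulating the rigid puparium.
    """
    if sampling_interval <= 0:
        raise ValidationError("sampling_interval must be > 0")
    t_ecl = truth.pupal_duration(temperature)
    times = np.arange(0.0, t_ecl + 1e-9, sampling_interval)
    if times[-1] < t_ecl:
        times = np.append(times, t_ecl)
    W = truth.pupal_weight(times, temperature)
    rng = _rng(seed, 202, int(round(temperature * 100)))
    n = len(times)
    wn = rng.normal(0.0, truth.sd_weight, n) if truth.sd_weight > 0 else 0.0
    ln = rng.normal(0.0, truth.sd_length, n) if truth.sd_length > 0 else 0.0
    dn = rng.normal(0.0, truth.sd_width, n) if truth.sd_width > 0 else 0.0
    df = pd.DataFrame({
        "temperature": temperature,
        "time": times,
        "length": np.clip(truth.pupal_length + ln, 0.0, None),
        "width": np.clip(truth.pupal_width + dn, 0.0, None),
        "weight": np.clip(W + wn, 0.0, None),
        "reference_event": "pupariation",
    })
    return validate_measurement_series(df, source="generate_pupal_series")


@dataclass(frozen=True)
class ConstantProfile:
    """A constant temperature, degC."""
    temperature: float


@dataclass(frozen=True)
class SinusoidProfile:
    """A diel-style sinusoid: mean +/- amplitude with the given period (h)."""
    mean: float
    amplitude: float
    period: float = 24.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.period <= 0:
            raise ValidationError("need amplitude >= 0 and period > 0")


def generate_temperature_log(profile, duration_h: float,
                             seed: int = 0) -> pd.DataFrame:
    """Hourly temperature log for a constant or sinusoidal profile.

    Emits duration_h + 1 rows at hours 0..duration_h. The sinusoid is
    mean + amplitude * sin(2 pi t / period). A profile dipping below the
    plausible lower bound (-20 degC) is rejected.
    """
    if duration_h <= 0:
        raise ValidationError("duration_h must be > 0")
    times = np.arange(0.0, math.floor(duration_h) + 1.0)
    if isinstance(profile, ConstantProfile):
        temp = np.full_like(times, profile.temperature)
        low = profile.temperature
    elif isinstance(profile, SinusoidProfile):
        temp = profile.mean + profile.amplitude * np.sin(
            2.0 * math.pi * times / profile.period)
        low = profile.mean - profile.amplitude
    else:
        raise ValidationError(
            "profile must be a ConstantProfile or SinusoidProfile")
    if low < TEMPERATURE_RANGE[0]:
        raise ValidationError(
            f"profile reaches {low:g} degC, below the plausible bound "
            f"{TEMPERATURE_RANGE[0]:g} degC")
    df = pd.DataFrame({"time": times, "temperature": temp})
    return validate_temperature_log(df, source="generate_temperature_log")
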
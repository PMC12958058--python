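"""Minimum-PMI estimation by inverting developmental models.

Given the developmental status of insect evidence and the temperature
record at the scene, each estimator solves backward for the oviposition
time and reports age-at-discovery as a minimum postmortem interval (no
pre-colonization interval is modelled):

* :func:`estimate_age_adh` — a milestone was just reached; find the start
  time at which the accumulated degree-hours above the stage's threshold
  D0 equal its thermal constant K. Uncertainty comes from re-solving at
  the (K -/+ SE, D0 +/- SE) parameter corners — a conservative box, since
  the two estimates are strongly coupled in the linearized fits.
* :func:`estimate_age_from_length` — a larva of measured length; invert
  the length-growth curve at the scene temperature and add that
  temperature's hatching time.
* :func:`estimate_age_pupal` — a pupa with a measured weight change since
  pupariation; invert the (reliable) pupal weight model and add the
  cumulative pre-pupal time.
* :func:`combine_estimates` — fuse several estimates by interval
  intersection (midpoint as the point estimate), falling back to the
  union with a conflict warning when they disagree.

All estimators refuse, or warn loudly, outside the validated 15-25 degC
experimental range: the underlying models come from constant-temperature
rearing and extrapolation is not silently trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import validate_temperature_log
from .exceptions import CoverageError, UnreliableModelError, ValidationError
from .growth import IsomorphenTable, LarvalGrowthResults
from .pupal import RELIABILITY_THRESHOLD, PupalIndicatorResults
from .thermal import ThermalSummationResults

__all__ = [
    "PMIEstimate",
    "VALIDATED_RANGE",
    "estimate_age_adh",
    "estimate_age_from_length",
    "estimate_age_pupal",
    "combine_estimates",
    "solve_start_time",
    "solve_completion_time",
]

#: Temperature range covered by the rearing experiments behind the models.
VALIDATED_RANGE: tuple[float, float] = (15.0, 25.0)

#: Below this linearized-fit R2 an ADH estimate carries a mandatory warning.
POOR_FIT_R2 = 0.5


@dataclass(frozen=True)
class PMIEstimate:
    """A minimum-PMI estimate: point and interval in hours, with provenance."""

    point: float
    interval: tuple[float, float]
    method: str          # adh_milestone | isomegalen_length | pupal_weight | combined
    inputs_digest: str
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.point <= hi):
            raise ValidationError(
                f"inconsistent estimate: interval [{lo}, {hi}] does not "
                f"contain the point {self.point}")

    def summary(self) -> str:
        lines = [
            f"PMI estimate ({self.method})",
            f"  point    = {self.point:.1f} h",
            f"  interval = [{self.interval[0]:.1f}, {self.interval[1]:.1f}] h",
            f"  evidence : {self.inputs_digest}",
        ]
        for w in self.warnings:
            lines.append(f"  warning  : {w}")
        return "\n".join(lines)


def _range_warnings(temperature: float, override: bool) -> list[str]:
    lo, hi = VALIDATED_RANGE
    if lo <= temperature <= hi:
        return []
    msg = (f"temperature {temperature:g} degC outside the validated "
           f"{lo:g}-{hi:g} degC range; models extrapolated")
    if not override:
        raise ValidationError(msg + " (pass allow_extrapolation=True to override)")
    return [msg]


def solve_start_time(log: pd.DataFrame, d0: float, k: float,
                     discovery_time: float) -> float:
    """Start time t0 with accumulated degree-hours(t0 -> discovery) = k.

    Scans backward over the log's sample points, accumulating the
    trapezoidal degree-hour integral of max(T - d0, 0), and linearly
    interpolates the crossing inside the bracketing sampling interval.
    Raises CoverageError (stating the shortfall) if the record is
    exhausted before k degree-hours accumulate.
    """
    log = validate_temperature_log(log)
    t = log["time"].to_numpy()
    if discovery_time > t[-1] + 1e-9 or discovery_time < t[0] - 1e-9:
        raise CoverageError(
            f"discovery time {discovery_time} h outside the record span "
            f"[{t[0]}, {t[-1]}] h")
    if k <= 0:
        return float(discovery_time)
    temp = log["temperature"].to_numpy()
    before = t[t < discovery_time]
    grid = np.concatenate((before, [discovery_time]))
    excess = np.clip(np.interp(grid, t, temp) - d0, 0.0, None)
    # per-segment trapezoid areas, then cumulative sum backward in time
    seg = 0.5 * (excess[1:] + excess[:-1]) * np.diff(grid)
    cum_back = np.concatenate(([0.0], np.cumsum(seg[::-1])))  # from discovery
    knots = grid[::-1]                                        # descending times
    if cum_back[-1] < k - 1e-9:
        raise CoverageError(
            f"temperature record accumulates only {cum_back[-1]:.1f} of the "
            f"required {k:.1f} degC*h before {discovery_time} h "
            f"(shortfall {k - cum_back[-1]:.1f} degC*h)")
    i = int(np.searchsorted(cum_back, k))
    # crossing between knots[i-1] and knots[i]; linear in cumulative ADH
    c0, c1 = cum_back[i - 1], cum_back[i]
    frac = 0.0 if c1 == c0 else (k - c0) / (c1 - c0)
    return float(knots[i - 1] + frac * (knots[i] - knots[i - 1]))


def solve_completion_time(log: pd.DataFrame, d0: float, k: float,
                          t_start: float) -> float:
    """Forward counterpart of :func:`solve_start_time`: the time at which
    k degree-hours above ``d0`` have accumulated since ``t_start``.

    Used to simulate development under a fluctuating record (each stage
    completes when its own thermal constant is reached). Raises
    CoverageError when the record ends first.
    """
    log = validate_temperature_log(log)
    t = log["time"].to_numpy()
    if t_start < t[0] - 1e-9 or t_start > t[-1] + 1e-9:
        raise CoverageError(
            f"start time {t_start} h outside the record span [{t[0]}, {t[-1]}] h")
    if k <= 0:
        return float(t_start)
    temp = log["temperature"].to_numpy()
    after = t[t > t_start]
    grid = np.concatenate(([t_start], after))
    excess = np.clip(np.interp(grid, t, temp) - d0, 0.0, None)
    seg = 0.5 * (excess[1:] + excess[:-1]) * np.diff(grid)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    if cum[-1] < k - 1e-9:
        raise CoverageError(
            f"temperature record accumulates only {cum[-1]:.1f} of the "
            f"required {k:.1f} degC*h after {t_start} h "
            f"(shortfall {k - cum[-1]:.1f} degC*h)")
    i = int(np.searchsorted(cum, k))
    c0, c1 = cum[i - 1], cum[i]
    frac = 0.0 if c1 == c0 else (k - c0) / (c1 - c0)
    return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))


def estimate_age_adh(params: ThermalSummationResults, log: pd.DataFrame,
                     discovery_time: float, *, stage: str | None = None,
                     allow_extrapolation: bool = False) -> PMIEstimate:
    """Age at discovery for a just-completed milestone, from degree-hours.

    ``stage``, when given, must match the parameter set's stage label.
    The interval re-solves at the (K - SE, D0 + SE) and (K + SE, D0 - SE)
    parameter corners; a corner the record cannot cover is clamped to the
    record start with a warning.
    """
    if stage is not None and stage != params.stage:
        raise ValidationError(
            f"milestone {stage!r} does not match fitted stage {params.stage!r}")
    log = validate_temperature_log(log)
    mean_temp = float(log["temperature"].mean())
    warnings_ = _range_warnings(mean_temp, allow_extrapolation)
    if params.r_squared < POOR_FIT_R2:
        warnings_.append(
            f"thermal fit for {params.stage!r} has R2 = "
            f"{params.r_squared:.4f} < {POOR_FIT_R2}: estimate is weakly "
            f"supported")
    t0 = solve_start_time(log, params.D0, params.K, discovery_time)
    point = discovery_time - t0
    bounds = []
    for kk, dd in ((params.K - params.se_K, params.D0 + params.se_D0),
                   (params.K + params.se_K, params.D0 - params.se_D0)):
        try:
            tb = solve_start_time(log, dd, max(kk, 0.0), discovery_time)
            bounds.append(discovery_time - tb)
        except CoverageError:
            bounds.append(discovery_time - float(log["time"].iloc[0]))
            warnings_.append(
                "record too short for the conservative parameter corner; "
                "upper age bound clamped to the record span")
    lo = min(bounds + [point])
    hi = max(bounds + [point])
    return PMIEstimate(
        point=point, interval=(lo, hi), method="adh_milestone",
        inputs_digest=(f"stage={params.stage}, K={params.K:.2f} degC*h, "
                       f"D0={params.D0:.2f} degC, discovery={discovery_time:g} h"),
        warnings=tuple(warnings_))


def estimate_age_from_length(length: float, temperature: float,
                             models: dict[float, LarvalGrowthResults],
                             isomorphen: IsomorphenTable, *,
                             allow_extrapolation: bool = False) -> PMIEstimate:
    """Age since oviposition for a larva of measured length.

    Inverts the growth curve fitted at the given temperature (age since
    hatching) and adds the hatching duration at that temperature from the
    isomorphen table. The interval maps the growth fit's residual SD
    through the local slope of the curve (delta method), so it widens
    toward the plateau where length stops discriminating age.
    """
    warnings_ = _range_warnings(temperature, allow_extrapolation)
    if temperature not in models:
        raise ValidationError(
            f"no fitted growth model at {temperature:g} degC "
            f"(available: {sorted(models)})")
    model = models[temperature]
    t_hatch_rel = model.invert(length)
    hatch = isomorphen.milestone_time("hatch", temperature)
    point = t_hatch_rel + hatch
    slope = abs(model.slope(t_hatch_rel))
    if slope < 1e-9:
        half = model.feeding_phase_end  # slope ~ 0: age unconstrained
        warnings_.append("length on the plateau: interval spans the full "
                         "feeding phase")
    else:
        half = model.resid_sd / slope
    lo = max(hatch, point - half)
    hi = point + half
    return PMIEstimate(
        point=point, interval=(lo, hi), method="isomegalen_length",
        inputs_digest=(f"length={length:g} mm at {temperature:g} degC; "
                       f"hatch offset {hatch:g} h"),
        warnings=tuple(warnings_))


def estimate_age_pupal(delta_weight: float, temperature: float,
                       pupal_models: dict[float, PupalIndicatorResults],
                       isomorphen: IsomorphenTable, *,
                       threshold: float = RELIABILITY_THRESHOLD,
                       allow_extrapolation: bool = False) -> PMIEstimate:
    """Age since oviposition for a pupa with a measured weight change.

    Refuses (UnreliableModelError) when the weight model at this
    temperature falls below the reliability threshold — at low rearing
    temperatures the weight-loss pattern is disrupted and must not be
    inverted for casework.
    """
    warnings_ = _range_warnings(temperature, allow_extrapolation)
    if temperature not in pupal_models:
        raise ValidationError(
            f"no pupal weight model at {temperature:g} degC "
            f"(available: {sorted(pupal_models)})")
    model = pupal_models[temperature]
    if model.indicator != "weight":
        raise ValidationError(f"expected a weight model, got {model.indicator!r}")
    if not model.reliable(threshold):
        raise UnreliableModelError(
            f"pupal weight model at {temperature:g} degC has R2 = "
            f"{model.r_squared:.4f} < {threshold:g}: low temperature disrupts "
            f"the weight-loss pattern; refusing the pupal-weight age estimate")
    t_intra = model.invert(delta_weight, threshold=threshold)
    pre_pupal = isomorphen.milestone_time("end_wandering", temperature)
    point = pre_pupal + t_intra
    slope = abs(model.slope(t_intra))
    if slope < 1e-12:
        half = model.time_range[1]
        warnings_.append("weight change locally flat: interval spans the "
                         "fitted pupal range")
    else:
        half = model.resid_sd / slope
    lo = max(pre_pupal, point - half)
    hi = point + half
    return PMIEstimate(
        point=point, interval=(lo, hi), method="pupal_weight",
        inputs_digest=(f"delta_weight={delta_weight:g} g at {temperature:g} "
                       f"degC; pre-pupal offset {pre_pupal:g} h"),
        warnings=tuple(warnings_))


def combine_estimates(estimates: list[PMIEstimate]) -> PMIEstimate:
    """Fuse estimates by interval intersection.

    Non-empty intersection: point = midpoint of the intersection.
    Disjoint intervals: the union is returned with a conflict warning —
    disagreement between lines of evidence is surfaced, never averaged
    away.
    """
    if not estimates:
        raise ValidationError("need at least one estimate")
    if len(estimates) == 1:
        return estimates[0]
    warnings_ = [w for e in estimates for w in e.warnings]
    lo = max(e.interval[0] for e in estimates)
    hi = min(e.interval[1] for e in estimates)
    if lo <= hi:
        point = 0.5 * (lo + hi)
        interval = (lo, hi)
    else:
        interval = (min(e.interval[0] for e in estimates),
                    max(e.interval[1] for e in estimates))
        point = 0.5 * (interval[0] + interval[1])
        warnings_.append(
            "estimates conflict (disjoint intervals); union reported")
    digest = " + ".join(e.method for e in estimates)
    return PMIEstimate(point=point, interval=interval, method="combined",
                       inputs_digest=digest, warnings=tuple(warnings_))
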
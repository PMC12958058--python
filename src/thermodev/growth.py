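"""Larval growth curves, their inversion, and the two diagnostic diagrams.

Larval body length over time after hatching follows an S-shaped
trajectory: rapid feeding-phase growth, then a plateau (and eventual
shrinkage toward pupariation). Per rearing temperature the package fits a
cubic polynomial with intercept,

    L(t) = b0 + b1 t + b2 t^2 + b3 t^3,

the standard parametric form for forensic length-age reference curves.
:class:`LarvalGrowthResults.invert` solves L(t) = length on the rising
(feeding) segment only, which is the well-posed direction used for aging
a larva of measured length.

Two derived reference charts:

* **isomegalen diagram** — for a grid of lengths (default 4..17 mm), the
  time to reach each length at each fitted temperature; contours of equal
  length over the (time, temperature) plane.
* **isomorphen diagram** — cumulative mean times to each developmental
  milestone (hatch, molts, pupariation, eclosion) per temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .datatypes import MILESTONES, STAGES, GroupSummary, validate_duration_table
from .exceptions import FitError, ValidationError

__all__ = [
    "LarvalGrowthModel",
    "LarvalGrowthResults",
    "IsomegalenGrid",
    "IsomorphenTable",
    "fit_cubic_growth",
    "build_isomegalen",
    "build_isomorphen",
]


@dataclass(frozen=True)
class LarvalGrowthResults:
    """A fitted cubic length-vs-time model at one temperature.

    ``feeding_phase_end`` is the time of maximum fitted length inside
    ``time_range``; evaluation outside ``time_range`` is refused rather
    than extrapolated.
    """

    temperature: float
    params: tuple[float, float, float, float]          # b0..b3
    bse: tuple[float, float, float, float]
    r_squared: float
    time_range: tuple[float, float]                    # hours after hatching
    feeding_phase_end: float
    resid_sd: float = 0.0
    reference_event: str = "hatching"

    def predict(self, t) -> np.ndarray | float:
        """Fitted length (mm) at time(s) ``t`` within the fitted range."""
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.time_range
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise ValidationError(
                f"time outside the fitted range [{lo:g}, {hi:g}] h")
        b0, b1, b2, b3 = self.params
        out = b0 + b1 * t_arr + b2 * t_arr ** 2 + b3 * t_arr ** 3
        return float(out) if np.isscalar(t) else out

    def slope(self, t: float) -> float:
        _, b1, b2, b3 = self.params
        return b1 + 2 * b2 * t + 3 * b3 * t ** 2

    def length_range(self) -> tuple[float, float]:
        """Attainable lengths on the rising segment [L(0), L(peak)]."""
        return (self.predict(self.time_range[0]),
                self.predict(self.feeding_phase_end))

    def invert(self, length: float, tol: float = 1e-6) -> float:
        """Time (h after hatching) at which the rising segment reaches
        ``length`` mm, by bracketed root finding to ``tol`` hours.

        Restricted to [start, feeding_phase_end] so plateau/shrinkage
        times are never matched. If the fitted segment is locally
        non-monotone the smallest root is returned with a warning.
        """
        lo = self.time_range[0]
        hi = self.feeding_phase_end
        f = lambda t: self.predict(t) - length
        l_lo, l_hi = self.length_range()
        if not (min(l_lo, l_hi) - 1e-12 <= length <= max(l_lo, l_hi) + 1e-12):
            raise ValidationError(
                f"length {length} mm outside the attainable range "
                f"[{l_lo:.3f}, {l_hi:.3f}] mm at {self.temperature:g} degC")
        grid = np.linspace(lo, hi, 512)
        vals = np.array([f(t) for t in grid])
        signs = np.sign(vals)
        crossings = np.nonzero(np.diff(signs) != 0)[0]
        exact = np.nonzero(vals == 0)[0]
        roots = [float(grid[i]) for i in exact]
        for i in crossings:
            roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=tol)))
        if not roots:  # numerically flat at the boundary
            roots = [lo if abs(f(lo)) < abs(f(hi)) else hi]
        roots = sorted(set(round(r, 9) for r in roots))
        if len(roots) > 1 and roots[-1] - roots[0] > 10 * tol:
            warnings.warn(
                f"multiple roots for length {length} mm at "
                f"{self.temperature:g} degC; returning the smallest",
                stacklevel=2)
        return roots[0]

    def summary(self) -> str:
        b = self.params
        se = self.bse
        return (
            f"Cubic larval growth fit at {self.temperature:g} degC\n"
            f"  L(t) = ({b[0]:.5f} +/- {se[0]:.5f}) + ({b[1]:.5f} +/- {se[1]:.5f}) t\n"
            f"         + ({b[2]:.5e} +/- {se[2]:.5e}) t^2 "
            f"+ ({b[3]:.5e} +/- {se[3]:.5e}) t^3\n"
            f"  R2 = {self.r_squared:.4f}; valid t in [{self.time_range[0]:g}, "
            f"{self.time_range[1]:g}] h; peak at {self.feeding_phase_end:.1f} h"
        )

    def to_dict(self) -> dict:
        return {
            "temperature": {"value": self.temperature, "unit": "degC"},
            "coefficients": {"value": list(self.params),
                             "unit": ["mm", "mm/h", "mm/h^2", "mm/h^3"]},
            "coefficient_se": list(self.bse),
            "r_squared": self.r_squared,
            "time_range": {"value": list(self.time_range), "unit": "h"},
            "feeding_phase_end": {"value": self.feeding_phase_end, "unit": "h"},
            "resid_sd": {"value": self.resid_sd, "unit": "mm"},
            "reference_event": self.reference_event,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LarvalGrowthResults":
        return cls(temperature=d["temperature"]["value"],
                   params=tuple(d["coefficients"]["value"]),
                   bse=tuple(d["coefficient_se"]),
                   r_squared=d["r_squared"],
                   time_range=tuple(d["time_range"]["value"]),
                   feeding_phase_end=d["feeding_phase_end"]["value"],
                   resid_sd=d["resid_sd"]["value"],
                   reference_event=d.get("reference_event", "hatching"))


def _cubic_argmax(params, lo: float, hi: float) -> float:
    """Time of maximum of a cubic on [lo, hi]: critical points + endpoints."""
    b0, b1, b2, b3 = params
    candidates = [lo, hi]
    # derivative 3*b3 t^2 + 2*b2 t + b1 = 0
    roots = np.roots([3 * b3, 2 * b2, b1]) if (b3 or b2) else (
        np.array([]) if b1 == 0 else np.array([]))
    for r in np.atleast_1d(roots):
        if np.isreal(r) and lo <= r.real <= hi:
            candidates.append(float(r.real))
    vals = [b0 + b1 * t + b2 * t ** 2 + b3 * t ** 3 for t in candidates]
    return float(candidates[int(np.argmax(vals))])


class LarvalGrowthModel:
    """Cubic length-vs-time model for one rearing temperature."""

    def __init__(self, times, lengths, temperature: float):
        t = np.asarray(times, dtype=float)
        L = np.asarray(lengths, dtype=float)
        keep = np.isfinite(t) & np.isfinite(L)
        self.times = t[keep]
        self.lengths = L[keep]
        self.temperature = float(temperature)

    @classmethod
    def from_series(cls, series: pd.DataFrame, temperature: float) -> "LarvalGrowthModel":
        sub = series[(series["temperature"] == temperature)
                     & (series["reference_event"] == "hatching")]
        return cls(sub["time"].to_numpy(), sub["length"].to_numpy(), temperature)

    def fit(self) -> LarvalGrowthResults:
        t, L = self.times, self.lengths
        if len(np.unique(t)) < 6:
            raise FitError(
                f"need >= 6 distinct time points, have {len(np.unique(t))}")
        X = np.column_stack([np.ones_like(t), t, t ** 2, t ** 3])
        if np.linalg.matrix_rank(X) < 4:
            raise FitError("rank-deficient design for the cubic fit")
        fit = sm.OLS(L, X).fit()
        params = tuple(float(p) for p in fit.params)
        lo, hi = float(t.min()), float(t.max())
        peak = _cubic_argmax(params, lo, hi)
        resid_sd = float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0
        return LarvalGrowthResults(
            temperature=self.temperature, params=params,
            bse=tuple(float(s) for s in fit.bse),
            r_squared=float(fit.rsquared), time_range=(lo, hi),
            feeding_phase_end=peak, resid_sd=resid_sd)


def fit_cubic_growth(series: pd.DataFrame, temperature: float) -> LarvalGrowthResults:
    """Fit the cubic growth model from a measurement series."""
    return LarvalGrowthModel.from_series(series, temperature).fit()


@dataclass(frozen=True)
class IsomegalenGrid:
    """Times (h after hatching) to reach each length at each temperature.

    ``times[i, j]`` is the age at which length ``lengths[i]`` is reached
    at ``temperatures[j]``; NaN marks lengths unattainable at that
    temperature.
    """

    lengths: tuple[float, ...]
    temperatures: tuple[float, ...]
    times: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.times, index=list(self.lengths),
                            columns=list(self.temperatures)).rename_axis(
            index="length_mm", columns="temperature_C")

    def interpolate_temperature(self, length: float, temperature: float) -> float:
        """Linear-in-time interpolation across fitted isotherms at a fixed
        length — presentation only, flagged separately from fitted values."""
        temps = np.asarray(self.temperatures)
        if not temps.min() <= temperature <= temps.max():
            raise ValidationError(
                f"temperature {temperature} degC outside the fitted span")
        i = int(np.argmin(np.abs(np.asarray(self.lengths) - length)))
        row = self.times[i]
        if np.any(np.isnan(row)):
            raise ValidationError(
                f"length {self.lengths[i]} mm undefined at some temperatures")
        order = np.argsort(temps)
        return float(np.interp(temperature, temps[order], row[order]))

    def to_dict(self) -> dict:
        return {
            "lengths": {"value": list(self.lengths), "unit": "mm"},
            "temperatures": {"value": list(self.temperatures), "unit": "degC"},
            "times": {"value": [[None if np.isnan(v) else float(v) for v in row]
                                for row in self.times], "unit": "h"},
            "provenance": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsomegalenGrid":
        times = np.array([[np.nan if v is None else v for v in row]
                          for row in d["times"]["value"]], dtype=float)
        return cls(lengths=tuple(d["lengths"]["value"]),
                   temperatures=tuple(d["temperatures"]["value"]),
                   times=times, provenance=tuple(d.get("provenance", [])))


DEFAULT_LENGTH_GRID: tuple[float, ...] = tuple(float(x) for x in range(4, 18))


def build_isomegalen(models: list[LarvalGrowthResults],
                     lengths=DEFAULT_LENGTH_GRID) -> IsomegalenGrid:
    """Invert each growth model over a grid of target lengths.

    Cells where a length is outside the attainable range of the fitted
    rising segment are NaN, never silently extrapolated.
    """
    if len(models) < 2:
        raise FitError("need fitted models at >= 2 temperatures")
    models = sorted(models, key=lambda m: m.temperature)
    temps = tuple(m.temperature for m in models)
    grid = np.full((len(lengths), len(models)), np.nan)
    for j, m in enumerate(models):
        lo, hi = m.length_range()
        for i, L in enumerate(lengths):
            if min(lo, hi) <= L <= max(lo, hi):
                grid[i, j] = m.invert(L)
    prov = tuple(f"cubic@{m.temperature:g}C(R2={m.r_squared:.4f})" for m in models)
    return IsomegalenGrid(lengths=tuple(float(x) for x in lengths),
                          temperatures=temps, times=grid, provenance=prov)


@dataclass(frozen=True)
class IsomorphenTable:
    """Cumulative mean time (h since oviposition) to each developmental
    milestone, per temperature."""

    temperatures: tuple[float, ...]
    milestones: tuple[str, ...]
    times: np.ndarray               # (n_milestones, n_temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.times, index=list(self.milestones),
                            columns=list(self.temperatures)).rename_axis(
            index="milestone", columns="temperature_C")

    def milestone_time(self, milestone: str, temperature: float) -> float:
        try:
            i = self.milestones.index(milestone)
        except ValueError:
            raise ValidationError(f"unknown milestone {milestone!r}") from None
        try:
            j = self.temperatures.index(temperature)
        except ValueError:
            raise ValidationError(
                f"no milestone data at {temperature} degC "
                f"(available: {list(self.temperatures)})") from None
        return float(self.times[i, j])

    def total_duration(self, temperature: float) -> float:
        return self.milestone_time(self.milestones[-1], temperature)

    def to_dict(self) -> dict:
        return {
            "temperatures": {"value": list(self.temperatures), "unit": "degC"},
            "milestones": list(self.milestones),
            "times": {"value": [[float(v) for v in row] for row in self.times],
                      "unit": "h"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsomorphenTable":
        return cls(temperatures=tuple(d["temperatures"]["value"]),
                   milestones=tuple(d["milestones"]),
                   times=np.array(d["times"]["value"], dtype=float))


def build_isomorphen(durations) -> IsomorphenTable:
    """Cumulative milestone times from stage durations.

    ``durations`` is either a replicate-level StageDurationTable (means
    are taken per stage and temperature) or a mapping
    ``{temperature: {stage: GroupSummary or mean hours}}``. All six stages
    must be present at every temperature; milestones are the cumulative
    sums in chronological stage order.
    """
    per_temp: dict[float, dict[str, float]] = {}
    if isinstance(durations, pd.DataFrame):
        table = validate_duration_table(durations)
        means = table.groupby(["temperature", "stage"])["duration"].mean()
        for (temp, stage), m in means.items():
            per_temp.setdefault(float(temp), {})[stage] = float(m)
    else:
        for temp, stages in durations.items():
            per_temp[float(temp)] = {
                s: (v.mean if isinstance(v, GroupSummary) else float(v))
                for s, v in stages.items()}
    temps = tuple(sorted(per_temp))
    if not temps:
        raise ValidationError("no duration data supplied")
    times = np.zeros((len(MILESTONES), len(temps)))
    for j, temp in enumerate(temps):
        stages = per_temp[temp]
        missing = [s for s in STAGES if s not in stages]
        if missing:
            raise ValidationError(
                f"missing stage(s) {missing} at {temp:g} degC")
        times[:, j] = np.cumsum([stages[s] for s in STAGES])
    return IsomorphenTable(temperatures=temps, milestones=MILESTONES, times=times)
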
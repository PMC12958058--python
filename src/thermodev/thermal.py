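"""Degree-hour accumulation and thermal summation (degree-day) fits.

The linear degree-day model says a stage completes once its accumulated
degree-hours above a lower developmental threshold D0 reach a thermal
constant K:

    D * (T - D0) = K          (D duration in h, T rearing temperature)

Two classical linearizations estimate (K, D0) from (duration, temperature)
pairs; both are exact on noiseless hyperbolic data:

``ikemoto``
    regress y = D*T on x = D; the slope is D0 and the intercept K
    (D*T = K + D0*D). This is the reduced-axis form recommended by
    Ikemoto & Takai for degree-day estimation.
``rate``
    regress developmental rate 1/D on T; 1/D = -D0/K + T/K, so
    K = 1/slope and D0 = -intercept/slope, with standard errors by
    first-order (delta-method) propagation from the OLS covariance.

:func:`accumulated_degree_hours` integrates max(T(t) - D0, 0) over a
temperature record by the trapezoidal rule — the casework-side quantity
that the PMI engine inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import validate_temperature_log
from .exceptions import CoverageError, FitError

__all__ = [
    "ThermalSummationModel",
    "ThermalSummationResults",
    "accumulated_degree_hours",
    "fit_thermal_ikemoto",
    "fit_thermal_rate",
    "exclude_nonlinear_points",
]

_METHODS = ("ikemoto", "rate")


def accumulated_degree_hours(log: pd.DataFrame, d0: float,
                             t_start: float, t_end: float) -> float:
    """Accumulated degree-hours above ``d0`` between two times.

    Integrates max(T(t) - d0, 0) by the trapezoidal rule on the log's
    sample points, with linear interpolation of temperature at the
    interval endpoints. Sub-threshold excess is clamped to zero before
    integration (the standard degree-day convention), making the result
    non-negative and additive over abutting intervals.
    """
    log = validate_temperature_log(log)
    t = log["time"].to_numpy()
    if t_start >= t_end:
        raise CoverageError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise CoverageError(
            f"interval [{t_start}, {t_end}] h outside the record span "
            f"[{t[0]}, {t[-1]}] h")
    temp = log["temperature"].to_numpy()
    interior = t[(t > t_start) & (t < t_end)]
    grid = np.concatenate(([t_start], interior, [t_end]))
    excess = np.clip(np.interp(grid, t, temp) - d0, 0.0, None)
    return float(np.trapezoid(excess, grid))


@dataclass(frozen=True)
class ThermalSummationResults:
    """Fitted thermal constant and lower developmental threshold.

    ``r_squared`` is that of the linearized regression actually fitted
    (not back-transformed to the hyperbola). ``excluded_points`` is the
    audit list of (duration, temperature, reason) dropped before fitting.
    """

    stage: str
    K: float                       # degree-hours
    D0: float                      # degC
    se_K: float
    se_D0: float
    r_squared: float
    method: str
    n_points: int
    excluded_points: tuple[tuple[float, float, str], ...] = field(default_factory=tuple)

    def predicted_duration(self, temperature: float) -> float:
        """Model duration K / (T - D0) at a constant temperature."""
        if temperature <= self.D0:
            raise CoverageError(
                f"temperature {temperature} degC at or below the threshold "
                f"D0 = {self.D0:.3f} degC: development does not complete")
        return self.K / (temperature - self.D0)

    def summary(self) -> str:
        lines = [
            f"Thermal summation fit ({self.method}), stage = {self.stage}",
            f"  K  = {self.K:.5f} +/- {self.se_K:.5f} degC*h",
            f"  D0 = {self.D0:.5f} +/- {self.se_D0:.5f} degC",
            f"  R2 = {self.r_squared:.4f} on {self.n_points} points",
        ]
        for d, t, reason in self.excluded_points:
            lines.append(f"  excluded (D = {d:g} h, T = {t:g} degC): {reason}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "K": {"value": self.K, "unit": "degC*h"},
            "D0": {"value": self.D0, "unit": "degC"},
            "se_K": {"value": self.se_K, "unit": "degC*h"},
            "se_D0": {"value": self.se_D0, "unit": "degC"},
            "r_squared": self.r_squared,
            "method": self.method,
            "n_points": self.n_points,
            "excluded_points": [list(p) for p in self.excluded_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalSummationResults":
        return cls(stage=d["stage"], K=d["K"]["value"], D0=d["D0"]["value"],
                   se_K=d["se_K"]["value"], se_D0=d["se_D0"]["value"],
                   r_squared=d["r_squared"], method=d["method"],
                   n_points=d["n_points"],
                   excluded_points=tuple((p[0], p[1], p[2])
                                         for p in d.get("excluded_points", [])))


class ThermalSummationModel:
    """Degree-day model of one developmental stage.

    Parameters
    ----------
    durations, temperatures:
        replicate- or mean-level (D, T) observations, hours and degC.
    stage:
        label carried into the results.
    """

    def __init__(self, durations, temperatures, stage: str = "stage"):
        D = np.asarray(durations, dtype=float)
        T = np.asarray(temperatures, dtype=float)
        if D.shape != T.shape or D.ndim != 1:
            raise FitError("durations and temperatures must be 1-d and equal length")
        if np.any(D <= 0):
            raise FitError("durations must be > 0 h")
        self.durations = D
        self.temperatures = T
        self.stage = stage

    @classmethod
    def from_table(cls, table: pd.DataFrame, stage: str) -> "ThermalSummationModel":
        sub = table[table["stage"] == stage]
        if not len(sub):
            raise FitError(f"no rows for stage {stage!r}")
        return cls(sub["duration"].to_numpy(), sub["temperature"].to_numpy(),
                   stage=stage)

    def fit(self, method: str = "ikemoto",
            exclude_threshold: float | None = None,
            manual_mask=None) -> ThermalSummationResults:
        """Fit the thermal summation parameters.

        ``exclude_threshold`` enables iterative exclusion of points with
        externally studentized residuals beyond the threshold (see
        :func:`exclude_nonlinear_points`); ``manual_mask`` is a list of
        point indices always excluded (reason "manual").
        """
        if method not in _METHODS:
            raise FitError(f"method must be one of {_METHODS}")
        points = list(zip(self.durations, self.temperatures))
        excluded: list[tuple[float, float, str]] = []
        if exclude_threshold is not None or manual_mask:
            points, excluded = exclude_nonlinear_points(
                points, max_abs_studentized_residual=exclude_threshold,
                manual_mask=manual_mask, method=method)
        D = np.array([p[0] for p in points])
        T = np.array([p[1] for p in points])
        if len(D) < 3:
            raise FitError(f"need >= 3 points after exclusion, have {len(D)}")
        if method == "ikemoto":
            res = _fit_ikemoto(D, T)
        else:
            res = _fit_rate(D, T)
        K, D0, se_K, se_D0, r2 = res
        return ThermalSummationResults(
            stage=self.stage, K=K, D0=D0, se_K=se_K, se_D0=se_D0,
            r_squared=r2, method=method, n_points=len(D),
            excluded_points=tuple(excluded))


def _ols(y: np.ndarray, x: np.ndarray):
    if np.ptp(x) == 0:
        raise FitError("singular design: all x values identical")
    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()


def _fit_ikemoto(D, T):
    fit = _ols(D * T, D)
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    return (float(intercept), float(slope), float(se_int), float(se_slope),
            float(fit.rsquared))


def _fit_rate(D, T):
    fit = _ols(1.0 / D, T)
    a, b = fit.params           # intercept, slope
    if b <= 0:
        raise FitError(
            f"rate regression slope {b:.3g} <= 0: no positive thermal constant")
    K = 1.0 / b
    D0 = -a / b
    cov = fit.cov_params()
    cov = np.asarray(cov)
    var_a, var_b, cov_ab = cov[0, 0], cov[1, 1], cov[0, 1]
    se_K = math.sqrt(var_b) / b ** 2
    # D0 = -a/b: grad (-1/b, a/b^2)
    var_D0 = (var_a / b ** 2 + a ** 2 * var_b / b ** 4
              - 2.0 * a * cov_ab / b ** 3)
    se_D0 = math.sqrt(max(var_D0, 0.0))
    return float(K), float(D0), float(se_K), float(se_D0), float(fit.rsquared)


def fit_thermal_ikemoto(points, stage: str = "stage") -> ThermalSummationResults:
    """Fit D*T = K + D0*D by OLS on (duration, temperature) pairs."""
    D = [p[0] for p in points]
    T = [p[1] for p in points]
    return ThermalSummationModel(D, T, stage=stage).fit(method="ikemoto")


def fit_thermal_rate(points, stage: str = "stage") -> ThermalSummationResults:
    """Fit 1/D = -D0/K + T/K by OLS on (duration, temperature) pairs."""
    D = [p[0] for p in points]
    T = [p[1] for p in points]
    return ThermalSummationModel(D, T, stage=stage).fit(method="rate")


def exclude_nonlinear_points(points, max_abs_studentized_residual: float | None = 3.0,
                             manual_mask=None, method: str = "ikemoto"):
    """Iteratively drop the worst outlier from a thermal summation fit.

    Refits after each removal, dropping the single point whose externally
    studentized residual has the largest magnitude above the threshold,
    until none exceed it or only 3 points remain (a fit on fewer is never
    attempted silently). ``manual_mask`` indices are always excluded with
    reason "manual". Returns (kept_points, excluded) where excluded items
    are (duration, temperature, reason).
    """
    points = [(float(d), float(t)) for d, t in points]
    excluded: list[tuple[float, float, str]] = []
    mask = sorted(set(manual_mask or []), reverse=True)
    for idx in mask:
        if not 0 <= idx < len(points):
            raise FitError(f"manual_mask index {idx} out of range")
    kept = [p for i, p in enumerate(points) if i not in set(mask)]
    for idx in sorted(set(mask)):
        d, t = points[idx]
        excluded.append((d, t, "manual"))
    if max_abs_studentized_residual is None or math.isinf(max_abs_studentized_residual):
        return kept, excluded
    if len(points) < 4:
        raise FitError("automatic exclusion needs >= 4 points")
    while len(kept) > 3:
        D = np.array([p[0] for p in kept])
        T = np.array([p[1] for p in kept])
        if method == "ikemoto":
            y, x = D * T, D
        else:
            y, x = 1.0 / D, T
        fit = _ols(y, x)
        # residual scale at numerical-noise level: the data are collinear
        if np.sqrt(fit.mse_resid) <= 1e-9 * np.mean(np.abs(y)):
            break
        resid = fit.get_influence().resid_studentized_external
        if not np.any(np.isfinite(resid)):
            break
        worst = int(np.nanargmax(np.abs(resid)))
        r = abs(resid[worst])
        if not np.isfinite(r) or r <= max_abs_studentized_residual:
            break
        d, t = kept.pop(worst)
        excluded.append((d, t,
                         f"|studentized residual| = {r:.2f} > "
                         f"{max_abs_studentized_residual:g}"))
    return kept, excluded
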
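"""Pupal growth indicators: cubic change-from-pupariation models.

Once the puparium forms, external dimensions barely change — the case
constrains length and width — while weight declines steadily as water is
lost and fat reserves are metabolised, accelerating toward eclosion.
Pupal age models therefore fit the *change* of each indicator from its
value at pupariation, as a cubic through the origin:

    dY(t) = b1 t + b2 t^2 + b3 t^3,   t hours after pupariation,

for Y in {length (mm), width (mm), weight (g)}. R-squared is computed
about the mean of the transformed response, so a useless fit can score
near zero or negative; fits below a reliability threshold (default 0.5)
are refused for age inversion — at low rearing temperatures pupal weight
loses its regular pattern and must not be used to age a pupa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .exceptions import FitError, UnreliableModelError, ValidationError

__all__ = [
    "PupalIndicatorModel",
    "PupalIndicatorResults",
    "IndicatorRanking",
    "fit_pupal_indicator",
    "rank_indicators",
    "invert_pupal_weight",
    "RELIABILITY_THRESHOLD",
]

INDICATORS = ("length", "width", "weight")

#: Minimum R2 for a pupal indicator model to be invertible for aging.
RELIABILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class PupalIndicatorResults:
    """A fitted through-origin cubic for one indicator at one temperature.

    The response frame is change-from-pupariation (delta mm or delta g);
    ``baseline`` records the indicator's value at pupariation so absolute
    observations can be converted.
    """

    temperature: float
    indicator: str
    params: tuple[float, float, float]       # b1..b3, no intercept
    bse: tuple[float, float, float]
    r_squared: float
    time_range: tuple[float, float]          # hours since pupariation
    baseline: float = 0.0
    resid_sd: float = 0.0
    response_frame: str = "change-from-pupariation"

    def reliable(self, threshold: float = RELIABILITY_THRESHOLD) -> bool:
        return np.isfinite(self.r_squared) and self.r_squared >= threshold

    def predict(self, t) -> np.ndarray | float:
        """Fitted indicator change at time(s) ``t`` since pupariation."""
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.time_range
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise ValidationError(
                f"time outside the fitted range [{lo:g}, {hi:g}] h")
        b1, b2, b3 = self.params
        out = b1 * t_arr + b2 * t_arr ** 2 + b3 * t_arr ** 3
        return float(out) if np.isscalar(t) else out

    def slope(self, t: float) -> float:
        b1, b2, b3 = self.params
        return b1 + 2 * b2 * t + 3 * b3 * t ** 2

    def monotone_end(self) -> float:
        """End of the initial monotone segment: first interior time where
        the fitted derivative changes sign, else the end of the range."""
        b1, b2, b3 = self.params
        lo, hi = self.time_range
        s0 = self.slope(lo + 1e-9 * max(hi, 1.0))
        roots = np.roots([3 * b3, 2 * b2, b1]) if (b3 or b2) else np.array([])
        interior = sorted(float(r.real) for r in np.atleast_1d(roots)
                          if np.isreal(r) and lo < r.real < hi)
        for r in interior:
            if self.slope(min(hi, r + 1e-6)) * s0 < 0 or s0 == 0:
                return r
        return hi

    def invert(self, observed_delta: float, tol: float = 1e-6,
               threshold: float = RELIABILITY_THRESHOLD) -> float:
        """Time since pupariation at which the fitted change equals
        ``observed_delta``, on the initial monotone segment.

        Refuses when the fit is below the reliability threshold (low
        temperatures disrupt the weight-loss pattern, so a poor fit must
        not be inverted for casework).
        """
        if not self.reliable(threshold):
            raise UnreliableModelError(
                f"{self.indicator} model at {self.temperature:g} degC has "
                f"R2 = {self.r_squared:.4f} < {threshold:g}: refusing age "
                f"inversion (indicator pattern unreliable at this temperature)")
        lo = self.time_range[0]
        hi = self.monotone_end()
        f_lo, f_hi = self.predict(lo), self.predict(hi)
        if not (min(f_lo, f_hi) - 1e-12 <= observed_delta <= max(f_lo, f_hi) + 1e-12):
            raise ValidationError(
                f"observed change {observed_delta:g} outside the fitted "
                f"response range [{min(f_lo, f_hi):.4g}, {max(f_lo, f_hi):.4g}]")
        f = lambda t: self.predict(t) - observed_delta
        if f(lo) == 0:
            return lo
        if f(hi) == 0:
            return hi
        return float(brentq(f, lo, hi, xtol=tol))

    def summary(self) -> str:
        b, se = self.params, self.bse
        return (
            f"Pupal {self.indicator} fit at {self.temperature:g} degC "
            f"({self.response_frame})\n"
            f"  dY(t) = ({b[0]:.5e} +/- {se[0]:.5e}) t "
            f"+ ({b[1]:.5e} +/- {se[1]:.5e}) t^2 + ({b[2]:.5e} +/- {se[2]:.5e}) t^3\n"
            f"  R2 = {self.r_squared:.4f}; valid t in [{self.time_range[0]:g}, "
            f"{self.time_range[1]:g}] h; reliable = {self.reliable()}"
        )

    def to_dict(self) -> dict:
        unit = "g" if self.indicator == "weight" else "mm"
        return {
            "temperature": {"value": self.temperature, "unit": "degC"},
            "indicator": self.indicator,
            "coefficients": {"value": list(self.params),
                             "unit": [f"{unit}/h", f"{unit}/h^2", f"{unit}/h^3"]},
            "coefficient_se": list(self.bse),
            "r_squared": self.r_squared,
            "time_range": {"value": list(self.time_range), "unit": "h"},
            "baseline": {"value": self.baseline, "unit": unit},
            "resid_sd": {"value": self.resid_sd, "unit": unit},
            "response_frame": self.response_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PupalIndicatorResults":
        return cls(temperature=d["temperature"]["value"],
                   indicator=d["indicator"],
                   params=tuple(d["coefficients"]["value"]),
                   bse=tuple(d["coefficient_se"]),
                   r_squared=d["r_squared"],
                   time_range=tuple(d["time_range"]["value"]),
                   baseline=d["baseline"]["value"],
                   resid_sd=d["resid_sd"]["value"],
                   response_frame=d.get("response_frame",
                                        "change-from-pupariation"))


class PupalIndicatorModel:
    """Through-origin cubic model of one pupal indicator's change."""

    def __init__(self, times, values, temperature: float, indicator: str):
        if indicator not in INDICATORS:
            raise FitError(f"indicator must be one of {INDICATORS}")
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        keep = np.isfinite(t) & np.isfinite(v)
        order = np.argsort(t[keep], kind="stable")
        self.times = t[keep][order]
        self.values = v[keep][order]
        self.temperature = float(temperature)
        self.indicator = indicator

    @classmethod
    def from_series(cls, series: pd.DataFrame, temperature: float,
                    indicator: str) -> "PupalIndicatorModel":
        if indicator not in series.columns:
            raise FitError(f"series has no {indicator!r} column")
        sub = series[(series["temperature"] == temperature)
                     & (series["reference_event"] == "pupariation")]
        sub = sub[np.isfinite(sub[indicator])]
        if not len(sub):
            raise FitError(
                f"no {indicator} observations at {temperature:g} degC")
        return cls(sub["time"].to_numpy(), sub[indicator].to_numpy(),
                   temperature, indicator)

    def fit(self) -> PupalIndicatorResults:
        t, v = self.times, self.values
        if len(np.unique(t)) < 5:
            raise FitError(
                f"need >= 5 distinct time points, have {len(np.unique(t))}")
        baseline = float(v[t == t.min()].mean())
        delta = v - baseline
        X = np.column_stack([t, t ** 2, t ** 3])
        fit = sm.OLS(delta, X).fit()
        resid = delta - X @ fit.params
        # R2 about the mean of the transformed response (not the
        # through-origin uncentered R2): can be negative for a useless fit
        sst = float(np.sum((delta - delta.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0
        resid_sd = (float(np.sqrt(np.sum(resid ** 2) / (len(t) - 3)))
                    if len(t) > 3 else 0.0)
        return PupalIndicatorResults(
            temperature=self.temperature, indicator=self.indicator,
            params=tuple(float(p) for p in fit.params),
            bse=tuple(float(s) for s in fit.bse),
            r_squared=float(r2),
            time_range=(float(t.min()), float(t.max())),
            baseline=baseline, resid_sd=resid_sd)


def fit_pupal_indicator(series: pd.DataFrame, temperature: float,
                        indicator: str) -> PupalIndicatorResults:
    """Fit a pupal indicator model from a pupariation-referenced series."""
    return PupalIndicatorModel.from_series(series, temperature, indicator).fit()


@dataclass(frozen=True)
class IndicatorRanking:
    """Indicators ordered by descending fit quality, per temperature."""

    temperature: float
    ranking: tuple[tuple[str, float], ...]     # (indicator, r_squared)
    reliability: dict[str, bool]
    threshold: float = RELIABILITY_THRESHOLD

    @property
    def best(self) -> str:
        return self.ranking[0][0]

    def summary(self) -> str:
        lines = [f"Indicator ranking at {self.temperature:g} degC "
                 f"(reliability threshold {self.threshold:g})"]
        for ind, r2 in self.ranking:
            flag = "reliable" if self.reliability[ind] else "UNRELIABLE"
            lines.append(f"  {ind:8s} R2 = {r2:.4f}  [{flag}]")
        return "\n".join(lines)


def rank_indicators(models: list[PupalIndicatorResults],
                    threshold: float = RELIABILITY_THRESHOLD) -> IndicatorRanking:
    """Rank >= 2 indicators at one temperature by descending R2.

    Ties break alphabetically by indicator name, making the order a pure
    function of the model set, not of input order.
    """
    if len(models) < 2:
        raise FitError("need >= 2 indicator models at a temperature")
    temps = {m.temperature for m in models}
    if len(temps) != 1:
        raise FitError(f"models span several temperatures: {sorted(temps)}")
    ordered = sorted(models, key=lambda m: (-m.r_squared, m.indicator))
    return IndicatorRanking(
        temperature=models[0].temperature,
        ranking=tuple((m.indicator, m.r_squared) for m in ordered),
        reliability={m.indicator: m.reliable(threshold) for m in ordered},
        threshold=threshold)


def invert_pupal_weight(model: PupalIndicatorResults, observed_delta_weight: float,
                        tol: float = 1e-6) -> float:
    """Intrapuparial age (h since pupariation) from an observed weight change."""
    if model.indicator != "weight":
        raise FitError(f"expected a weight model, got {model.indicator!r}")
    return model.invert(observed_delta_weight, tol=tol)
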
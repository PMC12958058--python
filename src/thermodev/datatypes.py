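"""Core tabular containers and their validation rules.

The package represents its three tabular inputs as pandas DataFrames with
fixed canonical column names, validated on construction:

``StageDurationTable``
    replicate-level stage durations: one row per
    (temperature, replicate, stage) with a positive duration in hours.
``MeasurementSeries``
    larval or pupal measurement time series: time in hours since a
    reference event (hatching for larvae, pupariation for pupae) plus any
    of length (mm), width (mm), weight (g); missing cells are NaN, never 0.
``TemperatureLog``
    an hourly (or finer) temperature record: strictly increasing timestamps
    in hours on a common clock, temperatures in Celsius.

Validation helpers raise :class:`~thermodev.exceptions.ValidationError`
naming the offending rows. Summary statistics travel as
:class:`GroupSummary` (mean, SD, n) — the form in which rearing studies
usually publish their data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Developmental stages, in chronological order. "hatching" is the egg
#: stage (oviposition -> hatch); "pupation" the intrapuparial period;
#: "eclosion" the final stretch until adult emergence.
STAGES: tuple[str, ...] = (
    "hatching",
    "instar2",
    "instar3",
    "wandering",
    "pupation",
    "eclosion",
)

#: Cumulative developmental milestones matching the stage order.
MILESTONES: tuple[str, ...] = (
    "hatch",
    "end_instar2",
    "end_instar3",
    "end_wandering",
    "end_pupation",
    "eclosion",
)

#: Events a measurement series may be referenced to.
REFERENCE_EVENTS: tuple[str, ...] = ("hatching", "pupariation")

#: Plausible temperature range for a field or laboratory record (deg C).
TEMPERATURE_RANGE: tuple[float, float] = (-20.0, 60.0)

DURATION_COLUMNS = ("temperature", "replicate", "stage", "duration")
MEASUREMENT_COLUMNS = ("temperature", "time", "length", "width", "weight",
                       "reference_event")
LOG_COLUMNS = ("time", "temperature")


@dataclass(frozen=True)
class GroupSummary:
    """Published summary statistics for one group: mean +/- SD with n.

    ``sd == 0`` is legal (a stage can complete simultaneously in all
    replicates when checks are coarser than the true spread).
    """

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(
                f"group {self.label!r}: n must be >= 2 (SD undefined for n < 2)")
        if not np.isfinite(self.mean):
            raise ValidationError(f"group {self.label!r}: mean must be finite")
        if not (np.isfinite(self.sd) and self.sd >= 0):
            raise ValidationError(f"group {self.label!r}: sd must be finite and >= 0")


def _line_numbers(index: pd.Index, offset: int = 2) -> list[int]:
    # +2: 1-based counting plus a header row
    return [int(i) + offset for i in index]


def validate_duration_table(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Validate a stage-duration table; returns it with canonical dtypes.

    Raises ValidationError naming 1-based input lines for bad rows.
    """
    missing = [c for c in DURATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {missing}")
    out = df.loc[:, list(DURATION_COLUMNS)].copy()

    bad_stage = out.index[~out["stage"].isin(STAGES)]
    if len(bad_stage):
        labels = sorted(out.loc[bad_stage, "stage"].astype(str).unique())
        raise ValidationError(
            f"{source}: unknown stage label(s) {labels} on line(s) "
            f"{_line_numbers(bad_stage)}; expected one of {list(STAGES)}")

    for col in ("temperature", "duration"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna()]
        if len(bad):
            raise ValidationError(
                f"{source}: non-numeric {col} on line(s) {_line_numbers(bad)}")
        out[col] = coerced.astype(float)

    bad_dur = out.index[out["duration"] <= 0]
    if len(bad_dur):
        raise ValidationError(
            f"{source}: duration must be > 0 h; offending line(s) "
            f"{_line_numbers(bad_dur)}")
    bad_temp = out.index[(out["temperature"] <= 0) | ~np.isfinite(out["temperature"])]
    if len(bad_temp):
        raise ValidationError(
            f"{source}: temperatures must be finite and > 0 degC; line(s) "
            f"{_line_numbers(bad_temp)}")
    out["replicate"] = out["replicate"].astype(str)
    return out.reset_index(drop=True)


def validate_measurement_series(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Validate a measurement series (larval lengths or pupal indicators)."""
    required = ("temperature", "time", "reference_event")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {missing}")
    out = df.copy()
    for col in ("length", "width", "weight"):
        if col not in out.columns:
            out[col] = np.nan
    out = out.loc[:, list(MEASUREMENT_COLUMNS)]

    bad_ev = out.index[~out["reference_event"].isin(REFERENCE_EVENTS)]
    if len(bad_ev):
        raise ValidationError(
            f"{source}: reference_event must be one of {list(REFERENCE_EVENTS)}; "
            f"line(s) {_line_numbers(bad_ev)}")
    for col in ("temperature", "time"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    for col in ("length", "width", "weight"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    bad_time = out.index[(out["time"] < 0) | ~np.isfinite(out["time"])]
    if len(bad_time):
        raise ValidationError(
            f"{source}: times must be non-negative; line(s) {_line_numbers(bad_time)}")
    no_measure = out.index[out[["length", "width", "weight"]].isna().all(axis=1)]
    if len(no_measure):
        raise ValidationError(
            f"{source}: each row needs at least one measurement; line(s) "
            f"{_line_numbers(no_measure)}")
    neg = out.index[(out[["length", "width", "weight"]] < 0).any(axis=1)]
    if len(neg):
        raise ValidationError(
            f"{source}: measurements must be >= 0; line(s) {_line_numbers(neg)}")

    for (_, _), grp in out.groupby(["temperature", "reference_event"], sort=False):
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValidationError(
                f"{source}: times must be non-decreasing within each "
                f"(temperature, reference_event) group")
    return out.reset_index(drop=True)


def validate_temperature_log(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Validate a temperature log; collapses duplicate timestamps by mean.

    Duplicate timestamps are averaged with a warning; decreasing timestamps
    are an error; temperatures outside the plausible range are an error.
    Gaps larger than twice the median sampling step are flagged by warning.
    """
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {missing}")
    out = df.loc[:, list(LOG_COLUMNS)].copy()
    if len(out) == 0:
        raise ValidationError(f"{source}: temperature log is empty")
    for col in LOG_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="raise").astype(float)

    t = out["time"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValidationError(f"{source}: timestamps must be non-decreasing")
    if out["time"].duplicated().any():
        warnings.warn(f"{source}: duplicate timestamps collapsed by averaging",
                      stacklevel=2)
        out = out.groupby("time", as_index=False)["temperature"].mean()

    lo, hi = TEMPERATURE_RANGE
    bad = out.index[(out["temperature"] < lo) | (out["temperature"] > hi)]
    if len(bad):
        raise ValidationError(
            f"{source}: temperatures outside the plausible range "
            f"[{lo}, {hi}] degC on line(s) {_line_numbers(bad)}")

    dt = np.diff(out["time"].to_numpy())
    if len(dt) and np.any(dt > 2 * np.median(dt)):
        warnings.warn(f"{source}: gaps detected in the temperature record",
                      stacklevel=2)
    return out.reset_index(drop=True)


def total_durations(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(temperature, replicate) total developmental duration.

    Sums the six stage durations; requires all stages present for each
    replicate so a partial record cannot masquerade as a short total.
    """
    table = validate_duration_table(table)
    counts = table.groupby(["temperature", "replicate"])["stage"].nunique()
    incomplete = counts[counts < len(STAGES)]
    if len(incomplete):
        raise ValidationError(
            f"total_durations: incomplete replicates (missing stages): "
            f"{list(incomplete.index)}")
    out = (table.groupby(["temperature", "replicate"], as_index=False)["duration"]
           .sum())
    return out.rename(columns={"duration": "total_duration"})
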
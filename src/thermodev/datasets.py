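"""Published reference data for *Protophormia terraenovae*.

A constant-temperature rearing study of this cold-adapted blow fly
(15/20/25 degC, three replicates of >= 100 eggs each) published its
results as summary tables: per-stage durations as mean +/- SD with the
one-way ANOVA statistics, cubic larval-growth equations per temperature,
thermal-summation parameters (thermal constant K in degree-hours and lower
developmental threshold D0), and cubic pupal-indicator equations.

Those printed tables are the only public form of the data, and they are
exactly what a forensic practitioner would plug into this package. This
module ships them as plain pandas DataFrames so the statistics can be
recomputed and the growth/pupal equations evaluated without retyping.

Durations are hours; temperatures degC; lengths/widths mm; weights g;
K degree-hours (degC*h).
"""

from __future__ import annotations

import pandas as pd

from .datatypes import STAGES, GroupSummary

#: Stage durations (mean +/- SD hours, n = 3 replicates) per temperature,
#: plus the whole-cycle total. The "total" row is the published total, not
#: a recomputed sum (the two agree).
_DURATION_ROWS = [
    # stage,       temp, mean,   sd
    ("hatching", 25.0, 20.67, 0.58),
    ("hatching", 20.0, 43.00, 0.00),
    ("hatching", 15.0, 79.33, 21.55),
    ("instar2", 25.0, 64.00, 6.93),
    ("instar2", 20.0, 52.00, 6.92),
    ("instar2", 15.0, 84.00, 12.00),
    ("instar3", 25.0, 52.00, 13.86),
    ("instar3", 20.0, 84.00, 31.75),
    ("instar3", 15.0, 196.00, 30.20),
    ("wandering", 25.0, 36.00, 31.75),
    ("wandering", 20.0, 40.00, 6.93),
    ("wandering", 15.0, 60.00, 31.75),
    ("pupation", 25.0, 160.00, 13.86),
    ("pupation", 20.0, 172.00, 6.93),
    ("pupation", 15.0, 264.00, 31.75),
    ("eclosion", 25.0, 64.00, 18.34),
    ("eclosion", 20.0, 76.00, 36.66),
    ("eclosion", 15.0, 96.00, 12.00),
    ("total", 25.0, 396.67, 13.58),
    ("total", 20.0, 467.00, 60.40),
    ("total", 15.0, 779.33, 36.23),
]

#: Published one-way ANOVA statistics per stage (F, P, eta-squared "R2").
#: The wandering row is known not to be reproducible from its own printed
#: means/SDs (recomputation gives F ~ 0.72); it is kept verbatim here and
#: flagged by ``reproducible=False``.
_ANOVA_ROWS = [
    ("hatching", 16.9821, 0.0034, 0.8499, True),
    ("instar2", 9.8000, 0.0129, 0.7656, True),
    ("instar3", 24.3636, 0.0013, 0.8904, True),
    ("wandering", 1.4091, 0.3150, 0.3196, False),
    ("pupation", 23.3462, 0.0015, 0.8861, True),
    ("eclosion", 1.2895, 0.3421, 0.3006, True),
    ("total", 72.5798, 6.25383e-5, 0.9603, True),
]

#: Published thermal-summation parameters per stage: thermal constant K
#: (degree-hours +/- SD), lower developmental threshold D0 (degC +/- SD)
#: and the R2 of the linearized regression.
_THERMAL_ROWS = [
    ("hatching", 292.59092, 42.22426, 11.81045, 0.77611, 0.9707),
    ("instar2", 792.1875, 412.44018, 7.61719, 6.03406, 0.1854),
    ("instar3", 632.74086, 117.33543, 12.11379, 0.91268, 0.9618),
    ("wandering", 525.71429, 93.28473, 8.33333, 1.80388, 0.8102),
    ("pupation", 3086.54015, 531.62711, 3.59124, 2.59704, 0.2146),
    ("eclosion", 506.50307, 368.5154, 12.88344, 4.47946, 0.5417),
    ("total", 7569.56127, 481.11602, 5.46316, 0.84914, 0.8922),
]

#: Published larval length-vs-time cubic equations, with intercept:
#: L(t) = b0 + b1 t + b2 t^2 + b3 t^3, t hours after hatching, L in mm.
_GROWTH_ROWS = [
    (15.0, -2.83809, 0.10291, 8.35363e-6, -4.18914e-7, 0.9800),
    (20.0, -4.02386, 0.18566, -1.30549e-4, -1.42089e-6, 0.9777),
    (25.0, 0.17901, 0.04756, 0.00228, -1.21548e-5, 0.9823),
]

#: Published pupal-indicator cubic equations (no intercept), responses as
#: change from pupariation: dY(t) = b1 t + b2 t^2 + b3 t^3,
#: t hours after pupariation.
_PUPAL_ROWS = [
    (25.0, "length", 0.0012, -8.35138e-5, 4.39393e-7, 0.6407),
    (20.0, "length", 0.00684, -4.65282e-5, 5.89353e-8, 0.3577),
    (15.0, "length", 0.00341, -1.39097e-5, 2.15819e-8, 0.2951),
    (25.0, "width", 0.01845, -2.72983e-4, 1.01809e-6, 0.7765),
    (20.0, "width", 0.00311, -2.60554e-5, 8.03755e-8, 0.6786),
    (15.0, "width", 4.39334e-4, 1.93412e-6, -1.23374e-8, 0.1904),
    (25.0, "weight", -1.43017e-4, 1.29382e-6, -5.59615e-9, 0.9203),
    (20.0, "weight", -1.14275e-4, 8.80181e-7, -4.71536e-9, 0.9567),
    (15.0, "weight", -2.77036e-5, 1.26933e-7, -2.74288e-10, 0.2896),
]

#: Published eclosion rates (%), per rearing temperature.
ECLOSION_RATES = {15.0: 88.72, 20.0: 76.63, 25.0: 77.78}

#: Number of replicates behind every published mean +/- SD.
N_REPLICATES = 3


def load_duration_summaries() -> pd.DataFrame:
    """Stage-duration summary statistics (stage, temperature, mean, sd, n)."""
    df = pd.DataFrame(_DURATION_ROWS, columns=["stage", "temperature", "mean", "sd"])
    df["n"] = N_REPLICATES
    return df


def load_anova_reference() -> pd.DataFrame:
    """Published one-way ANOVA statistics per stage."""
    return pd.DataFrame(_ANOVA_ROWS,
                        columns=["stage", "F", "p", "r_squared", "reproducible"])


def load_thermal_reference() -> pd.DataFrame:
    """Published thermal-summation parameters per stage."""
    return pd.DataFrame(_THERMAL_ROWS,
                        columns=["stage", "K", "sd_K", "D0", "sd_D0", "r_squared"])


def load_growth_reference() -> pd.DataFrame:
    """Published larval growth cubics (temperature, b0..b3, r_squared)."""
    return pd.DataFrame(_GROWTH_ROWS,
                        columns=["temperature", "b0", "b1", "b2", "b3", "r_squared"])


def load_pupal_reference() -> pd.DataFrame:
    """Published pupal-indicator cubics (temperature, indicator, b1..b3, r2)."""
    return pd.DataFrame(_PUPAL_ROWS,
                        columns=["temperature", "indicator", "b1", "b2", "b3",
                                 "r_squared"])


def duration_group_summaries(stage: str) -> list[GroupSummary]:
    """GroupSummary triplet (25/20/15 degC) for one stage or ``'total'``."""
    if stage not in STAGES and stage != "total":
        raise KeyError(f"unknown stage {stage!r}")
    df = load_duration_summaries()
    rows = df[df["stage"] == stage]
    return [GroupSummary(label=f"{r.temperature:g}C", mean=r.mean, sd=r.sd, n=int(r.n))
            for r in rows.itertuples()]


def stage_mean_points(stage: str) -> list[tuple[float, float]]:
    """(duration, temperature) pairs of published means — thermal-fit input."""
    df = load_duration_summaries()
    rows = df[df["stage"] == stage]
    return [(float(r.mean), float(r.temperature)) for r in rows.itertuples()]
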
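# thermodev

Temperature-dependent developmental modelling of the cold-adapted blow
fly *Protophormia terraenovae*, and postmortem-interval (PMI) estimation
from its developmental state.

Forensic entomologists estimate a minimum PMI — the time from fly
oviposition on remains to their discovery — by inverting reference
models of insect development against the temperature record at the
scene. This package implements that modelling chain for
constant-temperature rearing data at 15–25 °C:

* **stage-duration statistics** — one-way ANOVA (from raw replicates or
  from published mean ± SD summaries, exactly equivalently), eta-squared,
  Tukey–Kramer multiple comparisons with compact letter display,
  eclosion rates;
* **thermal summation models** — the degree-day law D(T − D₀) = K
  fitted by the Ikemoto–Takai linearization (D·T on D) or the rate
  linearization (1/D on T), with studentized-residual outlier exclusion
  and degree-hour accumulation over arbitrary temperature records;
* **larval growth curves** — per-temperature cubic length-vs-age models,
  inverted on the feeding segment, and the derived isomegalen
  (length-contour) and isomorphen (milestone) diagrams;
* **pupal indicators** — through-origin cubic models of
  change-from-pupariation in length, width and weight, ranked by fit
  quality, with weight inversion refused below a reliability threshold;
* **a PMI engine** — age estimation from a just-reached milestone
  (degree-hour back-solving), a measured larval length, or a pupal
  weight change, with uncertainty intervals, guardrails outside the
  validated temperature range, and interval-intersection fusion;
* **a synthetic-data generator** with known ground truth for recovery
  testing, emulating the rearing design end to end.

Fits are exposed statsmodels-style: a model object built from data whose
`fit()` returns a results object carrying estimates, standard errors,
R² and a `summary()`. The published summary tables for this species ship
in `thermodev.datasets` so the reference statistics can be recomputed
directly.

## Worked example

```python
>>> import thermodev as td
>>> from thermodev.datasets import duration_group_summaries, stage_mean_points

# ANOVA of hatching duration across 15/20/25 degC from published summaries
>>> res = td.anova_from_summary(duration_group_summaries("hatching"))
>>> print(res.summary())
One-way ANOVA
  F(2, 6) = 16.9756, p = 0.003387
  SS_between = 5259.4934, SS_within = 929.4778
  R2 (eta-squared) = 0.8498

>>> td.tukey_hsd(summaries=duration_group_summaries("hatching")).letters
{'15C': 'a', '20C': 'b', '25C': 'b'}

# Thermal summation fit on the published mean durations
>>> fit = td.fit_thermal_ikemoto(stage_mean_points("hatching"), stage="hatching")
>>> print(fit.summary())
Thermal summation fit (ikemoto), stage = hatching
  K  = 319.56620 +/- 89.80817 degC*h
  D0 = 11.24477 +/- 1.68035 degC
  R2 = 0.9782 on 3 points

# Age a larva: 100 h at a constant 25 degC accumulates (25 - 11.24) x 100
# degree-hours; the PMI engine inverts that against the record
>>> log = td.generate_temperature_log(td.ConstantProfile(25.0), 200)
>>> est = td.estimate_age_adh(fit, log, discovery_time=150.0)
>>> print(est.summary())
PMI estimate (adh_milestone)
  point    = 23.2 h
  interval = [19.0, 26.5] h
  evidence : stage=hatching, K=319.57 degC*h, D0=11.24 degC, discovery=150 h
```

The F = 16.98 and the letter display say hatching is significantly
slower at 15 °C than at 20/25 °C, with 85% of the duration variance
explained by temperature. The thermal fit estimates that hatching needs
≈ 320 degree-hours above ≈ 11.2 °C; the PMI estimate inverts exactly
that accumulation, and its interval re-solves at the fit's standard-error
corners.

A command-line interface wraps the same library:

```sh
thermodev simulate --seed 1 --out-prefix syn      # synthetic cohort + log
thermodev anova syn_durations.csv                 # per-stage ANOVA + letters
thermodev fit-thermal syn_durations.csv --method both
thermodev diagram --kind isomorphen syn_durations.csv
thermodev estimate-pmi --temperature-log syn_templog.csv \
    --models bundle.json --discovery-time 300 --milestone hatching
```

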
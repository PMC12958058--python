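# Methods

## The problem

Necrophagous blow flies colonize remains shortly after death, and their
developmental state is the standard biological clock for estimating a
minimum postmortem interval (PMI): the time from oviposition to
discovery. *Protophormia terraenovae* is a cold-adapted species that is
often the only entomological evidence in cool-climate casework, so
reference models of its temperature-dependent development are directly
operational. This package implements the modelling chain from
constant-temperature rearing data (15–25 °C) to casework-side PMI
inversion, together with a synthetic-data generator carrying known
ground truth so every fitting routine can be validated by recovery.

## Stage-duration statistics

Durations of the six stages (egg/hatching, 2nd instar, 3rd instar,
wandering, intrapuparial/pupation, eclosion) are compared across rearing
temperatures with classical one-way fixed-effects ANOVA. Because rearing
studies publish their data as mean ± SD with n, `anova_from_summary`
computes the exact decomposition from those summaries:

    SS_between = Σ nᵢ (meanᵢ − grand_mean)²,   SS_within = Σ (nᵢ−1) sdᵢ²

which equals the raw-data ANOVA for any dataset with those summaries
(property-tested). The "R²" printed next to F in such tables is
eta-squared, SS_between/SS_total; this interpretation reproduces the
published values for every stage except wandering (see Known
discrepancies). Tukey's HSD uses the studentized range distribution
(`scipy.stats.studentized_range`), with the Tukey–Kramer standard error
for unbalanced groups, and summarises all pairwise tests as a compact
letter display via the insert-and-absorb algorithm; letters are assigned
starting from the group with the largest mean, matching the convention
in which the slowest (coldest) group carries "a".

## Thermal summation (degree-day) model

The linear degree-day model states that a stage completes when the
accumulated temperature excess above a lower developmental threshold D₀
reaches a thermal constant K: D(T − D₀) = K, with D the duration at
constant temperature T. Two standard linearizations are fitted by
ordinary least squares (statsmodels):

* **Ikemoto–Takai form** (`method="ikemoto"`, the default): regress
  D·T on D; slope = D₀, intercept = K. This matches the axes used in
  degree-hour plots (duration on x, accumulated degree-hours on y).
* **Rate form** (`method="rate"`): regress 1/D on T;
  K = 1/slope, D₀ = −intercept/slope, with standard errors by
  first-order propagation from the OLS coefficient covariance.

Both are exact on noiseless hyperbolic data (tested to 1e-9 relative).
The reported R² is that of the linearized regression actually fitted,
not a back-transformed value — which is why a table can print a low R²
next to a usable fit. Outlier handling (`exclude_nonlinear_points`)
iteratively removes the single worst point with externally studentized
residual above a threshold (default 3.0), refitting each round, never
below three points, with a full audit list; manual exclusions are always
honoured and labelled. The exact exclusion rule used to produce the
published parameters is not recoverable from the summary tables, so
every exclusion here is explicit, logged and reversible.

Degree-hour accumulation over a temperature record integrates
max(T(t) − D₀, 0) by the trapezoidal rule on the record's sample points,
clamping sub-threshold excess to zero (the standard degree-day
convention; the alternative of integrating first and clamping after
would credit development during cold spells). The hourly trapezoid
agrees with 1-minute quadrature within 0.5% on diel sinusoids (tested).

### Fitting on replicate means

The parameter-recovery study fits on per-temperature **mean** durations
rather than replicate-level points. With multiplicative duration noise,
the Ikemoto regression has noise on both axes (x = D, y = D·T), a
classical errors-in-variables situation whose attenuation bias is large
enough to matter at realistic noise levels (σ ≈ 0.1); averaging
replicates per temperature before the linearized fit suppresses it, and
is also the form in which published summary tables can be refitted at
all. Replicate-level fits remain available (`on_means=False`).

## Larval growth curves and diagrams

Larval length after hatching follows an S-shaped trajectory. Per
temperature a cubic with intercept, L(t) = b₀ + b₁t + b₂t² + b₃t³, is
fitted by OLS — the standard parametric form for forensic length-age
reference curves. Aging a larva inverts the fitted curve on the rising
(feeding) segment only, up to the time of maximum fitted length, by
bracketed root finding (`scipy.optimize.brentq`, 1e-6 h); the
plateau/shrinkage phase is excluded by construction because a length
there is not age-identifying. If the fitted segment is locally
non-monotone the smallest root is returned with a warning.

The **isomegalen grid** tabulates, for lengths 4–17 mm (1 mm steps, the
conventional display range), the time to reach each length at each
fitted temperature; unattainable cells are NaN, never extrapolated.
Linear-in-time interpolation across fitted isotherms exists for
presentation, flagged as such, and is not used in PMI math without an
explicit override. The **isomorphen table** is the cumulative sum of
per-temperature mean stage durations in chronological order; its last
milestone equals the total developmental duration by construction.

The time span of each cubic fit is recorded per model (`time_range`)
and evaluation outside it is refused: a reference curve is only valid
over the data that produced it.

## Pupal indicators

Table-form pupal aging equations in this literature are cubics *without*
an intercept although pupae are ~9 mm long — so the response cannot be
the absolute measurement. The package models the **change from
pupariation** (Δmm, Δg), which is consistent with the through-origin
form and with near-zero coefficients, and records the response frame in
every serialization. R² for these through-origin fits is computed about
the mean of the transformed response (it can be negative; negative
values are always unreliable). A reliability threshold of R² ≥ 0.5
separates invertible models from refused ones: weight models at 20–25 °C
(published R² 0.9567/0.9203) pass, the 15 °C weight model (0.2896) is
refused — encoding the finding that low temperature disrupts the
weight-loss pattern — and the threshold sits comfortably between those
two regimes rather than being tuned to any single value. Indicator
ranking orders by descending R² with alphabetical tie-break, which makes
the "weight-priority" pattern reproducible on synthetic data where the
rigid puparium keeps length and width constant up to noise.

## PMI engine

All estimators return a `PMIEstimate` (point, interval, method,
provenance, warnings) with minimum-PMI semantics: oviposition to
discovery, no pre-colonization interval.

* **ADH milestone route**: given that a stage just completed at
  discovery, scan backward over the temperature record accumulating
  degree-hours above the stage's D₀ until K is reached, interpolating
  linearly inside the bracketing sampling interval. The backward solve
  inverts forward accumulation to within 0.1 h on hourly logs (tested).
  The interval re-solves at the (K−SE, D₀+SE) and (K+SE, D₀−SE)
  parameter corners — a conservative box chosen because the two
  estimates are strongly negatively coupled in the linearized fits and
  published tables print no covariance; the delta method would need one.
* **Length route**: invert the growth cubic at the scene temperature and
  add that temperature's hatching duration from the isomorphen table.
  The interval maps the fit's residual SD through the local slope, so it
  widens toward the plateau where length stops discriminating age (and
  degenerates to the full feeding phase at zero slope, with a warning).
* **Pupal route**: invert the (reliable) weight model and add the
  cumulative pre-pupal time. Unreliable models are refused, not warned.
* **Combination**: interval intersection with midpoint as the point
  estimate; disjoint intervals fall back to the union with a conflict
  warning. The rule is deliberately simple and auditable — no principled
  fusion method exists for these heterogeneous interval semantics, and
  conflict must be surfaced, not averaged away.

Guardrails: all routes refuse temperatures outside the validated
15–25 °C rearing range unless explicitly overridden (then they warn);
ADH estimates from fits with R² < 0.5 carry a mandatory warning.

## Synthetic data generator

The generator emulates the study design — constant-temperature rearing
at 15/20/25 °C with three replicates — and carries explicit ground
truth:

* **Durations**: D = K/(T−D₀)·exp(ε), ε ~ N(0, σ²), defaults patterned
  on the published stage parameters and σ = 0.1. Noise is multiplicative
  lognormal because durations are positive and their spread grows with
  the mean (rearing SDs at 15 °C are an order of magnitude above those
  at 25 °C). Sub-streams are keyed by (stage, temperature), so adding
  replicates extends rather than perturbs existing draws.
* **Larval length**: a logistic in physiological time,
  L = L_max/(1+exp(−ρ(τ−τ₀))) with τ = t(T−D₀_larval) degree-hours
  (L_max = 17 mm, ρ = 0.006 /°C·h, τ₀ = 700 °C·h). Writing the logistic
  in degree-hours (equivalently: a clock-time midpoint of τ₀/(T−D₀))
  makes warmer larvae reach every length earlier — the monotonicity the
  isomegalen diagram encodes; pivoting a temperature-scaled slope around
  a fixed clock-time midpoint would invert that ordering below the
  midpoint. The logistic is deliberately a different family from the
  cubic the analysis fits, so fit-quality checks are honest
  approximation tests, not self-fulfilling.
* **Pupal series**: weight W₀(1 − f·(t/t_ecl)^p) with W₀ = 80 mg,
  f = 0.3, p = 2 (> 1: accelerating loss toward eclosion, as observed;
  no functional form is published, so a power law is the simplest shape
  with that property); length and width constant (9.0/3.5 mm) plus
  noise. Measurement noise defaults (0.2 mm, 2 mg, within-replicate)
  are package choices — the study does not report its measurement error
  — and are flagged as such in the simulation manifest.
* **Temperature logs**: constant or sinusoidal hourly records; the diel
  sinusoid (mean ± amplitude, 24 h period) is the standard first
  approximation to field conditions.

What passing synthetic tests do **not** show: real larvae experience
maggot-mass heating, food limitation and genotype variation; real
temperature records have gaps and sensor error; and the generator's
hyperbolic truth matches the model family being fitted (except for the
larval curve, which deliberately does not). Recovery results therefore
validate the estimation machinery, not field accuracy.

## Validation studies (problem sizes)

* Parameter recovery: 100 seeds × (5 temperatures × 10 replicates),
  σ = 0.1, truth K = 300 °C·h, D₀ = 10 °C; medians reported for both
  fitting methods. Typical result ≈ 0.2 °C / 2.6% (Ikemoto).
* End-to-end PMI: 50 cases; each fits a whole-cycle model from an
  independent training cohort and ages a subject developed stage-by-
  stage with the true parameters under a 20 ± 5 °C diel sinusoid.
  The estimated-vs-true age error is ≈ 2% median, ≈ 4% maximum —
  dominated by fit error plus the approximation of six sequential stage
  thresholds by a single whole-cycle (K, D₀) pair under fluctuating
  temperature.

## Numerical choices

* Root finding: `brentq`, xtol 1e-6 h; inversions agree with exhaustive
  0.01-h grid scans (tested).
* Degenerate ANOVA inputs: all observations identical → F = 0, p = 1;
  zero within-group variance with unequal means → F = +inf, p = 0; zero
  pooled variance in Tukey → distinct means flagged significant.
* Cubic maximum located from the derivative's roots plus range
  endpoints; ties in inversion resolved toward the smallest root with a
  warning.
* Serialization is JSON with units recorded per field and %.17g CSV
  floats; read∘write is the identity at full float64 precision
  (round-trip parsing enabled in the readers).
* Duplicate temperature-log timestamps are averaged with a warning;
  decreasing timestamps are an error; values outside −20…60 °C are an
  error; gaps are flagged.

## Known discrepancies in the published reference tables

* The wandering-stage ANOVA row prints F = 1.4091, R² = 0.3196, but
  recomputation from its own printed means/SDs (36.00±31.75, 40.00±6.93,
  60.00±31.75, n = 3) gives F ≈ 0.72, R² ≈ 0.19. The shipped reference
  table keeps the printed values and flags the row `reproducible=False`;
  the package reports the recomputed value.
* The narrative text attributes the two best thermal fits
  (R² 0.9707/0.9618) to eclosion and third instar, while the parameter
  table assigns 0.9707 to hatching and 0.5417 to eclosion. The table is
  taken as authoritative.
* Text vs table R² for pupal weight (0.957 vs 0.9567 at 20 °C; 0.2897 vs
  0.2896 at 15 °C) are resolved in favour of the table.
* The published thermal parameters come from replicate-level data that
  were never released; refits from the printed means land within ±1 °C
  (D₀) and 15% (K) for the well-fitting stages (hatching, 3rd instar,
  total) and are treated as tolerance anchors, not exact targets. The
  published exclusions ("total at 20 and 15 °C; pupariation and
  post-feeding at 25 and 15 °C") must have operated on replicate-level
  points — dropping two of three temperature means would leave a single
  point — and cannot be reconstructed; they are representable here as a
  manual mask.

## Limitations

Constant-temperature models applied to fluctuating records assume rate
additivity (no rate-summation correction beyond degree-hour
integration); no upper developmental threshold or nonlinear rate model
(Brière, Lactin, Sharpe–Schoolfield) is implemented; no maggot-mass heat
correction; no Bayesian posterior over PMI — intervals are parameter-box
or delta-method constructions, not credible intervals.
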
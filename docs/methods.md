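# Methods

## Input and counting unit

The pipeline consumes event-level diagnosis records (patient identifier,
diagnosis code, calendar date) and reduces them to a code × month matrix
of **unique patients per code per month**. Repeat diagnoses of one patient
within a month are deliberately collapsed: the question is how many people
present with a condition, not how often it is coded. Codes are opaque
labels; no ICD hierarchy is consulted. The default analysis window is
January 1997 – December 2009 and codes are kept when their total
unique-patient count is *strictly greater than* a threshold (default 500).
Whether rare-code filtering should count events or patients is not a
settled convention; this implementation counts patients, consistent with
the counting unit, and the threshold is configurable.

The month axis is represented in decimal years at mid-month
(Jan 1997 → 1997.0417). Mid-month placement avoids a systematic
half-month phase bias in the spectral step; the axis is exactly evenly
spaced (1/12-year steps), which also lets the periodogram be validated
against the classical evenly-spaced periodogram.

## Trend model and de-trending

Each code's monthly series is modeled as a smooth secular level modulated
by bounded periodic factors plus counting noise. The level is estimated by
Gaussian-kernel Nadaraya–Watson regression evaluated at every month. Two
tunable parameters matter:

- **Bandwidth h (months).** Default: Silverman's normal-reference rule
  applied to the count-weighted month positions — each counted event is
  treated as an observation at its month, so n is the total count — then
  floored at **9 months**. The floor is essential: a Gaussian kernel of
  bandwidth h attenuates a cosine of period T by exp(−(2πh/T)²/2), so at
  h = 9 a 12-month signal contributes ~10⁻⁵ of its amplitude to the trend
  estimate and survives de-trending essentially intact, while decade-scale
  growth is absorbed almost completely. Without the floor, automatic
  bandwidths on high-count codes can shrink enough to swallow seasonal
  signal. Both the bandwidth and the floor are overridable.
- **Edge trim.** Kernel estimates within two bandwidths of either end of
  the series are unreliable (one-sided averaging biases them toward the
  interior), so ceil(2h) months are removed from each end of every aligned
  array. A standalone `detrend_series` call trims by the code's own
  bandwidth; the panel-level `TrendAdjuster` uses the widest trim implied
  by any code (or by the total series) for *all* codes, so every adjusted
  series shares one axis and the de-totaling subtraction is well defined.
  With the default floor this is 18 months per end, which is why input
  series shorter than five years are rejected.

Nadaraya–Watson does not exactly preserve mass, so the de-trended series
has mean near but not exactly zero; tests bound the residual mean by two
standard errors of the series mean.

## De-totaling (shared-seasonality removal)

Total hospital traffic oscillates within the year. Any code that is an
approximately fixed proportion of traffic inherits that oscillation, and
after de-trending it would show a genuine-looking sub-annual peak — the
central failure mode this package exists to prevent. The correction:

1. sum counts over all codes per month (the code under test included —
   with a realistic number of codes its own contribution is negligible);
2. de-trend the total with the same smoother on the common trimmed axis;
3. for code c, subtract scale꜀ × total_detrended(t), where
   scale꜀ = mean꜀ / mean_total on the trimmed axis — the code's expected
   counts if it were always a fixed proportion of the total.

The subtraction uses the raw de-trended total, not a re-smoothed version.
One known small-panel caveat: with few codes (≲ 20), a strong planted
signal on one code leaks into the others through the total at weight
scale꜀; panels in tests and examples use enough codes to keep this
negligible, as any real registry does.

## Periodogram and significance

The classical normalized Lomb–Scargle form (time-offset τ per frequency,
sample variance with the N−1 denominator) is implemented directly; on
evenly spaced data it reduces to the Schuster periodogram normalized by
the variance, which the tests assert to 10⁻¹⁰ relative tolerance, and a
noiseless unit sinusoid attains peak power (N−1)/2 ≈ N/2.

- **Grid.** Periods 2–60 months, frequency step 1/(4 × span) (oversampling
  factor 4). The grid spans more than the admissible period range so that
  long-period power can win the argmax and then be ruled inadmissible,
  rather than silently migrating to an in-range runner-up.
- **False-alarm probability.** At a single frequency the null power is
  Exp(1); the peak over the grid is assigned
  p = 1 − (1 − e^(−z))^M, computed via expm1/log1p so the small-p branch
  degrades gracefully to M e^(−z). M defaults to 2 × (grid size) /
  (oversampling factor) — the convention of the classical recipe, equal to
  N when the grid runs to the Nyquist frequency — and is configurable.
  Simulation places the realized null flag rate at p < 0.01 near 1% and
  the per-frequency power distribution indistinguishable from Exp(1)
  (KS test).
- **1.5-year rule.** If the best period exceeds 18 months the p-value is
  set to 1. A decade of monthly data supports very few cycles of such
  periods and they rarely admit a seasonal interpretation; the best period
  itself is still reported.
- **Multiplicity.** Benjamini–Hochberg q-values are computed across codes
  (statsmodels implementation, verified in tests against a hand-coded
  step-up oracle). The significance flag defaults to raw p < 0.01 with q
  reported alongside, so users can apply either convention.

## Clustering of seasonal codes

Significant codes are z-scored per row (zero-variance rows dropped with a
warning) and clustered agglomeratively with correlation distance
(1 − Pearson r between rows) and average linkage — both configurable. Row
z-scoring plus correlation distance makes the grouping sensitive to period
and phase, not to incidence level, which is what separates winter-peaking
from summer-peaking conditions. Equal-height merges follow scipy's
deterministic candidate ordering, so the tree is reproducible for a given
input row order. The adjusted (de-totaled) series are clustered, since
those are the series whose periodicity was established.

## Comorbidity screen

For a query code, each patient's index date is their *first* query event.
Control cohorts are built the same way from designated control codes;
patients in both a case and a control cohort are kept only as cases. For
every candidate condition, a is the number of distinct case patients with
at least one event in the half-open window [index − w, index) (default
w = 60 days; events on the index day are treated as plausible consequences
and excluded), and b the analogue for controls. Reported per condition:

- the **incidence ratio** (a/n₁)/(b/n₂), with a −1 sentinel when b = 0
  (an undefined ratio, not a zero effect);
- a **two-sided Fisher exact p** on the 2×2 table (a, n₁−a; b, n₂−b),
  plus BH q-values across conditions.

Multiple controls are screened independently and intersected: a condition
must reach significance against every control, which suppresses artifacts
of any single control's age or utilization profile. The printed statistics
of the first-listed control are reported for surviving conditions.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
dial. Monthly counts for code c are Poisson with mean

baseline꜀ × growth(t) × (1 + A_tot cos(2π t / P_tot − φ_tot))
× (1 + A꜀ cos(2π (t − φ꜀) / T꜀)),

with defaults: 156 months from January 1997; linear multiplicative growth
doubling over 12 years; shared oscillation period 6 months with amplitude
0.1 (hospital-wide spring/fall swings on the order of ten percent);
planted per-code signals off unless requested. Chronic-fraction codes
instead receive mean = fraction꜀ × (sum of the non-chronic codes' means),
so they are exactly a fixed proportion of traffic up to Poisson noise.
Counts are drawn first and the event table is materialized from them
(distinct patients per counted unit; an optional patient-reuse probability
adds duplicate same-month events without changing unique counts), so the
truth table is exact and aggregation must round-trip.

What the generator does **not** emulate: inter-patient and inter-code
correlation beyond the shared total, coding-practice drift and code-set
transitions, non-Poisson overdispersion, age structure, and irregular
observation gaps. Passing tests therefore demonstrate correctness of the
adjustment and detection machinery under the stated statistical structure,
not robustness to every pathology of production EHR extracts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale panels — 200 chronic codes on a
156-month axis for the confound demonstration, 500 null codes for
calibration, 50 planted codes for power, 2 000 replicates for the null
power distribution — sizes at which every claimed effect is comfortably
resolved while the whole suite runs in well under a minute. Degenerate
inputs are handled explicitly: all-zero series yield a zero trend with an
undefined-bandwidth sentinel; constant series are rejected by the
periodogram (zero variance); series shorter than 24 months after trimming
are errors, not warnings. p-values are clipped to [0, 1]; the −1 ratio
sentinel is produced only for b = 0.

## Limitations

- The smoother is fixed to Gaussian-kernel Nadaraya–Watson with the
  bandwidth policy above; alternative detrenders (loess, STL,
  differencing) are out of scope by design.
- False-alarm probabilities use the single-harmonic exponential null with
  an effective-independence correction; they are calibrated in simulation
  but are not exact finite-sample probabilities.
- Fisher's exact test accompanies the comorbidity ratios as an indicative
  significance measure; bootstrap-based FDR machinery from full
  comorbidity-discovery systems is intentionally not reimplemented.
- The screen reports association in a time window, which is not causal
  ordering beyond the window's direction.
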
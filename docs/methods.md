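# Methods

This note documents the models implemented in respkit, the design choices
made where several reasonable options existed, and what the synthetic-data
generator does and does not emulate.

## Respirometry model

MO₂ is computed per measurement cycle as `V_eff · M⁻¹ · |d[O₂]/dt|`, with
`d[O₂]/dt` the ordinary least-squares slope of O₂ concentration against
time (hours) over the closed measurement window. Choices:

- **Effective volume.** `V_eff` = chamber volume (default 0.36229 L) minus
  the fish's body volume, taken as mass at a density of 1 kg L⁻¹ unless a
  measured volume is supplied.
- **Timestamping.** Each cycle's MO₂ is stamped at the midpoint of its
  measurement window. For any MO₂ trajectory that is linear within a window
  the OLS slope equals the trajectory at that midpoint exactly (symmetric
  uniform sampling), which is what makes the noiseless round-trip tests
  exact.
- **QC.** A cycle passes when R² ≥ 0.95 (squared Pearson correlation) and
  the *final* saturation of the window — the worst case — is ≥ 80%. A
  zero-variance (flat) window is assigned R² = 0 and therefore rejected.
  Raising the R² threshold can only shrink the passing set (tested
  property).
- **Rising slopes.** Apparent O₂ production is kept as negative MO₂ with a
  warning rather than silently dropped, so QC accounting stays complete.
- **Background respiration.** Estimated as the mean O₂ decline over the
  measurement windows of empty-chamber recordings made before and after the
  experiment (25 min each; one side may be missing, with a warning), flagged
  when it reaches 1% of the experiment's mean gross slope. Correction
  subtracts the (linearly interpolated) background slope *before* the MO₂
  equation; for a constant trajectory with background fraction f this
  rescales MO₂ by exactly (1 − f).
- **Solubility.** 100%-saturation concentration from the Benson–Krause
  freshwater polynomial (0–40 °C, zero salinity, constant pressure);
  saturation and concentration columns interconvert exactly.

## Synthetic traces

The generator emits per-second O₂ concentration with phase flags over
flush (default 77 s) / wait (3 s) / measure (80 s) cycles (160 s total, so a
48 h record holds 1080 cycles). During closed phases the true concentration
declines at `MO₂(t)·M/V_eff` plus the background slope; the per-second
decrement uses the trajectory at each step's midpoint, so (piecewise)
linear trajectories are recovered to solver precision. During the flush the
concentration relaxes exponentially to the saturated value with time
constant `V/flow` (300 L h⁻¹ → ~4.3 s); only closed-phase slopes matter
downstream. Optode noise is i.i.d. Gaussian *observation* noise
(default SD 0.02 mg L⁻¹, a typical optode resolution figure) added to the
true concentration. Background is generated as a constant slope equal to
`f/(1−f)` times the mean fish-driven slope, i.e. the fraction `f` of the
total measured slope (default 0.005, below the 1% flag). The generator
refuses trajectories that would drive the true concentration below zero.

Not emulated: optode drift and hysteresis, incomplete chamber mixing,
multi-fish group effects, diel temperature fluctuation outside the ramp
scenario. Passing round-trip tests therefore demonstrate correctness of the
computational chain under ideal sensor physics, not robustness to real
optode pathologies.

## Scenario presets

Each preset carries the published group-level values of the corresponding
experiment as its generative defaults:

- **daily_rhythm** — 48 h cosinor MO₂ (mesor 90.5, amplitude 16.9
  mg O₂ kg⁻¹ h⁻¹, acrophase 13.2 h), recording starting at 10:00; fish
  17.1 ± 3.1 g, n = 8. The matching locomotor rhythm (mesor 27.83,
  amplitude 21.5 pulses/10 min, acrophase 12.7 h) is generated by
  `synthesize_activity` (noiseless intensity or Poisson counts).
- **feeding** — a postprandial wave `baseline · (1 + w(t))` with `w` a
  piecewise-linear tent rising from feeding time to a 35% peak at 180 min
  and back to zero at 420 min; only the peak fraction, peak time and return
  time are published, so the tent is the minimal shape consistent with
  them. The fasted baseline is flat at the routine level (90.5); a rhythmic
  baseline can be configured instead.
- **acute_stress** — three-segment piecewise-linear course from 180
  mg O₂ kg⁻¹ h⁻¹: slopes +1.26, −0.72, −0.0184 units min⁻¹ with breaks at
  72 and 185 min. The published raw-data peak (252.02 at 39 min) is a
  feature of raw excursions, inconsistent with the fitted segments, and is
  deliberately not forced into the smooth preset.
- **temperature** — 0.1 °C min⁻¹ ramp 21→30 °C over 90 min. MO₂ rises at
  1.9 units min⁻¹ during the ramp (19 units per °C), continues to the
  published maximum 352 at minute 154, then declines at 0.16 units min⁻¹.
  The water-temperature column follows the ramp and holds at 30 °C.
- **anesthetic_{control,2pe,clove,ms222}** — rise/fall/plateau profiles
  built from the published table values (maximum; increase rate; time to
  maximum; decrease rate; stabilization time). The published "Base" row is
  internally inconsistent with a continuous profile built from the other
  five parameters (e.g. control: 353 − 0.025·36.8 ≈ 352, not 288.8), so the
  preset's plateau level is derived from those five and the Base row is
  reported by the analysis, not imposed by the generator.

All presets validate their invariants at import. Masses are drawn once per
simulated fish from the preset's normal distribution (truncated at 5 g),
and every random component is reproducible from a single integer seed.

## Rhythm analysis

- **Cosinor.** Linearized least squares on {1, cos ωt, sin ωt}; amplitude
  = √(βc² + βs²), acrophase Φ = atan2(βs, βc), reported both in radians and
  as the clock hour of the fitted maximum (t in hours since midnight, so
  clock anchoring of the series is required metadata; lights-on 08:00 = ZT0
  in the presets). Significance is the zero-amplitude test
  `F = ((SS₀ − SS₁)/2)/(SS₁/(n−3))` against F(2, n−3); its type-I error is
  verified at 5% by simulation. Fits default to the pooled raw points;
  hourly-grouped fitting is available but slightly attenuates the amplitude
  (mean of a cosine over an hour), which is why it is not the default — the
  noiseless end-to-end identity holds only for the raw fit.
- **Periodogram.** Sokolove–Bushell `Q_P = N·Var_h(M_h)/Var_i(x_i)` for
  K = P/bin integer columns, against the χ²(K−1) 1−α quantile. This
  normalization is χ² calibrated under an uncorrelated null (E[Q_P] ≈ K−1)
  and saturates towards N for a noiseless periodic signal. Candidate
  periods default to 1000–1700 min in bin-width steps; non-multiples of the
  bin are skipped rather than interpolated. Note the α-level threshold is
  per period: with ~70 candidates a pure-noise series crosses it
  occasionally, so peak calls on weak data should be read against the
  threshold margin.
- **Waveform/actogram.** Mean ± SD per time-of-day bin across days, and the
  day × bin matrix (double-plotted rows concatenate day i with day i+1);
  partial tail days are NaN-padded.

## Trend analysis

- **Segmented regression.** Continuous piecewise-linear least squares with
  the truncated-line basis {1, t, (t−b)+…}; breakpoints are found by
  exhaustive search over the observed time values with ≥ 5 points per
  segment, so the result is the exact RSS minimizer on that grid (earliest
  breaks win exact ties). The iterative estimator used by R's `segmented`
  would approximate the same optimum; at these instance sizes (≤ a few
  hundred points, ≤ 3 breaks) exact search is affordable and removes a
  convergence failure mode. A near-zero RSS improvement over a straight
  line triggers a degenerate-breakpoint warning. Slope standard errors
  condition on the selected breakpoints.
- **Stabilization time.** First breakpoint whose following segment slope is
  within 0.05 units min⁻¹ of zero (0 if the first segment is already flat,
  None if none is). The anesthetic profiles' published decrease rates
  (0.004–0.042 units min⁻¹) sit *below* that default, so the anesthetic
  analysis uses an adaptive tolerance — half the fitted falling slope,
  capped at 0.05 — to separate the plateau from the decline.
- **Mixed models.** Random-intercept REML fits go through statsmodels
  MixedLM (fish as the grouping factor); fixed-effect slopes are unbiased
  in simulation and reduce exactly to pooled OLS in balanced designs with
  zero between-fish variance. Backward selection drops the largest-p fixed
  term above α = 0.05 per step and the random intercept only at the zero
  variance boundary, keeping an audit log. Random slopes are out of scope.
- **Contrasts and classical tests.** Pairwise Wald contrasts (normal
  reference) with Benjamini–Hochberg adjustment by default (Holm–Sidak
  available); type-II two-way ANOVA with Holm–Sidak pairwise comparisons
  per family; paired Student t-test with the all-zero-differences case
  defined as t = 0, p = 1.

## Challenge metrics

- **SDA.** Fed and fasted series from the same fish are averaged within
  10-min bins (labeled by bin start, minutes post-feeding); percent change
  is computed per fish and averaged; a paired t-test per bin defines the
  significant window, with the degenerate zero-variance bin resolved by its
  mean (all-zero → p = 1, uniformly shifted → p = 0). Return to baseline is
  the first post-peak bin from which non-significance is sustained to the
  end of the record, the only operational reading of "returned to baseline"
  the source data support.
- **Q10.** `(r2/r1)^(10/(t2−t1))`, computed per fish and then averaged with
  SEM. The closed form applied to group-mean rates (112 → 278 over
  21→30 °C gives ≈ 2.75) is *not* the same number as a per-animal mean and
  the two are reported as distinct quantities.
- **Anesthetic profiles.** Per fish, a one-breakpoint fit gives the
  increase rate, time to maximum, fitted maximum and decrease rate; a
  two-breakpoint fit plus the stabilization rule gives stabilization time
  and the post-stabilization base (mean fitted value of the final segment).
  Raw maxima are logged alongside fitted maxima since the two differ in
  noisy data. Fish with infeasible fits are excluded with a log entry.
  Group metrics are compared by Wald contrasts on mean ± SEM, BH-adjusted
  within each metric.

## Problem sizes and determinism

Default test and acceptance runs use one to two simulated fish, 24–48 h
records at 1-s resolution, 500-replicate simulations for REML calibration
and 1000 for the zero-amplitude type-I check; these sizes make every
distributional claim testable while keeping the full suite under a minute
of compute for the deterministic parts. All randomness flows from explicit
integer seeds; identical configurations produce bit-identical outputs.

## Known limitations

- Breakpoint uncertainty is not propagated (no bootstrap CIs); slope SEs
  are conditional on the selected breaks.
- Discretization: extracted MO₂ lives on the cycle-midpoint grid (~2.7 min
  apart), so end-to-end breakpoint recovery is exact only to one cycle.
- The trace model has ideal optode physics (white noise only) and perfect
  mixing; flush dynamics are a single exponential.
- Periodogram periods are restricted to integer multiples of the bin width.
- Only random intercepts are supported in the mixed models; random slopes
  and crossed designs are out of scope.
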
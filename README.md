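# respkit

Simulation and analysis of **intermittent-flow fish respirometry**: from raw
per-second chamber O₂ traces to mass-specific metabolic rate (MO₂) and the
downstream inference a welfare-physiology study needs — daily-rhythm
(cosinor) analysis, chi-square periodograms of locomotor activity,
breakpoint/segmented trend analysis with random-intercept mixed models, and
challenge-specific metrics (postprandial specific dynamic action, thermal
Q10, anesthetic recovery profiles).

It is written for experimental fish physiologists who run chamber
respirometry (e.g. on goldfish-sized, 17–25 g animals in a ~362 mL chamber)
and for method developers who need a fully synthetic, ground-truth-known
test bed for respirometry pipelines.

## The model

An intermittent-flow respirometer alternates an open **flush** phase
(75–79 s), a short **wait** (1–10 s) and a closed **measure** phase
(75–150 s). During each closed phase the O₂ concentration declines linearly
and the mass-specific oxygen uptake follows from the fitted slope:

```
MO₂ = V · M⁻¹ · |d[O₂]/dt|      [mg O₂ kg⁻¹ h⁻¹]
```

with `V` the chamber volume minus the fish's body volume (L), `M` the fish
mass (kg). Quality control keeps a cycle only if the regression has
R² > 0.95 and the window never falls below 80% air saturation; microbial
background respiration (flagged when ≥ 1% of total) can be subtracted on the
slope scale.

Downstream, a daily rhythm is fit by the cosinor model
`Y = M + A·cos(t·π/12 − Φ)` (mesor `M`, amplitude `A`, acrophase `Φ`) with a
zero-amplitude F-test; locomotor periodicity by the Sokolove–Bushell
chi-square periodogram `Q_P = N·Var(column means)/Var(data)` against
χ²(K−1); challenge time courses by continuous piecewise-linear (segmented)
least squares with exhaustively searched breakpoints, REML random-intercept
models per segment, and BH-adjusted pairwise contrasts.

The `synthetic_data` module generates raw traces, MO₂ trajectories and
activity series for eight scenario presets (daily rhythm, feeding, acute
stress, temperature ramp 21→30 °C at 0.1 °C min⁻¹, and four anesthetic
groups), each parameterized with published group-level values, so every
stage of the pipeline is testable against known ground truth.

## Worked example

Simulate the acute-stress scenario (5-min chase, then a rise–fall–plateau
MO₂ time course) for two fish with optode noise, extract MO₂, and fit the
two-breakpoint segmented model:

```sh
respkit run --scenario acute_stress --seed 1 --n-fish 2 --out demo_out
```

prints (abridged):

```json
{
  "qc": {"n_measurements": 270, "n_qc_pass": 256, "n_rejected": 14},
  "segmented": {
    "breakpoints_min": [71.325, 183.325],
    "segment_slopes": [1.3006, -0.7197, -0.0291],
    "stabilization_time_min": 183.325,
    "basal_mo2": 189.26
  }
}
```

Reading: out of 270 measurement cycles, 256 pass QC. MO₂ rises at
~1.30 mg O₂ kg⁻¹ h⁻¹ per minute until ~71 min post-stress, falls at
~0.72 units min⁻¹ until ~183 min, then is essentially flat (|slope| < 0.05
units min⁻¹), i.e. the fish has metabolically stabilized about 3 h after
handling; the post-stabilization plateau averages ~189 mg O₂ kg⁻¹ h⁻¹. With
noise turned off the generating preset values (slopes 1.26 / −0.72 /
−0.0184, breaks 72 / 185 min) are recovered to within one measurement
cycle.

The same entry point runs the other scenarios (`daily_rhythm` reports the
cosinor fit, `feeding` the SDA metrics, `temperature` the per-degree slope,
peak time and Q10, `anesthetic_*` the recovery-profile table), and the
individual subcommands (`simulate`, `mo2`, `rhythm`, `periodogram`,
`segments`, `contrasts`, `sda`, `q10`, `anesthetic`) expose each stage over
the documented CSV dialects.

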
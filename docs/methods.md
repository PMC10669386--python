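# Methods

This note documents the models implemented in `glucofuzz`, the defaults
they ship with, and what the synthetic data can and cannot show.

## Clarke Error Grid and the severity score

Zone membership uses the standard 1987 inequality set over the
(reference *r*, estimate *ŷ*) plane, evaluated in the fixed order A, E,
C, D, else B with non-strict comparisons. The order makes boundary points
deterministic: a point lying on two zone boundaries takes the first
matching (more benign-first) label. `zone_intervals(r)` cuts the estimate
axis at every inequality threshold relevant at that reference
(0.8r, 1.2r, 70, 180, r+110, 1.4r−182) and labels each cell by
classifying its midpoint, so the interval labels agree with the
classifier at every interior point by construction; this doubles as the
brute-force oracle in the tests.

The continuous grid position ("severity") feeding the fuzzy system is
(*z* + *d*)/5, *z* the zone ordinal (A=0 … E=4) and *d* ∈ [0, 1) the
fractional depth of *ŷ* within its zone's interval at that reference,
measured away from the identity line. Inside zone A the depth is taken
from the identity line to the A boundary on the estimate's side, so
severity is exactly 0 on the identity line and nowhere else. The score is
piecewise-linear, clipped to [0, 1], and non-decreasing along any
vertical ray leaving the identity line (verified exhaustively on 1 mg/dL
sweeps). The estimate axis is normalised to `axis_max` = 600 mg/dL;
readings above are clipped for depth purposes only.

## Mamdani error model

The published description fixes the label structure (four voltage
triangles LoGl/MiGl/MoGl/HiGl, five CEG and five error triangles A–E,
centroid defuzzification) but not the numeric breakpoints, so the default
system declares them: evenly spaced triangular partitions with touching
feet and shoulders at the domain ends, over

- voltage: [1.0, 4.5] V — the span of the observed fingertip and tear
  channel readings, peaks at 1.0, 2.17, 3.33, 4.5 V;
- severity: [0, 1], peaks at 0, 0.25, 0.5, 0.75, 1;
- error: [0, 100] %, peaks at 0, 25, 50, 75, 100.

The rule base is the complete 4×5 grid with the consequent equal to the
CEG antecedent label; both published example rules have this form, and
the full grid preserves completeness (every input pair fires at least one
rule, so centroid defuzzification is always defined). Operators are fixed
at AND = min, implication = min, aggregation = max; the centroid is the
discrete Σxμ/Σμ over 1001 evenly spaced samples, which the tests hold to
within 0.1 of a trapezoidal integration at 100× resolution. Out-of-domain
inputs are clamped to the domain edge (and logged) rather than rejected,
since field measurements can slightly exceed the calibration span.
Because the consequent label tracks the CEG label and the output
partition is ordered, the defuzzified error is non-decreasing in severity
at any fixed voltage — the property that makes the prediction clinically
interpretable. Alternative breakpoints can be supplied via the YAML/JSON
system spec, which round-trips bit-exactly.

The predicted error is relative: the reported interval is
estimate ± estimate·error/100, and the point estimate is never altered.
With unpublished original membership functions, the packaged tables' ±
values serve as a plausibility reference, not a reproduction target.

## Calibration

Glucose is fit as an affine function of the selected channel voltages by
ordinary least squares (the detector output is proportional to received
light, and no richer form is identifiable from 15 printed rows). The fit
requires n ≥ channels + 2 rows and a full-rank design; constant voltages
raise a degenerate-fit error. Either the reference-device glucose
(default) or the prototype's displayed glucose can be the target; the
dual-channel mode is a single joint fit glucose ~ 1 + v_finger + v_tear.
Predictions are floored at 1 mg/dL with a logged warning. Residual
summaries (mean and max absolute residual) travel with the model.

## Sensor simulator

The forward chain is μₐ = μₐ₀ + k·G (linear glucose→absorption map),
μ_eff = 2μₐ(μₐ+μs′) as published — note this lacks the square root of
standard diffusion theory, so a `diffusion` mode √(3μₐ(μₐ+μs′)) is
provided and the mode is recorded in cohort metadata — then
*I* = *I*₀e^(−μ_eff·L) and *V* = *I*·responsivity·(1 + R₂/R₁).

Defaults: μₐ₀ = 0.8 mm⁻¹, μs′ = 2.4 mm⁻¹, L = 2 mm, *I*₀ = 30 (the
emitter's rated 30 mW), R₁ = 10 kΩ, R₂ = 20 kΩ (G = 3). The remaining
two degrees of freedom, k and the responsivity, are solved once
(deterministically, by bracketed root finding) so that the chain passes
through the two endpoints observed on the hardware's fingertip channel,
103 mg/dL → 1.22 V and 175 mg/dL → 3.5 V. This yields k ≈ −9.8×10⁻⁴
mm⁻¹/(mg/dL): voltage increases with glucose, matching the recorded
tables, and μₐ stays positive for glucose below ≈ 870 mg/dL. The PWM
drive (1 kHz), RC low-pass (330 Ω, 10 µF), 300 kΩ transimpedance resistor
and the 940/980 nm wavelengths are carried as metadata constants only; no
time-domain signal is simulated.

The cohort generator emulates the pilot protocol: 30 participants, half
diabetic, 12 measurements each at 15-minute intervals spanning a meal.
Per-participant baselines are truncated normals — healthy
N(115, 10²) on [100, 130] mg/dL, diabetic N(165, 10²) on [150, 180] —
matching the reference ranges the study cohort actually occupied. The
meal profile is a deterministic hump (peak +10 mg/dL around 45–60 min
post-meal) plus N(0, 2²) measurement noise, clipped to the group range;
the resulting within-participant spread of ~2–6 mg/dL matches the
per-participant standard deviations in the packaged summary table.
Voltage noise is additive Gaussian (default sd 0.03 V; the recorded
voltages are printed to 0.01 V), the tear channel is an affine companion
of the fingertip voltage (slope 1.3, offset −0.25 V, noise sd 0.05 V,
chosen to track the printed tear/finger relationship), and the
device-displayed glucose is the numeric inverse of the forward chain
applied to the noisy voltage. Everything derives from a single
`numpy` Generator seed; recorded voltages are rounded to 6 decimals and
glucose to integers, giving platform-stable reproducibility.

What the simulator does **not** emulate: physiological tear-to-blood lag,
drift or temperature sensitivity of the electronics, skin-tone and
perfusion variability, and any nonlinearity of the true glucose-optics
relationship. Passing tests on synthetic cohorts therefore demonstrate
the internal consistency of the chain (calibration recovers the
generating line, groups separate in voltage, intensity obeys *I* ≤ *I*₀),
not clinical performance on real measurements.

## Problem sizes and numerical choices

The packaged analyses run on the printed 15-row tables; simulated cohorts
default to the protocol size of 360 measurements. The exhaustive
classification check covers the integer grid [1, 600]² (360k points,
vectorised), interval-oracle agreement is sampled at 10⁴ random points,
and centroid oracles use 100× the default 1001-point resolution — all
chosen as comfortable desk-scale sizes. Ties at zone boundaries,
degenerate triangle shoulders, all-zero fuzzy curves, rank-deficient
calibration designs and out-of-range simulator glucose all have explicit,
tested behaviours (first-match labels, one-sided ramps, a no-rule-fired
error, a degenerate-fit error, and an invalid-input error respectively).

## Known limitations

- Zone percentages from the full 360-measurement study (97.5/2.2/0.3) and
  the exact printed ± half-widths depend on the original, unpublished
  membership functions and raw data; the package reproduces the printed
  15-pair statistics exactly and the qualitative error ordering, not
  those full-study figures.
- The severity formula and the MF breakpoints are declared package
  defaults, not recovered constants; both are configurable.
- The two-channel fusion is a transparent joint OLS fit; the original
  device's fusion procedure is not described and may differ.
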
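# Methods

This note documents the models, the synthetic cohort, the numerical choices
and the limitations of `ippid`. Everything stated here is computed by the
package's tests or scripts; nothing is quoted from external runs.

## Control-relevant model

The insulin→glucose channel on the 5-min control grid is a third-order
discrete transfer function with a three-step (15-min) delay,

    G(z)/I(z) = K z⁻³ / ((1 − p₁z⁻¹)(1 − p₂z⁻¹)(1 − p₃z⁻¹)),

with one slow real pole and a faster complex-conjugate pair. The
population-average values are

    p₁ = 0.9887,  p₂,₃ = 0.8353 ± 0.1949i,  K = −0.0769 (mg/dl)/(U/h).

Expanding the conjugate pair gives the quadratic factor
1 − 1.6706 z⁻¹ + 0.7357 z⁻². The `+0.7357` sign is forced by the pole values
and by stability; the equivalent ARX lag polynomial is
(a₁, a₂, a₃) = (−2.6593, 2.3874, −0.7274) with b = K. The DC gain is
K/∏(1−pᵢ) ≈ −104.5 mg/dl per U/h: insulin is slow-acting and strongly
persistent, which shapes everything downstream (long rise time, post-meal
undershoot risk).

## PID law and anti-windup

Error E(k) = 110 − Ĝ(k) (reference: the middle of the tight euglycemic range),
control period T = 5 min:

    I(k) = K_p E(k) + K_d (E(k) − E(k−1))/T + K_i S(k),
    S(k) = S(k−1) + T·E(k)   if Ĝ(k) ≤ 140 mg/dl,
    S(k) = S(k−1)            otherwise.

Average gains: K_p = −0.0665, K_i = −1.9342×10⁻⁴, K_d = −2.0922. The integral
freeze above 140 mg/dl is the only anti-windup element; proportional and
derivative action stay live, the previous error always updates (the
derivative must remain well defined), and the boundary value 140 itself
updates the integral. The commanded rate is clamped to [0, 15] U/h
(configurable upper clamp; prevents unphysical rates). The integral starts at
0 and needs a multi-day warm-up to ramp to the basal-compensating level, so
the first protocol day is excluded from all metrics.

Design check (deterministic): the linear closed loop (no clamp, integral
always active — the tuning target is a linear object) on the average plant
gives a 10→90 % rise time of 130.5 min and an overshoot of 2.19 %. Two
orderings of the integral update are defensible (use S before or after adding
the current error); this package follows the written law — S(k) includes
T·E(k) — which changes the overshoot by ~0.13 pp relative to the alternative.

## Personalization

Both schemes divide all three gains by a coefficient K′ > 0:

* **CR mode (time-varying)**: K′(h) = CRF(h)/CR_max with CR_max = 39.8381 g/U.
  CRF is the patient's piecewise-constant carbohydrate-ratio day curve
  (breakfast [05:00–11:00), lunch [11:00–17:00), dinner wrapping overnight)
  smoothed acausally. The smoother is a periodic zero-phase Gaussian kernel
  whose −3 dB point sits at 1/300 min⁻¹ (σ ≈ 39.7 min). A Gaussian kernel is
  a convex smoother: it preserves the daily mean exactly and can create no
  values outside the input range, properties a recursive zero-phase filter
  (e.g. filtfilt-Butterworth) does not guarantee at segment edges.
* **TDI mode (constant)**: K′ = TDI_max/TDI with TDI_max = 97.9932 U.

K′ is evaluated at every 5-min controller step from the clock. Note the two
schemes are *not* mutually calibrated — they differ by a patient-dependent
factor; the cohort construction below keeps both inside the loop's stability
margin (measured ≈ 3.3× on the average design point).

## Synthetic virtual cohort

No proprietary metabolic simulator is used; the cohort is generated by
`make_population` and is fully self-contained. Per patient:

* **Dynamics**: real pole ~ N(0.9887, 0.004), complex pair
  N(0.8353, 0.03) ± i·N(0.1949, 0.03) (redrawn until stable), gain
  −0.0769·κ with κ lognormal (mean 1, log-sd 0.3). A single `dispersion`
  knob scales all spreads; dispersion 0 collapses every patient onto the
  average model.
* **Circadian sensitivity**: nominal breakfast/lunch/dinner multipliers
  f = (0.75, 0.925, 0.85) ± (0.20, 0.175, 0.20) uniform (breakfast lowest —
  morning insulin resistance). Each day the three meal-time values are
  multiplied by independent Gaussian(1, 0.2) draws (±40 % with probability
  95.45 %) before smoothing with the same Gaussian smoother; the robust setup
  multiplies the whole path by one per-patient factor U[0.7, 1.3], constant
  over the experiment (a systematic error in the clinical parameters, not
  day-to-day noise).
* **Clinical parameters**: CR_meal = CR_max·κ·f_meal·ε (ε lognormal, sd 5 %),
  truncated to [3, CR_max]. Anchoring CR to the patient's gain ratio κ is
  what makes CR personalization meaningful: the CR-arm loop gain becomes
  κ·si(t)/K′(h) ≈ the daily noise alone. A side effect is that the stand-in's
  CRs concentrate in the upper clinical range (~20–40 g/U); real cohorts are
  broader. TDI is derived for consistency as basal·24 + Σ(mean meal CHO/CR),
  capped at TDI_max.
* **Endogenous production**: zero-insulin equilibrium glucose
  G₀ ~ N(300, 25) mg/dl (untreated-T1D hyperglycemia); the constant output
  term is c_e = G₀·∏(1−pᵢ). The basal rate is chosen so fasting glucose sits
  near 115 mg/dl, which puts TDI in the 40–90 U range and the TDI-arm
  bandwidth at roughly half the design point. The dawn phenomenon multiplies
  the endogenous term by 1 + a·sin²-bump over 04:00–08:00 with
  a ≈ 0.10 (≈ +30 mg/dl open loop, a typical clinical magnitude).
* **Meals**: linear two-compartment absorption, appearance ∝ t·e^(−t/τ) with
  τ = 40 min, scaled so a meal of g grams peaks at `meal_gain`·g mg/dl with
  meal_gain ≈ 0.8. This targets the modest postprandial excursions
  characteristic of fast IP insulin delivery; a 60 g meal raises open-loop
  glucose by ≈ 48 mg/dl at peak (the calibration test accepts 40–180).

### Plant realization

The patient TF is simulated in modal (diagonalized) form at a 30-s internal
step: 5-min poles map to p^(1/10), and per-mode input coefficients are scaled
by (1−q)/(1−p) so that — with insulin held over each 5-min period (zero-order
hold, which itself contributes one step of the three-step delay) — the plant
sampled at 5 min reproduces the ARX recursion *exactly* (unit-tested against
direct difference-equation evaluation). Insulin is multiplied by the current
sensitivity path before entering the TF; endogenous, dawn and meal terms are
additive on the output. Output glucose is floored at 0; a non-finite state
aborts the run naming the step.

## Sensing chain

First-order lag dGm/dt = (G(t−θ) − Gm)/τ with τ = 5.6 min, θ = 0.68 min,
discretized exactly (e^(−Δ/τ) recursion, delayed glucose linearly
interpolated, Gm(0) = G(0)). Zero-mean Gaussian noise with sd = 5 % of the
current *blood* glucose is added to each 30-s sample; the onboard filter
delivers the mean of the last ten 30-s samples to the controller every 5 min
(during start-up the available samples are averaged). With noise off and
constant input the chain is unbiased end to end.

## Protocol, rescue policy, metrics

Meals per day (uniform draws): breakfast 07:00–08:30 / 40 g ± 20 %, lunch
12:30–13:30 / 80 g ± 20 %, dinner 19:30–20:30 / 60 g ± 20 %; two optional
snacks (20 g ± 20 %), each present with probability 50 %, 120 ± 15 min after
breakfast/lunch. Hypo rescue (a clinical-convention stand-in, configurable):
15 g when the filtered measurement drops below 65 mg/dl, 30-min lockout.

Metrics are computed on **true plant glucose** at the 5-min grid, per window
(D&N: whole record after the warm-up day; PP: union of 4-h windows after main
meals, snacks excluded): mean, SD, TR [70–180], TTR [70–140], TA180, TA250,
TB70 (percent of samples), and LBGI/HBGI with the standard risk transform
f(g) = 1.509((ln g)^1.084 − 5.381), risk = 10 f², averaging the hypo- and
hyperglycemic sides separately. Samples are clamped to the risk scale's
defined domain [20, 600] mg/dl before the transform (below ~1 mg/dl the
fractional power is undefined); nonpositive samples are excluded with a
warning. Arms are compared two-sided with
Mann–Whitney U (continuous) and Fisher's exact test (fraction of patients
with ≥ 1 rescue); both are unit-tested against brute-force enumeration.
Experiments are paired: both arms see bit-identical scenarios, sensitivity
realizations and sensor noise (hierarchical seed splitting).

## Problem sizes and numerical choices

* Internal step 30 s; control period 5 min; step-response evaluation horizon
  2000 min with settledness = last 10 % of the trace within 0.5 % of the
  final value; rise-time crossings linearly interpolated between samples.
* The direction-of-effect comparison (CR vs TDI arm) is exercised in the test
  suite at 20 patients / 2 weeks, a scale at which the ordering of the median
  TTR and glucose-SD is already stable; larger runs (100 patients / 12 weeks)
  use the same code path via `run_experiment`.
* Identification runs through the full sensing chain with noise off; the
  sensor lag adds unmodelled dynamics, so identified poles sit slightly
  slower than the plant's — as they would on any real sensing chain. The
  identifiability guarantees (exact noiseless recovery, OLS consistency) are
  asserted on data generated directly from the ARX model class.
* Pole classification for averaging: the pair with the largest |imaginary
  part| is the complex pair, the remainder the real pole; all-real fits are
  excluded from the population average and counted.

## What the stand-in does and does not show

The cohort emulates: linear per-patient dynamics scattered around the average
model, circadian and day-to-day sensitivity variation, dawn phenomenon,
meal-driven excursions, a realistic sensing chain, and clinically consistent
CR/TDI parameters. It does **not** emulate nonlinear glucose–insulin
physiology — in particular there is no insulin-independent glucose uptake and
no counterregulatory response, so post-meal undershoot ends in a rescue
rather than being buffered hepatically; rescue counts are therefore higher
than a full metabolic simulator would produce, and absolute metric values
(not the CR-vs-TDI orderings) should be read with that in mind. Sensor
drift/dropout, exercise, illness and insulin-on-board estimation are out of
scope.
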
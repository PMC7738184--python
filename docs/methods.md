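# Methods

This note documents the models implemented in `chromadapt`, the parameter
choices that matter, and what the synthetic-data tests do and do not
establish about real data.

## Stimulus color space

Cone absorptions are rectangle-rule integrals at 1 nm of a radiance spectrum
against a cone-fundamental set (trapezoid integration differs below every
tolerance used here). The packaged *task-space* fundamentals are built by
the Smith–Pokorny partition of the Judd-modified luminosity function:

    L(λ) =  0.15514·x̄(λ) + 0.54312·ȳ′(λ) − 0.03286·z̄(λ)
    M(λ) = −0.15514·x̄(λ) + 0.45684·ȳ′(λ) + 0.03286·z̄(λ)
    S(λ) =  0.01608·z̄(λ)

with x̄, z̄ the CIE 1931 2° colour-matching functions and ȳ′ the Judd (1951)
revision of V(λ); L and M are jointly renormalised so that L + M = V′
exactly (the published row sums give 0.99996). Using CIE 1931 x̄, z̄ in place
of the fully revised short-wavelength functions is an approximation confined
below ~410 nm and negligible for the broadband lights handled here. The S
scale 0.01608 is the published constant that makes max_λ S/(L+M) = 1,
completing the conventional MacLeod-Boynton scaling; because rmb = L/(L+M)
is a ratio, the choice of reference light for the overall normalisation
(equal energy vs Illuminant C) has no effect on chromaticity, which is why
the package fixes L + M = V′ (peak 1) rather than exposing a knob.

MacLeod-Boynton chromaticity is `rmb = L/(L+M)`, `bmb = S/(L+M)`. Note that
the red-green coordinate is the standard MB *l* coordinate: with the
convention above, equal-energy white sits at rmb = 0.6654 (the matrix row
sum) and CIE Illuminant C computes to (0.65570, 0.01884), within 1.2e-3 and
6e-4 of the nominal (0.6568, 0.01825) used as the affine origin of the task
space. A difference form (L−M)/(L+M) sometimes written for this axis is
inconsistent with those Illuminant C coordinates under any standard scaling
and is not used. The scaled plane is

    LM = (rmb − 0.6568) × 2168      S = (bmb − 0.01825) × 6210

(one unit ≈ one detection threshold), and stimuli live on a circle of
radius 80 at 51 cd/m², parameterised by hue angle (degrees, CCW, 0° = +LM);
the task spans 200° (green endpoint) to 360° (red endpoint). Unique yellow
falls near 290–300°.

Standard tables (CIE 1931 2° CMFs at 5 nm, Judd short-wave V(λ) values at
10 nm, Illuminant C at 10 nm) are transcribed into `src/chromadapt/data/`
and linearly interpolated to 1 nm with zero outside support. The test suite
validates the transcriptions through independent identities: equal energy at
(1/3, 1/3) and Illuminant C at its published (0.3101, 0.3162) chromaticity,
both to 2e-3.

## Display and glasses

The default monitor has Gaussian gun spectra (peaks 610/530/450 nm, widths
28/33/30 nm) — a deliberate surrogate for unmeasured CRT phosphor spectra —
balanced so that full drive renders the Illuminant C chromaticity at
100 cd/m²; measured gun spectra drop in as two-column CSVs. Gamma is 1.0
(linearised guns) but configurable. Because L + M absorption equals
luminance/683 under the task fundamentals, a target (hue, radius, luminance)
fixes the L, M, S absorptions linearly and rendering reduces to one 3×3
solve; out-of-gamut targets raise an error naming the violating gun. The
full task circle is inside the default gamut at 51 cd/m².

The red glasses are a logistic edge
`T(λ) = floor + (ceiling − floor)/(1 + exp(−(λ − λ0)/w))` with defaults
λ0 = 585 nm, w = 8 nm, floor = 0.02, ceiling = 0.95, chosen to satisfy the
published characterisation of the physical glasses (T < 0.10 below 550 nm,
T > 0.90 above 620 nm); the constructor rejects parameters violating those
bounds. The measured transmittance exists only as a figure; no digitisation
is attempted, and every downstream computation accepts a measured curve.

## Generative model of the experiment

For observer parameters θ, day d (1…5), time t minutes:

* pre-glasses: `B_d = baseline0 + drift·(d−1)` with drift −0.94 °/day;
* glasses on: `B_d + rapid_d + slope·t/60`, `rapid_d = min(0, rapid_day1 +
  learn·(d−1))` with rapid_day1 = −72.64°, learn = +4.06 °/day, slope =
  13.30 °/hr. The cap at 0 forbids overshooting the no-glasses baseline;
* post-removal: `B_d + amp·exp(−t/τ)` with amp = 10°, τ = 12 min;
* follow-up (a month later): the rapid offset is `rapid_1 +
  retention·(rapid_5 − rapid_1)` with retention = 0.66, and the baseline
  holds at its day-5 value (the within-experiment drift is not extrapolated
  over the retention interval).

The headline means are the study's estimands; amp, τ, per-match noise
(σ = 3°), matches per block (shifted Poisson, mean 3, min 1) and all
between-observer SDs are free generative choices, set once to plausible
magnitudes for this task. Three deserve comment:

* **σ = 3° per match** makes cohort SEMs of a few degrees at n = 11,
  matching the scale of published group data for unique-yellow settings.
* **sd(gradual slope) = 0.** In a one-way ANOVA of session slopes with the
  same 11 observers in every session group, a shared observer term cancels
  from the between-group mean square but not the within-group one, so
  E[F] ≈ σ²_w/(σ²_b + σ²_w). A near-unity reported F for this design
  therefore implies σ_b ≈ 0 for the within-session slope, and the generator
  adopts that.
* **Latent learning ability.** One standard-normal factor loads (0.3) on
  learning rate and retention; with sd(learn) = 1.6 °/day and
  sd(retention) = 0.20 this puts the population correlation between the
  day-1→day-5 learning delta and the day-1→follow-up delta at ≈ 0.80, the
  regime of strong test-retest reliability. Sample correlations at n = 11
  scatter widely around it (10–90% range roughly 0.58–0.92).

AM and PM sessions share the same expected values by default (`pm_offset`
exists for sensitivity analyses). Simulated matches are clipped to the
task's [200°, 360°] range, as the apparatus enforces. One consequence is a
small genuine censoring bias: for observers whose day-1 on-glasses settings
approach the green endpoint, clipping flattens the early-session ramp and
depresses the grand within-session slope estimate by about 0.2% (−0.03 °/hr
at the defaults) — real truncation physics, not estimator error; removing
the clip restores exact unbiasedness.

The button-press micro-simulation starts uniformly in 290 ± 45°, holds a
noisy percept of the target (σ = 2° by default), presses 5° steps while more
than 6° away and 1° steps inside that, accepts within half a fine step, and
stops at a 20 s cap. Presses cost 0.75 s each: the task's 1.5 s cadence is
the stimulus presentation interval, and observers press about twice per
presentation. Presses have no effect beyond the endpoints, and a pinned
trace stays pinned — traces never exhibit endpoint-anchoring artefacts.

## Statistics

Tests are summarised as the mean of all five blocks (default), the first
block's mean, or the very first setting; missing cells become explicit NaN
rows. Baseline correction subtracts each day's morning pre-glasses value
from all of that day's settings (the follow-up uses its own pre test).
Within-session slopes are OLS of the five on-glasses tests on hours.
Cross-day trends are pooled OLS over observer-day points (55 points at the
defaults) with t-based 95% CIs; because the unit of analysis is a genuine
open choice, CIs are also reported for day-mean OLS (df = 3) and for the
per-observer-slope t interval — the slope itself coincides across all three
under a balanced design. The aftereffect decay is a bounded least-squares
fit of `asymptote + amp·exp(−t/τ)` with τ ∈ (0.1, 500] min, three τ starts
(5, 15, 60) against local minima, and the asymptote initialised at the
day's baseline. The session ANOVA is one-way and fixed-effects; the
degenerate all-equal input is reported as F = 0, p = 1. Retention is
`(followup − day1)/(day5 − day1)` on cohort means of the baseline-corrected
first on-glasses values; test-retest reliability is the Pearson correlation
of per-observer deltas; follow-up comparisons are paired two-sided t tests
(zero-variance differences are flagged degenerate rather than silently
infinite). No multiple-testing correction is applied anywhere; p values are
reported raw. Every stage is a pure function of its input table.

## Cone gain and constancy

`k = L/M` uses the same fundamental family rescaled to peak 1. Because the
gain set and the task set share curve shapes, k is fixed by chromaticity:
`k = rmb/(1−rmb) · M_max/L_max`. The absolute level therefore depends
entirely on the normalisation convention — with these Smith–Pokorny-shaped
curves, baseline unique yellow sits near k ≈ 1.27, whereas tables whose
peak-normalised L/M ratio at white is lower (e.g. Stockman–Sharpe-type)
place it near 1. Differences and fractions of k, which carry the analysis,
are unaffected by that constant. The constancy fraction is computed on the
scalar k axis (the analysis lives entirely in k); the perfect-constancy
reference is fixed from the day-1 morning baseline only. Aggregation order
(cohort-mean settings vs per-observer fractions averaged) is an open choice
and both are implemented; they coincide for homogeneous cohorts.

## Numerical choices and degenerate inputs

Spectra resample by linear interpolation, zero outside support; integrating
spectra with disjoint supports raises. Chromaticity requires L + M > 0; the
polar angle of the origin is undefined and raises. Rendering tolerates
1e-9 numerical slack at the gamut boundary. Decay fits report a convergence
flag instead of raising; flat curves fit with amplitude ≈ 0 and an
unidentified τ. All simulation randomness flows from one integer seed
through `numpy.random.default_rng`; identical seed and configuration
reproduce settings tables and report bundles byte for byte.

## Problem sizes used by the test suite

Replicate studies use 200 cohorts (seeds 0…199) for parameter recovery and
trend statistics, 1000 summary-level replicates for the ANOVA type-I
calibration, 500 replicate fits for decay-constant recovery, and 40 + 40
cohorts for the SE scaling law (11 vs 44 observers). These sizes resolve
biases of roughly 2% of an SD while keeping the full suite to a few
minutes on one CPU.

## Limitations

* The monitor and glasses are parametric surrogates; absolute gamut shapes
  and k levels will differ from any specific hardware, though all structural
  conclusions (gamut compression, redward shift, constancy growth,
  monotonicity of k in hue) are robust to the surrogate choice.
* The generator emulates the *statistical* structure of adaptation time
  courses (means, random effects, noise, censoring); it does not model
  block-to-block micro-dynamics, fatigue, criterion drift, or the between-
  lab activities of real observers. Passing recovery tests shows the
  estimators are correct for data of this structure, not that the structure
  exhausts real data.
* The one-way session ANOVA ignores the repeated-measures structure; with
  observer slope heterogeneity it becomes conservative (see above). A
  mixed-effects re-analysis is a documented extension, not implemented.
* Hue angles are treated as linear quantities on [200°, 360°]; no circular
  statistics are needed at these ranges, but settings pinned at the
  endpoints censor rather than wrap.
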
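# chromadapt

Colorimetric rendering and time-course statistics for repeated
color-adaptation experiments — the "visual mode switching" paradigm in which
observers don and remove strongly tinted (red) glasses several times a day
for days, and the state of their red-green adaptation is tracked with
unique-yellow settings.

The package is for visual psychophysicists who want to analyse (or power,
via simulation) such experiments end to end:

* **Stimulus colorimetry.** Cone absorptions from spectra, MacLeod-Boynton
  chromaticity `rmb = L/(L+M)`, `bmb = S/(L+M)`, and the threshold-scaled
  task plane `LM = (rmb − 0.6568)·2168`, `S = (bmb − 0.01825)·6210`, whose
  origin is CIE Illuminant C. Stimuli live on a radius-80 hue circle on the
  51 cd/m² isoluminant plane; the response variable is hue angle (200° green
  endpoint … 360° red endpoint).
* **Display + filter model.** Gaussian-primary monitor (drop-in CSVs for
  measured gun spectra), logistic red-glasses transmittance satisfying the
  published bounds (T < 0.10 below 550 nm, T > 0.90 above 620 nm), gamut
  computation, and exact rendering of hue settings via a 3×3 linear solve.
* **Synthetic observers.** A generative model of the full experiment:
  per-day baselines with slow greenward drift (−0.94 °/day), a day-by-day
  growing rapid adjustment on donning the glasses (+4.06 °/day on a −72.64°
  day-1 offset), a constant within-session adaptation ramp (13.30 °/hr), an
  exponentially decaying redward aftereffect after removal, a follow-up
  session retaining 66% of the learning, per-observer random effects with a
  latent "learning ability" factor, and a button-press adjustment
  micro-simulation (5°/1° steps, 20 s cap, endpoint pinning).
* **Statistics pipeline.** Test summaries (all blocks / first block / first
  setting), morning-baseline correction, within-session OLS slopes,
  cross-day linear trends with 95% CIs under three df conventions, bounded
  multi-start exponential decay fits, one-way session ANOVA, retention
  fraction, test-retest Pearson correlation, and paired comparisons.
* **Cone-gain constancy.** Relative gain `k = L/M` of the light at the eye
  (through the glasses for glasses-on settings) with peak-normalised
  fundamentals, the perfect-constancy reference (baseline pixels viewed
  through the glasses), and the constancy fraction
  `|k_setting − k_baseline| / |k_perfect − k_baseline|`.

## Worked example

```bash
python examples/03_simulate_and_analyze.py
```

```
simulated 18066 individual matches

grand within-session slope: 13.22 deg/hr (generative truth 13.30: gradual adaptation toward red)
slope change across sessions: F(9,100) = 1.33, p = 0.23 (no change: adaptation rate is stable)
baseline drift   : -0.92 deg/day, 95% CI [-1.71, -0.13] (truth -0.94)
rapid adjustment : +3.97 deg/day, 95% CI [2.64, 5.31] (truth +4.06)
total adaptation : +3.94 deg/day, 95% CI [2.63, 5.25] (truth +4.06)
aftereffect decay (day 1): amplitude 9.3 deg, tau 11.9 min (truth 10 deg, 12 min)
retention at follow-up: 68% of the 5-day learning (truth 66%)
test-retest correlation of learning: r = 0.52, p = 0.104 (generative population value ~0.8)
```

The pipeline recovers the generating parameters of one simulated cohort:
the within-session ramp (observers add less green over the hour as they
adapt), the day-by-day growth of the immediate adjustment (the learning
effect), the slow greenward baseline drift, and the month-later retention.
A single 11-observer correlation estimate is noisy — here r = 0.52 against a
population value near 0.8 — which is exactly the sampling behaviour the
replicate tests quantify. `examples/04_constancy.py` continues into the
cone-gain analysis, where the constancy of the first on-glasses setting
grows from ~68% on day 1 to ~73% on day 5 for the default cohort.

The other examples cover the color space and white-point anchor
(`01_color_space.py`) and the glasses/gamut model (`02_glasses_and_gamut.py`).
A thin CLI wraps the same functions:

```bash
chromadapt analyze --seed 3 --out run1     # simulate + full report bundle
chromadapt constancy --input run1/settings.csv
chromadapt gamut --glasses
```

## Layout

```
src/chromadapt/
  spectra.py        # Spectrum container, resampling, integration
  fundamentals.py   # packaged standard tables, cone-fundamental sets
  colorspace.py     # MacLeod-Boynton + scaled task space, hue geometry
  display.py        # monitor, glasses filter, rendering, gamut
  observer.py       # synthetic cohort generator, adjustment traces
  pipeline.py       # the statistics stages and full-report driver
  gain.py           # cone gain k = L/M and constancy fractions
  io.py, cli.py     # settings I/O, run config, pipeline runner, CLI
docs/methods.md     # model, assumptions, parameter choices, limitations
```
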
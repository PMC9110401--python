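# Methods

This note documents the generative model behind `swimquant`'s synthetic
data, the analysis definitions, the numerical choices that affect results,
and the limitations of both. Everything here describes what the code
computes; no empirical claim below goes beyond what the test suite and
`scripts/acceptance.py` actually calculate.

## 1. Locomotor generative model

### 1.1 Bout process

Each fish swims in discrete bouts. Within a 10-min integration bin the
bout count is Poisson with mean

```
E[count | bin] = λ_day · 10 min · f_light(bin) · h_fish
```

- `λ_day` (`Scenario.day_bout_rate`, bouts/min) is the *mean* daytime
  rate, so `λ_day × 10 min × mean displacement` is exactly the expected
  daytime distance per bin for an average fish.
- `h_fish` is a per-fish log-normal factor with mean 1 and CV
  `fish_rate_cv`, drawn once per fish and applied to every bin. It models
  stable between-animal differences and is what makes group SDs realistic
  rather than Poisson-thin.
- `f_light(bin)` depends on the light state of the bin.

**Light bins.** Activity declines across each light period. With decline
fraction `d = within_day_decline` and `frac` the bin midpoint's fractional
position in its light period,

```
f_light = 1 + d/2 − d · frac
```

This linear ramp is *mean-preserving*: it averages to 1 over the period,
so the calibration `λ_day × displacement = group mean distance` holds
regardless of `d`. (The alternative — anchoring the ramp at 1 in the
morning and `1 − d` in the evening — would silently shrink every daytime
mean by `d/2` and break the calibration.)

**Dark bins.** The baseline night factor is `night_rate_multiplier`
(default 0.1). A light→dark switch triggers a transient boost: the rate
factor starts at `dark_switch_boost` (default 3, i.e. 3× the day rate)
and decays exponentially toward the night level with time constant
`boost_decay_min` (default 5 min). The per-bin factor is the analytic
average of that exponential over the bin, so results are independent of
bin width. The boost is an *interpolation* between the startle level and
the night level, not a multiplier on the night level: multiplying
(3 × 0.1 = 0.3) could never produce a dark response exceeding the
preceding light activity, which is the defining feature of the
visuomotor assay. Setting `dark_switch_boost=0` disables the startle and
gives pure night suppression (with `night_rate_multiplier=0` this yields
exactly zero dark bouts).

### 1.2 Displacements and active duration

Per-bout displacement is log-normal with mean
`bout_displacement_mean_cm` and CV `bout_displacement_cv`; the log-space
parameters are solved exactly from (mean, CV). Bin distance is the sum of
that bin's bout displacements (vectorized via `np.add.reduceat`). Active
duration per bin is `count × bout_duration_s`; per-bin mean speed is
distance / active duration, so the generative mean speed is
`bout_displacement_mean_cm / bout_duration_s` (0.5 cm / 0.25 s = 2 cm/s
for the default 24-well wild type, comfortably in the "large movement"
class).

### 1.3 Light schedule

`make_light_schedule` is clock-driven: lights on 07:00, off 21:00
(14L:10D), recording starts 09:00 by default. Bins are half-open
`[start, start + bin_s)` and take the light state at their start. Days
are labelled `d1, n1, d2, …`; a 72-h session at 10-min bins has 432 bins,
with day 1 partial (acclimation) and days 2–3 complete (84 light bins
each). The visuomotor schedule is 180 min light, then 30/30/30/30 min
dark/light alternation, then three 10/10-min cycles — 360 one-min bins
with five light→dark transitions at 180, 240, 300, 320, 340 min and 90
dark minutes total.

### 1.4 Swim-pattern trajectories and trace images

Each (fish, bin) is assigned one of four pattern modes drawn from
`pattern_mode_probs` — `full-lap`, `partial`, `center-heavy`,
`quiescent` — and a parametrized trajectory is synthesized:

- **full-lap**: two complete perimeter laps (257 points) plus 3–4 brief
  center transits with a 4-point dwell (±0.1 × well radius). The transits
  guarantee the center square is never classified "low", so a group's
  full-lap probability is *negatively* coupled to its low-center fraction
  by construction.
- **partial**: a 2–6-square arc of the perimeter traversed three times;
  it can never light all 8 outer squares (max score 7).
- **center-heavy**: 60 points jittered ±0.12 × radius around the center;
  always scores "high" center.
- **quiescent**: a single point; minimal pixel mass everywhere.

`render_trace_image` draws the polyline with `skimage.draw.line` on a
`image_px × image_px` canvas (uint32 accumulator). Interior segment
endpoints are excluded to avoid double-counting shared vertices; the
final point is kept. The shipped default is **99 px**, chosen because
99 = 3 × 33 divides evenly into the 3 × 3 grid and because at this scale
the three classification thresholds (outer sum > 9, center < 100,
center > 550) separate the four modes cleanly: a full lap deposits far
more than 9 px in every outer square, the center transits deposit
150–400 center pixels (intermediate), and center-heavy dwells exceed
550. The thresholds are treated as fixed constants of the assay; the
image scale is the package's rendering choice made to match them.

### 1.5 Grid scoring

`grid_pixel_values` splits the image into a 3 × 3 grid, assigning
remainder rows/columns to the trailing squares. The perimeter score
counts outer squares with pixel sum **strictly greater than** 9 (0–8);
the center class is `low` (< 100), `high` (> 550), else `intermediate`.
Sums are exactly conserved: the nine square sums add up to the total
image sum (property-tested on 1000 random images).

## 2. Locomotor metrics

Per fish, over the selected period (default: `d2` and `d3` light bins;
day 1 is excluded as acclimation, day 4 is partial):

- **daytime distance** — mean `distance_cm` per 10-min bin;
- **daytime activity** — mean `bout_count` per bin;
- **mean speed** — Σ distance / Σ active duration (flagged undefined,
  with a logged warning, for fish with zero active time);
- **movement class** — speeds ≥ 0.5 cm/s are "large", below are "small"
  (boundary inclusive on "large").

Percent reduction is `100 × (1 − test/reference)`; for multiple
independent sessions, the per-session reductions of the group medians
are averaged unweighted. The visuomotor response ratio is the first dark
bin's distance divided by the mean of the three preceding light bins
(+ 1e-9 in the denominator to keep an all-zero pre-switch baseline
finite rather than raising).

## 3. Fluorescence and cell fields

- **ΔF/F₀** uses F₀ = the trace mean. With 1 Hz × 10 min traces and
  sparse transients the mean sits close to baseline; this estimator is
  simple, parameter-free, and identical for every trace length.
- **Transients** are maximal runs of ΔF/F₀ > threshold (default 0.2);
  runs separated by fewer than `min_gap_timepoints` (default 1)
  sub-threshold samples merge into one event. The counter is verified
  against a brute-force oracle on 1000 random series.
- **Relative level**: per-ROI mean raw fluorescence divided by the mean
  of the *region-matched control group*. Normalizing within region makes
  levels comparable across regions with different optical access, and
  makes the group fold change equal to the ratio of raw group means.
- **Cell fields**: cell count ~ Poisson(`mean_cell_count ×
  (1 − depletion_fraction)`); cells are non-overlapping disks placed by
  rejection sampling inside the ROI (hard 20 000-attempt limit; at the
  shipped density ≈ 30 disks of radius 3 px in a 100 × 100 ROI the
  packing fraction is ~1 %, so rejection is rare). `quantify_objects`
  counts 8-connected components (`scipy.ndimage.label`) or sums
  supra-threshold pixels in the half-open ROI. Because disks never
  overlap, area is proportional to count and a 90 % depletion produces a
  ~90 % area reduction.

## 4. Statistics

- **Two-group**: an F test for equal variances (two-sided, α = 0.05)
  gates between the pooled-variance t-test and Welch's t-test. Two
  identical constant samples return (t = 0, p = 1) instead of NaN.
- **Multi-group**: one-way ANOVA, Welch's heteroscedastic ANOVA
  (closed-form Welch 1951 statistic), or two-way type-II ANOVA via a
  `statsmodels` OLS fit of `value ~ C(factor_a) * C(factor_b)` (empty or
  singleton design cells are rejected). All pairwise two-group tests
  follow, Benjamini–Hochberg-adjusted as one family
  (`statsmodels.stats.multitest.multipletests`, `fdr_bh`). The omnibus
  result is returned first, unadjusted.
- Calibration is verified empirically in the test suite: the pooled
  t-test's type-I error over 1000 null replicates falls in the binomial
  99 % band around 0.05, and BH adjustment matches hand-computed step-up
  values on enumerated cases.

## 5. Shipped scenarios (defaults are the study conditions)

| Parameter | Default | Rationale |
|---|---|---|
| `bin_s` | 600 s | standard 10-min integration bins |
| lights on/off | 07:00 / 21:00 | 14L:10D cycle |
| `day_bout_rate` (24-well) | wt 7.12, mutant 3.10, rescued 7.34 /min | × 0.5 cm/bout reproduces daytime distances 35.6, 15.5, 36.7 cm/10 min |
| `day_bout_rate` (96-well) | sibling 6.0; mutant × 0.635; microglia-less × 0.86 | encodes 36.5 % and 14 % median-activity reductions |
| microglia-less displacement | 0.35/0.86 cm | rate down 14 %, displacement up 1/0.86 → distance unchanged |
| `bout_displacement_cv` | 0.5 | broad, right-skewed bout sizes |
| `bout_duration_s` | 0.25 s | gives 2 cm/s mean speed at 0.5 cm bouts |
| `night_rate_multiplier` | 0.1 | strong nocturnal suppression |
| `within_day_decline` | 0.3 | visible morning→evening ramp, mean-preserving |
| `fish_rate_cv` | 0.28 | chosen a priori so the wild-type group SD ≈ 9.9 at mean 35.6 (CV 0.28); fixed before any target was evaluated |
| `dark_switch_boost`, `boost_decay_min` | 3.0, 5 min | light-off startle ~3× day rate, minutes-scale decay |
| `pattern_mode_probs` | sibling (0.40, 0.35, 0.15, 0.10); mutant full-lap × 0.70 → (0.28, 0.47, …) | 30 % reduction in full-perimeter fraction, difference absorbed by `partial` |
| diencephalon baselines | 400 vs 100 a.u. | 4-fold genotype difference |
| tectum transient rates | 2 vs 3 per 10 min | modest hyperactivity of transients |
| morphant depletion | 0.9 | 90 % neutrophil depletion |

Well geometry defaults: 96-well 0.9 cm square; 24-well 1.55 cm circular.

## 6. Recovery targets and problem sizes

`swimquant.targets.TARGETS` defines eight end-to-end checks, each run at
a deliberately desk-scale size (the package's own choice, sized to finish
in well under a minute total):

| id | quantity | expected | tolerance | size |
|---|---|---|---|---|
| t4 | perimeter score of one full-lap image | 8 | exact | 1 image |
| t5 | median-activity reduction, mutant (96-well) | 36.5 % | ± 13.6 | 3 sessions × (24 + 12) fish |
| t6 | median-activity reduction, microglia-less | 14 % | ± 18.4 | 2 sessions × (24 + 24) fish |
| t7 | full-perimeter-fraction reduction (24-well) | 30 % | ± 4.0 | 3 sessions × 2 × 24 fish, every daytime bin imaged |
| t8 | mutant daytime distance | 15.5 cm/10 min | ± 1.6 | 3 × 24 fish |
| t9 | wild-type daytime distance | 35.6 cm/10 min | ± 3.6 | 3 × 24 fish |
| t10 | diencephalic fold change | 4.0 | ± 0.63 | 2 × 30 ROIs |
| t11 | neutrophil area reduction | 90 % | ± 4.1 | 2 × 20 images |

Tolerances are **three analytic Monte-Carlo standard errors** at those
sizes, derived a priori from the generative model (delta method on
medians/ratios with the log-normal between-fish CV), not tuned to any
observed run. Seeds for sub-experiments are derived deterministically as
`(seed × 100003 + offset) mod (2³¹ − 1)`; session seeds are
`seed, seed+1, seed+2`.

## 7. Resolutions of underdetermined analysis choices

- **Relative fluorescence level** is defined as raw ROI mean ÷
  region-matched control-group mean (not ΔF/F₀-based), because the
  quantity of interest is a *baseline* difference and ΔF/F₀ removes
  baseline by construction.
- **Intermediate center class**: center sums in (100, 550] are an
  explicit third class rather than forced into low/high; full-lap images
  land there by design.
- **Visuomotor response** uses the mean of the three pre-switch light
  bins as the reference and only the first dark bin as the response,
  which isolates the startle from the subsequent decay.

## 8. What the generator does and does not emulate

It emulates: integrated per-bin tracking records (count, distance,
active duration), trace images, light schedules, 1 Hz ROI fluorescence
traces with Poisson transients, and labelled-cell fields — i.e. every
input the analysis modules consume.

It does **not** emulate: continuous (sub-bin) kinematics, turning angles
or thigmotaxis dynamics beyond the four discrete pattern modes,
habituation across repeated light-off stimuli, circadian drift across
days beyond the fixed within-day ramp, optical artifacts
(bleaching, motion, background gradients) in fluorescence, or spatial
clustering of cells. Transient counts from the spike caller are exact on
the generator's clean traces; on real data the threshold and gap
parameters would need tuning.

## 9. Limitations

- Group-median reductions at small n are noisy: t6's 14 % effect is at
  the edge of Monte-Carlo resolution at the simulated size (its ± 18.4
  tolerance is honest about that), and t5 can land ~2 SE from 36.5 % at
  particular seeds without any bias — the estimator's unbiasedness, not
  any one draw, is the calibrated property.
- The F-test gate is itself a pretest; its known effect on downstream
  type-I error is accepted as part of the documented procedure rather
  than corrected for.
- The mean-based F₀ slightly overestimates baseline on transient-rich
  traces, shrinking ΔF/F₀ amplitudes; at the default transient rate the
  bias is small and identical across groups.
- Pattern-mode rendering is stylized; the guarantee tested is the
  mode→score mapping (full-lap ⇒ score 8, never-low center; partial ⇒
  < 8; center-heavy ⇒ high), not pixel-level realism.
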
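# Methods

This note documents the models, operational definitions and numerical
choices behind `escapekit`, the assumptions of the synthetic-session
generator, and the limitations of both.

## Coordinate conventions and stimuli

All behavioral quantities live on a 1-D *shelter-distance* axis d along the
80-cm arena: d = 0 at the shelter exit, d ∈ [−10, 0] inside the 10-cm-deep
shelter, the 30-cm threat zone at d ∈ [40, 70]. 2-D positions are cm with
the origin at the shelter-end corner. Head direction is the angle of the
head→nose vector: 0° facing the threat zone, ±180° facing the shelter,
wrapped to (−180°, 180°].

The looming stimulus is a train of three dark spots, each expanding
linearly at 55 °/s from 1° to 20.8° radius (0.36 s), held 0.25 s, with
0.5-s gaps — a 2.83-s train. Spot darkness is the negative Weber contrast
c = −(I − I_B)/I_B against the 9 cd·m⁻² background, so darker = larger c,
c ∈ (0, 1]. Full-field luminance steps use five log-spaced levels
{1, 3, 9, 27, 81} cd·m⁻², reported on the base-3 log axis
log₃(I / 9 cd·m⁻²) ∈ {−2 … +2}.

## Kinematics

Positions and head direction are smoothed with a 100-ms running average
*before* differentiation (speed = Euclidean frame-to-frame step over Δt;
angular velocity = minimal signed circular difference over Δt; first sample
duplicated to preserve length). The filter is centred with edge shrinkage;
a causal variant is available (`causal=True`) since the original filter's
phase is not documented anywhere we could pin it down. Heading is smoothed
on the unwrapped angle and re-wrapped so the running mean never averages
across the ±180° branch cut.

Tracking gaps (confidence < 0.9, configurable) are linearly interpolated up
to 200 ms; longer runs remain filled for continuity but are flagged
invalid, and any trial whose window touches an invalid stretch is dropped
rather than classified.

## Behavioral definitions

- **Eligibility**: at stimulus onset d ≥ 10 cm and |heading| < 60°.
- **Successful escape**: shelter reached (d < 0) within 5 s of onset *and*
  within 2.5 s of escape onset.
- **Escape onset**: the sample before the body rotation that launches the
  run home. Operationally: among episodes of |angular velocity| > 100 °/s
  between stimulus onset (or, for spontaneous escapes, a 10-s look-back)
  and shelter arrival, keep those that are *sustained* — net heading change
  ≥ 30° — and *linked* to the arrival (no stop of > 0.5 s at < 2 cm/s in
  between), and take the **last** such episode. Net-turn gating rejects
  jitter around a fixed heading (brief super-threshold samples with ~0 net
  rotation, ubiquitous under keypoint noise); taking the last linked
  episode attributes the onset to the turn of the escape itself rather
  than to an earlier orienting turn the animal happened not to rest after.
- **Spontaneous escape**: the same fast-return criteria on a shelter
  return with no loom or sound in the preceding 10 s; the probability
  denominator is threat-zone entries (1-cm hysteresis debounce) that did
  not trigger a stimulus — evoked and spontaneous probabilities are
  computed on disjoint event sets.
- **Non-escape return**: stimulus-free shelter return with peak speed
  ≤ 40 cm/s in the final 2 s.
- **Freezing**: complete absence of motion for ≥ 2 s during the stimulus.
  The motion floor is 1 cm/s (configurable; `method="speed"` applies the
  literal instantaneous-speed rule). The default `method="displacement"`
  tests the equivalent condition on net movement — some 2-s window in
  which the animal never strays more than floor × 2 s = 2 cm from the
  window's start. For a genuinely motionless animal the two are identical;
  the displacement form is insensitive to keypoint noise, which inflates
  instantaneous speed estimates by several cm/s at 0.3-cm jitter.
- **Fast rotations**: ≥ 250 °/s sustained ≥ 100 ms, evaluated as a net
  heading change ≥ 25° over a sliding 100-ms window (exactly equivalent
  for an idealized monotone turn, and robust to the smoothing filter
  shortening super-threshold runs at episode edges). **Running bouts**:
  movement episodes with peak speed ≥ 35 cm/s. Both are escape-tagged when
  the shelter is reached < 2.5 s after event onset.
- **Laser timing**: cumulative |heading change| between loom onset and
  laser onset < 30° → before escape initiation; > 60° → after; the 30–60°
  gap is left unclassified rather than forced; trials < 10 cm from the
  shelter at laser onset are excluded.
- **Experience phases**: naive until the first stimulus, experienced
  after it, habituating once the habituation protocol starts, habituated
  after three consecutive non-escapes at intermediate contrast (50–60 %;
  85 dB for sound sessions).
- **Peak escape speed**: max speed in the 3.75-s window from stimulus
  onset. **Displacement after loom** (non-escape trials): path length from
  0.5 s after onset to stimulus end.

The psychometric is a single trial-level logistic fit of escape outcome on
contrast in %, mice pooled; per-mouse fits are available alongside.
Complete separation is detected (all-or-none outcome at every level, or a
divergent fit) and reported as a saturated fit with the empirical
per-contrast fractions attached. Confidence bands come from the delta
method on the linear predictor.

## Photometry

Pipeline order is fixed and pinned by tests: (1) 10-min centred
running-median detrend of both channels (median of a monotone drift equals
its central value, so slow bleaching is removed while 1-s transients pass
nearly untouched; sessions shorter than the window fall back to a global
median, flagged); (2) OLS fit (with intercept) of the detrended isosbestic
trace to the detrended calcium trace, subtracted — the isosbestic channel
carries the calcium-independent components (motion of the patch cord,
residual bleaching), so subtracting its fitted projection removes what the
two channels share; (3) session z-score; (4) linear interpolation onto the
50-Hz camera frames. The output is invariant (to numerical precision) to
adding any multiple of the isosbestic trace to the calcium trace.

ON/OFF responses are 1-s post-minus-pre window means at stimulus onset and
offset; trials with truncated margins are dropped. Event-aligned averages
aggregate trial→mouse→group in that order. Distance-binned activity uses
the 30 s before each threat-zone entry, 5-cm bins plus one aggregate
shelter bin (d < 0). Covariate regressions are per-covariate OLS of
epoch-averaged activity.

## Spike-train quantification

Rates are causal 50-ms box-filter counts on a 50-Hz grid. A unit is
**loom-responsive** if its trial-averaged rate after 99 %-contrast no-laser
looms exceeds baseline mean + 2 × baseline SD continuously for ≥ 200 ms
within the first 500 ms (baseline = the 500 ms pre-onset; the SD is taken
across time bins of the trial-averaged rate — the across-trial alternative
is a config switch). Sound responses are one-sided above baseline;
grating and blank-laser responses are two-sided. Units are classed
visual / non-visual and visual-only / sound-only from these calls.

Population contrast curves average all unit types over the 3-s post-onset
window and normalize to the 99 %-contrast no-laser response; population
suppression is 1 − rate_laser/rate_control at 99 % contrast, positive when
stimulation reduces spiking, split by layer (depth boundaries: superficial
< 400 µm, intermediate 400–1100 µm, deep > 1100 µm from the collicular
surface — histology is unavailable to this pipeline, so depth stands in,
configurable). Per-unit spontaneous suppression uses blank-laser trials:
1 − ⟨rate in first 1.5 s of laser⟩ / ⟨rate in 500 ms pre⟩, with both rates
averaged across trials *before* the ratio — a per-trial ratio whose
denominator is a handful of baseline spikes is unstable and biased by
E[1/N] > 1/E[N], while the ratio of averages estimates the same relative
change without that bias. Units enter this analysis only if single,
in intermediate/deep layers, with ≥ 5 Hz spontaneous rate (inter-trial
intervals serve as the spontaneous epochs).

## Slice conductance

Evoked synaptic currents follow I = g (V_m − E_rev); a least-squares line
through peak current vs holding potential gives g (slope; pA/mV ≡ nS) and
E_rev (zero crossing). Cells whose I–V is degenerate (one potential, or
slope ≈ 0 making the reversal unidentifiable) fall back to the mean
reversal of the successfully fitted cells: g = mean over potentials of
I(V)/(V − E_shared), skipping potentials at the shared reversal. The
connectivity call operationalizes "consistent response with short,
reliable latency" as: evoked peak > 3 baseline SDs in ≥ 80 % of ≥ 5
trials, latency SD < 2 ms, mean latency < 15 ms (all configurable — no
published numbers exist for this rule). Conductance is summarized per
mouse by median with IQR; connection probability per mouse as the
connected fraction with cross-mouse mean/SEM; conductance vs layer by OLS
on the ordinal layer code.

## Statistics policy

Repeated trials are averaged within animal first; animals are the units of
analysis. The Shapiro–Wilk gate (α = 0.05) tests each group separately for
unpaired/multi-group designs and the difference vector for paired designs;
any rejection, n < 3, or a constant sample selects the non-parametric
branch. The selection table is fixed: paired t / Wilcoxon signed-rank
(paired), independent t / rank-sum (two unpaired groups), repeated-measures
one-way ANOVA + Tukey / Kruskal–Wallis + Dunn (repeated measures). For > 2
independent non-repeated groups no parametric post hoc is named in the
source material; one-way ANOVA + Tukey is assumed by symmetry. Display
summaries match the gate: mean ± SEM or median ± IQR (type-7 linear
interpolation quantiles). All tests are two-tailed; the statistics
themselves are delegated to scipy/statsmodels.

## The synthetic-session generator

The generator's role is to emulate the statistical structure each analysis
assumes, with exact ground truth — not biophysical realism.

- **Locomotion**: alternating shelter rests (exponential durations) and
  excursions to the threat zone at bout speeds ~N(12, 2) cm/s with a small
  transverse wiggle; smooth in-place turns (300–480 °/s) join segments.
  Escapes execute the species-typical sequence: reaction delay
  (0.25–0.45 s), turn to the shelter at 480 °/s (well above the 100 °/s
  detection threshold) with a slow drift, then a straight 55-cm/s run.
  Looms trigger on 35 % of eligible threat-zone entries with ≥ 120-s
  inter-stimulus intervals; escape outcomes are Bernoulli draws from the
  logistic p(c) with β₀ = −2, β₁ = 0.05 per contrast-% (p(40 %) = 0.5,
  p(99 %) ≈ 0.95); contrasts {20, 40, 60, 99} %. Spontaneous escapes occur
  on 10 % of unstimulated approaches; 10 % of evoked non-escapes freeze
  for 2.4 s.
- **Scripted boundary battery**: a separate generator scripts single
  trials on grids spanning the decision boundaries (start distances
  5–70 cm, headings 0–180°, arrivals ~1.8–6.5 s, long-run and ineligible
  variants, freezes, spontaneous escapes, slow returns). Grid values keep
  deliberate margins from the thresholds (≥ 0.8 cm from 10 cm, ≥ 11° from
  60°, ≥ 0.12 s from 2.5/5 s) so that labels stay well defined under the
  0.3-cm keypoint-noise condition; the boundaries are still bracketed
  from both sides.
- **Photometry**: f_ca = bleach(t)·(baseline + clean + g_ca·artifact) + ε,
  f_iso = bleach(t)·(baseline + g_iso·artifact) + ε, with a single-
  exponential bleach (τ = 2000 s; the detrend removes any slow trend
  regardless of form), a Gaussian-smoothed shared artifact, and
  clean = calcium kernel (0.1-s rise, 1-s decay) ⊛ state drivers (shelter
  indicator, distance term, escape-onset and luminance impulses).
- **Spikes**: piecewise-constant intensities per unit (baseline 6–20 Hz;
  loom gain × contrast over the 3-s window for visual classes; sound gain
  for auditory classes), sampled exactly per segment (Poisson counts +
  uniform times). Laser multiplies visual-class intensity by (1 − s)
  while on; s = 0.3 by default. The head-fixed schedule mirrors the
  recording protocol: blocks of 8 looms (4 contrasts × laser on/off,
  shuffled within block) repeated 25 times, plus sound and blank-laser
  trials.
- **I–V**: I = g(V − E_rev) + ε at potentials between −90 and −40 mV.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: pose-estimation failure modes beyond i.i.d.
Gaussian jitter and uniform dropouts, curved or hesitant escape
trajectories, bursty or adapting spike trains, hemodynamic or spectral
artifacts in photometry, and series-resistance errors in voltage clamp.

## Problem sizes and determinism

All simulations are deterministic given their seed. The analysis drivers
use a 30-min behavioral session, 20 units × 240 head-fixed trials, and 12
voltage-clamped cells; the acceptance benchmarks use 200 scripted trials,
20 psychometric seeds (10 mice × 40 trials), 20 suppression seeds
(20 units × 25 trials/condition), 50 calibration seeds (800 stationary
units per implementation), 50 conductance seeds, and 500 normality-gate
seeds — sizes at which every recovery bound holds with margin while the
full suite runs in well under a minute.

## Known limitations

- The escape-onset linkage rule (net-turn ≥ 30°, stop ≤ 0.5 s, last
  episode) is one reasonable operationalization of an under-specified
  definition; alternatives (first linked episode, different net-turn
  floors) are a parameter away but change onset times on real, meandering
  trajectories more than on scripted ones.
- The loom-responsiveness rule's false-positive rate at these settings is
  ≈ 0; the calibration against the brute-force oracle therefore checks
  agreement of two implementations in a conservative regime rather than a
  non-trivial rate.
- Layer assignment from depth is a proxy for histological assignment.
- The isosbestic correction assumes the artifact enters both channels
  linearly and time-lock free; wavelength-dependent artifact dynamics
  would violate it.
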
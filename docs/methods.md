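# Methods

## The closed-loop detection algorithm

The apparatus this package models is a two-choice fly feeding arena in
which each food source sits on a capacitive sensor. A proboscis–food
contact ("sip") raises the sensor signal by hundreds of counts for tens
of milliseconds. The control loop runs a running-minimum filter: at every
sample it computes the minimum of the signal over the most recent 100 ms
and compares the current sample against it. When

    current − min(last 100 ms) > threshold        (threshold = 100 counts)

the sample is a rising edge and the stimulation LED is commanded on (or
held on). The LED command is exactly the truth value of this condition at
each sample — there is no separate off-detector. Both published turn-off
behaviours then emerge from the same inequality:

* **Falling edge.** When the signal returns toward baseline, the current
  sample falls to within the threshold of the window minimum and the
  condition fails at that first sample.
* **Plateau.** When the signal stops rising and stays constant, the
  window minimum climbs to the plateau value as old samples age out; one
  full window (100 ms) after the last strict increase, the difference is
  zero and the LED is off. Measured on a step input, the LED goes dark
  exactly when the plateau has lasted one full window.

Whichever occurs sooner wins, since both act through the same per-sample
condition. We adopt this *emergent* reading rather than implementing a
separate plateau timer: with the window equal to the plateau timeout
(both 100 ms) the two are behaviourally indistinguishable, and the
single-condition form is the simplest machine consistent with the
published description. The window at sample *t* covers the W most recent
samples *including t* (indices (t−W, t]); the inequality is strict
("greater than a threshold").

Two implementations are provided and tested for bitwise equality:

* **Streaming** (`SipDetector.step`): a monotonic deque holding at most
  W (index, value) pairs; amortised O(1) per sample, decision emitted
  before the next sample is consumed, memory bounded by the window. This
  is the desk-testable analogue of the real-time hardware loop.
* **Batch** (`detect`): an O(n) vectorised block prefix/suffix-minima
  decomposition of the trailing-window minimum (each window of length W
  spans at most two adjacent W-blocks, so the minimum is the cheaper of
  two precomputed cumulative minima).

Both are checked elementwise against a brute-force per-window minimum on
random traces.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `threshold` | 100 | counts | published value, "set to exceed noise" |
| `window` | 0.100 | s | published running-minimum window |
| `sample_period` | 0.010 | s | the capacitance front-end rate is not published; 100 Hz makes the window exactly 10 samples and resolves 20 ms sip edges. Configurable. |

All durations are converted to whole samples by round-half-even
(`to_samples`), the single conversion used package-wide.

## The simulator

`simulate_session` emulates what the sensors would record, with exact
ground truth for benchmarking the detector:

* **Baseline**: constant level (default 1000 counts) plus a slow sinusoid
  (default amplitude 50 counts, period 600 s, random phase per channel)
  emulating thermal/humidity drift. At these defaults drift changes by
  well under 1 count per 100 ms window, so it cannot trigger the
  detector.
* **Noise**: white Gaussian, SD 10 counts, rounded to integers — an
  order of magnitude below the threshold, honouring the published design
  that the threshold exceeds noise. The windowed range of a noise-only
  signal stays far below 100 counts, so sip-free stretches produce no
  events.
* **Sips**: trapezoidal pulses, default amplitude 500 counts, 20 ms
  rise, 60 ms hold, 20 ms fall. The published description gives no
  waveform beyond "the signal rises during a sip"; the trapezoid is the
  simplest shape with distinct rising edge, plateau and falling edge, and
  ~100 ms is a realistic sip duration for this kind of monitor. Gaps
  between sips are gamma distributed with mean 1/rate; the `burstiness`
  dispersion parameter (shape = 1/burstiness) reduces to a Poisson
  process at 1 (the default) and produces feeding bursts above 1.
  Overlapping pulses are summed and their ground-truth intervals merged,
  with a logged warning.
* **Session length**: 3600 s, the published experiment duration. Default
  per-channel sip rate 0.05 /s gives ~180 sips per channel per hour —
  comfortably above the 15-sip inclusion minimum, as in a feeding fly.

Cohorts (`simulate_cohort`) derive one seed per fly from the cohort seed
via `SeedSequence([cohort_seed, fly_index])`, so any fly is reproducible
in isolation; each fly's session is simulated, detected, classified and
flagged for inclusion. Raw traces are not retained on the cohort objects
(an hour of two-channel data per fly); planted ground truth is.

What the simulator does **not** emulate: the biophysics of
proboscis–electrode coupling, non-Gaussian sensor artefacts, grooming or
walking contacts that real arenas register, channel crosstalk, and any
dependence of feeding on the LED (the loop is open in simulation —
pulses are planted independently of the stimulation state). Passing the
recovery benchmarks therefore shows the algorithm is implemented
correctly, not that real signals are this clean.

## Feeding analytics

Detected events are classified as sips by duration bounds, default
[0.02 s, 5 s]. The hardware's upstream sip-vs-other-interaction
classifier is from earlier work on the monitor and is not described in
the source for this package, so a transparent stand-in is used; the
bounds are configurable and the default trapezoid produces ~90 ms events
well inside them.

Per fly, the preference index is PI = (sips₁ − sips₂)/(sips₁ + sips₂),
undefined (NaN, not 0) when both counts are zero. Inclusion requires at
least 15 total sips — summed over both channels, the weaker reading of
the published rule (which does not say per-channel); a fly with exactly
15 is included. Cohort summaries report mean ± SEM (sample SD/√n) over
included flies only, with excluded flies retained in the table and their
reason logged. No inferential statistics are computed.

With per-channel Poisson sip counts at rates λ₁, λ₂, the expected per-fly
PI approaches (λ₁−λ₂)/(λ₁+λ₂) for large counts; cohort recovery tests
check the detected-sip PI against this closed form within Monte-Carlo
error (3 SE).

## Dye choice and PER

Dye two-choice groups are scored as PI = (n Food-1-coloured − n
Food-2-coloured)/(n fed). Flies labelled with both dyes fed, so they
enter the denominator but favour neither food — the literal reading of
the published formula, which defines the denominator as all flies that
fed; how dual-coloured abdomens were scored is not stated, so this is a
package decision. Dye-swapped replicate groups are computed in
Food 1/Food 2 space regardless of orientation, with the orientation
retained so a symmetric dye bias demonstrably cancels in the pooled mean.

PER is summarised per fly as extensions over presentations (default 3
presentations per stimulus) and aggregated as mean ± SEM across flies.

## ΔF/F quantification

ΔF/F = (peak − baseline)/baseline, where baseline is the mean of the 10
frames immediately preceding stimulus onset and peak is the maximum
3-frame rolling mean over the stimulus-and-post window (windows lie
entirely at/after onset; ties break toward the earliest window, whose
centre index is reported). The published definition fixes the point
counts (10 and 3) but not the window placement; the rolling-mean /
immediately-pre-stimulus reading is the conventional one and both counts
are configurable. The statistic is invariant to positive rescaling and —
deliberately not — to additive offsets, so traces must be background-free.

The simulated transient is F(t) = f₀(1 + ΔF/F_true · k(t)) + noise on
the 5 s baseline / 1 s stimulus / 9 s post timeline, where k is a
difference-of-exponentials kernel (defaults: rise τ 0.2 s, decay τ 2 s,
matching fast indicator kinetics) normalised to a continuous-time peak
of 1. The frame period defaults to 0.1 s, the order of a confocal frame
scan at the published line settings. Because the rolling-3 mean averages
samples off the kernel peak, the noiseless estimate slightly
underestimates the true amplitude (≈1% at defaults; asserted < 5%);
with noise, taking the maximum of noisy window means adds a non-negative
bias relative to that noiseless estimate (max-of-means effect), which
tests assert rather than hide.

## Numerical and design choices

* Sensor values are integers (capacitance-to-digital counts); thresholds
  compare in integer counts. Fractional trace inputs are rejected.
* `to_samples` snaps the duration/period ratio to 9 decimals before
  rounding half-even, so ratios that are exact halves in real arithmetic
  are not mis-rounded by floating-point representation.
* Empty traces yield empty timelines and event lists; an all-excluded
  cohort yields an NaN mean non-fatally; a zero-fed dye group and a
  zero-sip fly yield NaN indices.
* Trace/event/LED/cohort files are plain CSV/TSV; parsers reject ragged
  rows, non-uniform sampling (tolerance 1 ns) and inverted event
  intervals, naming the offending row. Every CLI run writes a JSON
  manifest (resolved config, seed, package version, SHA-256 of inputs and
  outputs) sufficient to replay it.

## Problem sizes used in verification

Oracle-equivalence checks use 100 random traces of 10⁵ samples;
streaming/batch identity 100 random traces; planted-event recovery 50
default hour-long sessions (and 20 in the reproduction script, which
reports the n it used); preference recovery two 50-fly cohorts of
hour-long sessions; count calibration 200 seeds of 300 s sessions; noisy
ΔF/F recovery 200 traces.

## Known limitations

* The sip classifier is a duration filter, not the published monitor's
  feature-based classifier; absolute sip counts on real data would
  differ, though the PI is robust to symmetric misclassification.
* The simulator's open-loop planting cannot express LED-dependent
  feedback on feeding (the very effect the apparatus exists to create);
  it benchmarks detection, not behaviour.
* Hardware concerns — converter configuration, serial protocols,
  real-time guarantees beyond the per-sample contract — are out of scope.
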
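# Methods

## Kinematic definitions

A recording is a sequence of n frames, each a timestamp plus 3D positions
(meters, right-handed camera frame) of up to 20 named skeleton joints; the
four arm joints of the dominant side (shoulder, elbow, wrist, hand) must be
present. Instantaneous velocity of a joint is the per-frame displacement
norm divided by the sampling interval; the series has length n−1, sample k
belonging to frame k+1. Acceleration is the first difference of the
(optionally filtered) velocity divided by the same interval, length n−2.

Two timing modes exist because depth cameras advertise 30 Hz but deliver
jittered intervals (we model mean 0.0334 s, SD 0.0037 s, which implies an
effective rate fluctuating between 26.95 and 33.67 Hz):

* `nominal` (default): T = 1/30 s for every step — the definition used when
  only the advertised rate is known, and the one all headline numbers use;
* `measured`: each displacement is divided by its own recorded timestamp
  difference, compensating jitter at the cost of amplifying timestamp noise.

`timing_summary` reports population (1/N) moments of the intervals, the
same convention as a Gaussian fit to an interval histogram; `fs_max` is
undefined (None) when the interval SD reaches the mean.

## Zero-phase low-pass filter

Arm-raise content lies below 6 Hz; sensor noise is broadband and is further
high-passed by the differencing that produces velocity. We therefore smooth
velocity with a first-order zero-phase low-pass Butterworth, cutoff 6 Hz.
Forward–backward application of a first-order Butterworth has zero net
phase and squared-magnitude response |H(f)|² = 1/(1 + (f/f_c)²). The
default implementation realizes exactly that response: the series is
padded by odd (point-symmetric) reflection at both ends — the padding that
minimizes edge transients on short motions — multiplied by |H|² in the
frequency domain, and trimmed. At a 30 Hz frame rate this matters: a
bilinear-transform IIR run forward and backward (`method="filtfilt"`,
scipy, odd padding of length 3·(order+1)) sags below the Butterworth
magnitude as f approaches Nyquist (gain 0.15 instead of 0.26 at 10 Hz),
because the bilinear warp compresses high frequencies. Both methods agree
in the passband (gain 0.83 vs 0.80 at 3 Hz); the exact-magnitude form is
the default because its response is the one the first-order bidirectional
design specifies, and it keeps the filter's behavior analytically
predictable on the short series typical here. First order is deliberate:
higher orders over-smooth motions of a few dozen frames.

Power spectra use a single-taper (boxcar) periodogram with the mean
removed, so the integral of the one-sided density equals the series
variance; motions are tens of frames long, leaving no room for segment
averaging.

## Features

f1/f2 are the mean and population (1/N) SD of the velocity series; f3/f4
the same moments of the acceleration series. N is the velocity-series
length for f1/f2 and the acceleration-series length for f3/f4. Population
rather than sample SD is part of the feature definition, not an estimator
choice, and is kept exactly.

Partial-motion variants slice the *frames*: a prefix keeps the first
⌊fraction·n⌋ frames; a window keeps frames [⌊a·n⌋, ⌊b·n⌋) with the ten
canonical windows [0,0.1), …, [0.9,1.0]. Floor indexing with half-open
intervals is deterministic and reproducible. By default the whole velocity
series is filtered once and then sliced, so slices carry no extra filter
edge transients; `refilter=True` filters each slice independently for
comparison. A slice must contain at least 2 velocity samples (3 frames) so
that both f1 and f2 are defined; this floor is set by physics — a fast arm
raise whose mean hand speed exceeds 1.5 m/s lasts about a second, i.e.
~30–40 frames at 30 Hz, so a 10% window simply cannot be required to hold
more. Windows of 3 frames leave a single acceleration sample; f3/f4 are
then NaN and any analysis requesting them reports the slice unavailable.

## Classification

Two thresholds on one feature: value ≤ THR1 → slow; ≤ THR2 → normal; else
fast. Ties go to the slower class — deterministic and conservative toward
detecting slowness, the clinically relevant direction.

* **Interclass (pooled) fitting**: Gaussian-kernel density (Silverman
  bandwidth) of all training values on a 512-point grid spanning the data
  range; THR1 is the density argmin strictly between the slow and normal
  class means, THR2 between normal and fast — the two valleys of the
  pooled distribution. If a search interval has no interior minimum the
  midpoint rule substitutes for that boundary.
* **Midpoint rule**: midpoint between the lower class's maximum and the
  upper class's minimum.
* **Intraclass fitting**: per-subject midpoint thresholds (a KDE valley is
  ill-posed on ~5 values per class), averaged componentwise.

Fitting requires every class present with ≥ 2 values and class means
ordered slow < normal < fast; otherwise the training set admits no
monotone decision rule and fitting errors out.

Leave-one-subject-out validation refits thresholds for every held-out
subject and reports per-fold thresholds and error plus the pooled overall
error (misclassified / total motions; the mean of per-fold rates is also
reported — the two coincide for equal fold sizes). The overall error is
invariant to subject ordering and to positive rescaling of the feature.

**Degenerate folds.** Some features carry no monotone speed information by
construction — the mean acceleration f3 of a rest-to-rest movement is ~0
for every class — and their training folds cannot be ordered. By default
this raises; with `on_degenerate="chance"` the fold predicts the central
class for every motion (66.7% error on balanced data), which is how the
joint/feature comparison tables report such features, and how the partial-
motion analysis keeps the uninformative edge windows (the stationary holds)
visible as high-error points instead of missing rows.

Class separation is checked with one-way ANOVA and Kruskal–Wallis;
all-identical input degenerates both and returns NaN p-values with an
explicit warning.

## Synthetic cohorts

The generator emulates the benchmark acquisition: 27 subjects × 5
repetitions × 3 instructed speeds (405 recordings), arm length drawn from
Normal(0.713, 0.052) m truncated to (0.5, 0.9), ~2 in 27 subjects
left-handed, a camera 2.7 m away. The dominant arm is a rigid chain —
upper arm 0.55·L, forearm 0.45·L, hand point 0.10 m beyond the wrist —
rotating about the shoulder through Δθ = 135° along the minimum-jerk
profile 10τ³ − 15τ⁴ + 6τ⁵, the standard model of voluntary point-to-point
reaching. The shoulder point itself elevates 0.08 m over the raise
(scapular elevation, which any skeleton tracker reflects); set
`shoulder_sway=0` for a strictly fixed pivot. The other 16 joints are
static points. Per-frame i.i.d. Gaussian position noise (SD 3 mm per axis)
models sensor error; timestamps are cumulative truncated-Gaussian intervals
(mean 0.0334 s, SD 0.0037 s, floor 5 ms).

Movement duration is derived, not tuned: D = hand path length / target
speed, with class targets 0.35 / 1.0 / 2.0 m/s (times a per-subject
multiplier, Normal(1, 0.08)) chosen so the measured class means straddle
the canonical decision boundaries 0.58 and 1.50 m/s. Each recording frames
the movement with 0.10 s stationary holds (reaction to the start signal;
holding the arm up until the stop signal) and is padded to at least 34
frames so every canonical 10% window holds ≥ 3 frames. The holds dilute
the whole-recording mean: measured class means are ≈ 0.42 / 0.98 / 1.7 m/s
(the ground-truth record keeps the movement-phase target). Intraclass
thresholds fitted on default cohorts land near 0.70 and 1.35.

What the generator does **not** emulate: tremor or pathological movement,
elbow flexion (the arm stays straight), occlusion and tracking dropouts,
correlated or joint-dependent sensor noise, postural sway of the torso,
and annotator disagreement (both synthetic annotators label the true
class, so no recording is discarded). Passing tests therefore demonstrate
that the pipeline recovers what this idealized model encodes — ordered,
well-separated class speeds under realistic noise and jitter — not that
real patient data would separate equally well; with these speed gaps
(≈ 7–10× the within-class spread) the LOO error is 0%, far below the
error rates expected on real recordings.

## Numerical choices and degenerate inputs

* Velocity series length n−1, acceleration n−2; slices use floor/half-open
  frame indexing (above).
* Filter requires ≥ 3·(order+1) samples and 0 < cutoff < Nyquist.
* KDE valley grid: 512 points over the pooled range; the valley position
  agrees with an exhaustive fine-grid scan to within the grid resolution.
* Unfiltered velocity is non-negative by construction and validated as
  such; filtered series may undershoot slightly.
* CSV round-trips write 17 significant digits; read∘write reproduces
  timestamps and positions to ≤ 1e-9 relative error.
* All randomness flows from explicit integer seeds (`numpy` Generator);
  identical seeds reproduce recordings bit for bit.

## Problem sizes used by the acceptance script

Worked kinematic examples run on 3-frame recordings; filter gains on 12 s
tones at 30 Hz; the pipeline quantities on one default 405-recording
cohort; threshold recovery on 20 seeded default cohorts; null calibration
of the separation tests on 1000 replicates of 3 × 50 values. These sizes
give stable statistics (binomial SE ≈ 0.7 percentage points on the type-I
rates) while keeping a full run to seconds.
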
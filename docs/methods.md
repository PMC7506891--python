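# Methods

## Problem and signal model

Facial muscle contractions emit low-frequency sound (acoustic
mechanomyography, A-MMG): vibrations in the 2–200 Hz band with most of
the power below 50 Hz. Six stethoscope-microphones placed at
glasses-frame positions (temples, eyebrows, cheeks) record these
sounds through 12-bit ADCs at 200 Hz with a DC bias at mid-scale
(2048 counts at VCC = 3.3 V, one LSB ≈ 0.805 mV, dynamic range
20·log10(2¹²) ≈ 72 dB).

Single microphones are omnidirectional and pick up room noise. A
first-order differential microphone array (DMA) subtracts two
microphone outputs: sound arriving broadside to the pair axis reaches
both elements in phase and cancels (end-fire dipole), and any
common-mode component — ambient noise in particular — is removed. The
dipole's frequency response peaks at the tuning frequency
f = V/(2d) for element spacing d and sound speed V = 343 m/s; with
facial spacings of 5–12 cm the tuning frequencies (3.4 kHz down to
1.4 kHz) lie far above the A-MMG band, so the arrays operate on the
rising low-frequency slope. Adding an inter-element delay T = d/V
turns the dipole into a cardioid; at a sampling period Ts the delay is
realised as N = round(T/Ts) whole samples, the realised delay implies
a null at 1/(2T) and a usable capture band up to half of that. The
plane-wave directivity formulas assume the source is beyond the
Fraunhofer distance 2W²/λ; on-face sources violate this, so the
package exposes the criterion for callers to flag near-field queries
but does not model spherical wavefronts.

## Calibration

Hand-built stethoscope heads have unequal gains. Each microphone is
swept with discrete square-wave tones
(21…101, 501…1251, 1501…2501 Hz), 20 s per tone in the hardware
procedure; the peak-to-peak ADC response A = V·G per tone is
aggregated into min/max/mean per spectral band — Area1 (21–751 Hz,
where muscle sound lives), Area2 (1001–1751 Hz), Area3 (2001–2501 Hz).
The first 10% of each tone segment is discarded as a settling guard
(square-wave onset transients); the statistic is the whole-segment
max − min after the guard. A matching factor MF = A_y/A_x (by default
the max statistic over Area1; min/mean/unity are selectable) rescales
the first channel before subtraction:

    caldma = MF · Mx − My

Each channel's sample mean is removed before differencing so the MF
scaling does not shift the mid-scale DC bias — the differencing model
presumes zero-mean sound signals. Eleven pairs are formed from the six
sites: three horizontal (temple–temple, eyebrow–eyebrow, cheek–cheek),
four temple×cheek, four eyebrow×cheek; temple–eyebrow pairs are too
close to be useful and are never formed. Reduced configurations use
the six pairs among the temples+cheeks or eyebrows+cheeks sites.
Within a pair the minuend is the site listed first in canonical order
(left before right, temple/eyebrow before cheek).

## Synthetic session generator

The real recordings (8 subjects × 3 sessions × 11 classes ×
10 repetitions = 2640 events) were never deposited, so the package
generates synthetic sessions with the statistical structure the
analysis assumes. Each of the 11 gesture classes (happy, angry,
surprise, sad, upset, disgust, kiss, blink, tongue-out, take-pill,
neutral) is an activation vector over 8 muscle source regions
(frontalis, orbicularis oculi, zygomaticus — each left/right —
orbicularis oris, masseter). Per event:

* each active region emits band-limited Gaussian noise (Butterworth
  band-pass 2–45 Hz at fs = 200 Hz, so ≥ 70% of power lies below
  50 Hz) under a trapezoidal start–hold–release envelope that is zero
  at both ends; event duration is uniform on 2–3 s;
* propagation to each microphone follows 1/(1 + dist/λ) with
  attenuation length λ = 3 cm over face-plane coordinates chosen so
  pair spacings fall in the hardware's 4–13 cm range;
* channels share common-mode ambient noise (default amplitude 20% of
  the source scale, no envelope) and carry independent sensor noise
  (sd 2 counts); each channel is scaled by a per-subject microphone
  gain (drawn uniformly from 0.5–1.8, spread ≤ ×3.6, within the
  observed ×4 hardware bound) times a per-session drift (sd 5%);
* sensors are re-placed each session: per-site positional jitter
  (sd 0.5 cm) and the gain drift are resampled per session;
* per-subject physiology: a global expressiveness scale (sd 0.2) and
  a relative (multiplicative) perturbation of the activation vectors
  (sd 5%) — relative, so silent regions stay silent and the neutral
  class remains a residual tone (activation 0.01);
* samples are biased to 2048, clipped to [0, 4095] and rounded.

Randomness uses a splittable counter scheme: every event stream is
seeded by (global seed, subject, session, event index), so any subset
of the protocol is reproducible in isolation.

Synthetic calibration sweeps run the same square-wave/peak-to-peak
path as the hardware procedure against each session's effective gains,
with a stylised response shape that is flat within each spectral band;
1 s per tone at fs = 4 kHz suffices because the peak-to-peak of a
deterministic square wave is duration-invariant.

Three presets control difficulty. `paper-like` (the default) uses
face-valid activation patterns in which sad, upset and disgust are
deliberately close (their pairwise L1 distances, 0.35–0.5, are the
three smallest among all class pairs) — these overlapping brow/mouth
patterns emulate the weak-class structure of the real data.
`separable` keeps each class's primary region but assigns secondary
activations chosen once by maximising the minimum pairwise distance
between the classes' expected DMA-channel energy signatures under the
propagation model, with low noise, drift and jitter; it is the
solvable control condition. `hard` adds heavy subject heterogeneity
(expressiveness sd 0.5, jitter 0.8 cm). What the generator does not
emulate: biomechanically realistic muscle acoustics, within-event
non-stationarity beyond the envelope, correlated multi-muscle timing
(e.g. the chew–swallow sequence of taking a pill), room reverberation,
or motion artefacts. Passing tests therefore demonstrate that the
pipeline recovers spatial activation patterns from calibrated
differential channels under realistic gain/placement/noise
perturbations — not that real-data accuracies are reproduced.

## Feature catalogue

Each calibrated DMA channel of an event is mean-removed and
zero-padded to a fixed 512-sample window (events vary 400–600
samples), so FFT coefficient indices address fixed frequencies
(bin k ↦ k·200/512 Hz; bins 20/38/94 ↦ 7.8/14.8/36.7 Hz, inside the
sub-50 Hz band). The 16 features per channel: 80% and 10% quantiles
(linear interpolation); |FFT| coefficients #94, #38, #20 (no
normalisation); p-value and standard error of the linear trend (OLS on
the sample index; two-sided t-test of zero slope); energy ratio of
segments 1 and 8 of 10 (1-based focus; `np.array_split` chunking, so
ratios always sum to 1); autocorrelation at lag 2 (full-series mean,
population 1/n variance); the c3 nonlinearity statistic at lag 3;
count of samples strictly below the mean; the minimum-aggregated
linear-trend r-value (chunks of 10 aggregated by their minimum, one
trend over the aggregate — the alternative per-chunk reading is
available behind a flag); the largest Langevin fixed point
(below); the fraction of samples beyond 1.5 population standard
deviations; and the mean absolute change over the full quantile
corridor.

The Langevin feature reconstructs the drift of dx = D1(x)dt + noise by
the Friedrich procedure: bin states into 30 quantile bins, average the
one-step increments per bin, fit a cubic to increment-vs-state, and
report the largest real root (a fixed point of the dynamics). Roots
are only accepted inside the sampled state range: outside the data
support the fitted cubic is unconstrained and can sprout spurious far
roots (visible when fitting a cubic to a linear mean-reverting drift).
Increments are not divided by the (constant) time step — positive
scaling of the drift polynomial leaves its roots unchanged. Degenerate
fits (constant series, too few occupied bins, no in-range real root)
yield a NaN sentinel, which is imputed with the training-column median
at standardisation time.

Conventions adopted where the procedure leaves freedom: population
(1/n) variance in the autocorrelation and r-sigma features; constant
series get slope 0, r = 0, p = 1, stderr 0 (total functions rather
than errors). With 11 pairs the matrix has 176 columns (6 pairs → 96);
columns are standardised to zero mean / unit variance with statistics
fitted on training rows only.

## Feature selection

Each column's relevance p-value is the minimum over classes of a
two-sided one-vs-rest rank-sum (Mann–Whitney U) test, Bonferroni
multiplied by the class count and capped at 1 — a distribution-free
choice suited to real-valued features and a multiclass target; the
test is pluggable. The Benjamini–Yekutieli step-up rule retains the k*
smallest p-values, with k* the largest k satisfying
P(k) ≤ k·α/(m·c(m)) and c(m) = Σ 1/i (harmonic number) under arbitrary
dependence — the appropriate variant for heavily correlated feature
columns; c(m) = 1 reduces it to Benjamini–Hochberg, of which BY is
always a subset at equal α. Default α = 0.05. Selection runs per
volunteer; feature definitions are consolidated by cross-subject
retention count (ties: smaller mean p, then canonical order). The
final pipeline applies all 16 retained definitions to every pair, so
the consolidated ranking is diagnostic rather than a hard filter.

## Classification and evaluation

Sensors are re-placed between sessions, so evaluation is
leave-session-out: train on two sessions, test on the held-out one,
rotated over all three sessions; user-dependent mode restricts to one
subject, user-independent pools all subjects. The SVM grid is fixed:
linear kernel with C ∈ {0.001, 0.01, 1, 10}; polynomial with
C ∈ {7, 8, 9, 10, 12, 15, 20}, degree ∈ {1, 2, 3} and
γ ∈ {4, 16, 1, ¼, 1/16}/n_features; in user-independent mode a
Gaussian kernel with C ∈ {3, 5, 6, 7, 8, 9} and the same γ rules is
added. Grid points are scored by 10-fold stratified CV macro-recall;
the winner is refitted on the full training split. `grid_search` can
first carve a seeded class-stratified 33% hold-out and tune on the
remaining 67%; the pipeline default runs CV on the full training
split, treating the hold-out as a one-off model-family triage step
that is not re-run here (it remains available via `use_holdout`).
Multiclass decomposition defaults to the SVC-native one-vs-one
(matching the scikit-learn classifier family the procedure used);
one-vs-rest is available via `decomposition="ovr"`.

Reports carry the 11×11 confusion matrix and per-class
precision/recall/F1 with macro (headline; classes are balanced, so
macro ≈ weighted, and both are emitted) and weighted averages. A class
never predicted gets precision 0 rather than NaN. Chance accuracy for
the balanced 11-class problem is 1/11 ≈ 0.09.

## Problem sizes and numerical choices

The acceptance experiments run the full pipeline at 3 subjects ×
3 sessions × 4 repetitions (396 events) over three seeds per preset —
a scale chosen so each grid search retains ≥ 10 training events per
class in every CV fold while keeping the whole evaluation in the
minutes range; protocol bookkeeping (2640 events, 240 per class,
880/110 test splits) is checked at the full default scale, where
generation is cheap because no classifier is trained. The
separable preset's expected macro-F1 (≥ 0.9) and the weak-triad rank
property of the paper-like preset are stable across seeds at this
scale.

Known limitations: the synthetic generator's activation tables are
configuration, not physiology; the 176-column matrix is heavily
correlated, so BY under arbitrary dependence is conservative and
per-subject retention counts vary; the Langevin feature is the only
catalogue entry with a non-trivial failure mode (NaN sentinel) and its
estimate degrades when a fixed point lies near the edge of the sampled
range; fractional-delay cardioid designs and near-field directivity
are out of scope.
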
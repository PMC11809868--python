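# Methods

## Problem

On an instrumented split-belt treadmill, heel strikes (HS) and toe offs
(TO) are conventionally detected by thresholding the vertical ground
reaction force (GRF) at a small fraction of body weight (1% here).  That
baseline breaks down during exoskeleton-assisted walking: foot drag
produces premature-contact force blips mid-swing, and unclean strikes
deposit part of a step on the contralateral force plate — both inject
spurious threshold crossings.  gaitmark implements a learned alternative:
single-signal LSTM regressors that map each input channel to per-sample
*confidence curves* peaking at events, fused across signals and decoded
by constrained peak detection.

## Event encoding

Each (side, event-type) stream is encoded as a curve with a unit-height
Gaussian of standard deviation sigma = 53.3 ms centred on every event and
zero in between.  Numerically the Gaussian support is truncated at
±4 sigma (~213 ms); the value at the cut is exp(−8) < 4·10⁻⁴, far below
decoding relevance, and the truncation realises the "zero between events"
contract exactly.  Where supports overlap, the curves combine by
elementwise maximum so peak height stays 1; with ~2 s stride times
same-type events never overlap in practice.  Events need not fall on the
sample grid: the Gaussian is evaluated at exact sample times, so an
off-grid event yields a peak sample slightly below 1.

## Decoding

Events are read back from a curve as local maxima of height ≥ 0.3,
accepted greedily in descending height order with any remaining peak
strictly within 1000 ms of an accepted peak rejected (the semantics of
MATLAB-style `findpeaks` with a minimum peak distance).  Equal heights
break ties toward the earlier peak; plateau maxima report the plateau
centre; decoding works at sample resolution (no sub-sample refinement).
Each of the four streams is decoded independently.

## Models

Each detector is one LSTM layer over a single normalized input feature,
followed by a linear map to two outputs (HS and TO confidence), trained
with MSE loss.  There is no deep-learning framework dependency: the
forward pass, backpropagation through time, and Adam are implemented
directly in NumPy (float64, bit-reproducible for a fixed seed).  Inputs
are normalized per trial: GRF in body-weight units, heel height min-max
scaled to [0, 1] (a constant heel channel maps to zeros).

Training is *incremental*: sequences are ordered per trial left side
first then right, cleanest trial first; each sequence is trained for a
fixed number of epochs continuing from the current weights.  Within an
increment the learning rate is `initial · 0.5^floor(epoch/50)`, and the
Adam moments restart (the schedule restart implies a fresh optimiser
state).  Long sequences are split into fixed-length chunks for
minibatching; a minibatch counts chunks.  At prediction time per-chunk
outputs are stitched with each chunk's leading overlap discarded — the
overlap is the recurrent warm-up.  Prediction may use longer chunks than
training (cheaper and strictly more context); results are identical in
practice once the warm-up covers a full stride.

Two presets are shipped:

| preset | rate | hidden | minibatch | epochs/incr | chunk | overlap | initial lr |
|--------|------|--------|-----------|-------------|-------|---------|------------|
| paper  | 1000 Hz | 540 | 110 | 500 | 2000 | 200 | 1e-3 |
| desk   | 100 Hz  | 64  | 16  | 100 | 400  | 200 | 5e-3 |

The desk overlap of half a chunk gives every emitted sample at least one
stride of context; its learning rate was chosen by training-loss
convergence within the 100-epoch budget (1e-3 left the loss visibly
unconverged at epoch 100; gradient clipping at global norm 1.0 never
engages on this problem).  Optimiser (Adam, lr 1e-3 full scale), chunking
and normalization are package design decisions; the architecture, loss,
incremental order, epoch/minibatch/hidden sizes and the 50%-per-50-epochs
decay are fixed by the method.  Whether the epoch budget is per increment
or total is ambiguous in the method's description; it is implemented per
increment, which matches the decay-schedule arithmetic.

## Fusion

The per-signal curves combine elementwise as

    C = sign(C_iGRF)·|C_iGRF|^a · sign(C_cGRF)·|C_cGRF|^b · sign(C_iHeel)·|C_iHeel|^c

with exponents in [0, 3] and shipped defaults (a, b, c) = (0.3, 0, 0.01).
A zero exponent replaces its term by the constant 1 (so the
contralateral-GRF model drops out at the default weights), and the signed
power sign(x)|x|^p keeps the product real for fractional exponents and
negative model outputs.  Exponents can be re-tuned by grid search
(`tune_weights`): candidates are scored by the RMS timing error of the
decoded events against reference events, with a reference event lacking
any detection within 1000 ms penalised at 1000 ms (the matching horizon;
leaving such events out entirely would reward under-detection).  The
default grid {0, 0.01, 0.03, 0.1, 0.3, 1, 3} per coefficient covers
[0, 3] log-spaced and contains the shipped optimum.

Note the small-exponent behaviour: |x|^0.01 is ≈ 1 for any x of moderate
magnitude, so the heel term acts mostly through its *sign* — a tiny
negative wiggle in the heel curve flips the fused curve negative at that
sample.  This is a property of the fusion formula itself and is the
mechanism by which low-confidence noise can occasionally be amplified
above the decoding threshold.

## Error metrics

Each reference ("manual") event is paired with the closest detected event
of the same stream (detected events may be reused; equidistant ties go to
the earlier event).  Error sign is model − manual: positive means the
manual event was earlier.  The bundle: ME (mean signed error), MAE
(median absolute error), IQR (of the signed error; the signed reading of
"interquartile range of the error"), SD (sample standard deviation over
*successful* matches only, |error| ≤ 16 ms, so a few large errors do not
inflate it), MAX (maximum absolute error), SR (% of reference events with
a detection within 16 ms, inclusive), DR (same within 1000 ms), and the
signed extra-event count after trimming the detected stream to the span
aligned with the first and last reference events.

## Synthetic gait generator

The simulator produces the study conditions for all tests: slow treadmill
walking (stride period 2000 ms with 20 ms jitter — ~1% stride-time CV,
typical of steady treadmill gait; stance fraction 0.65; belt speed
0.491 m/s recorded as metadata).  Per stance the vertical GRF follows the
smooth two-harmonic M-shape A·sin(πp)(1 + 0.5·cos(2πp)), which has exact
maxima of `grf_peak_factor`·BW (default 1.1) at 25% and 75% of stance, a
midstance dip of ~0.78 BW, and zero force at contact and lift-off.  (A
literal pair of truncated raised-cosine lobes cannot make the endpoint
zeros and a nonzero midstance dip simultaneously; the two-harmonic form
is the closest smooth shape that can.)  The heel marker is on the ground
(0 mm) throughout stance and follows a raised-cosine arc up to 150 mm
during swing, peaking at 35% of swing — shortly after toe off, as real
heel trajectories do.

Artifacts reproduce the two failure modes of thresholding: *foot drag*
(per-swing probability `drag_rate`) injects a sin²-windowed GRF blip of
2–8% BW lasting 50–150 ms mid-swing on the swinging foot's plate, and
*cross-plate strikes* (per-stance probability `cross_plate_rate`) add
10–40% of a stance's force profile to the opposite plate.  Additive
Gaussian sensor noise (1 N on GRF, 0.5 mm on heel height, both clipped to
physical non-negativity) completes the signal.  All randomness flows from
one seeded generator in a fixed draw order (schedule, drag, cross-plate,
noise), so trials are bit-reproducible.

What the generator does *not* emulate: realistic force-curve morphology
beyond the M-shape (no inter-subject variability, no anterior–posterior
or mediolateral components), marker soft-tissue artifact, exoskeleton-
specific gait changes beyond timing jitter, or missing-marker gaps
(inputs must be gap-free).  Event *timing* is the contract; passing tests
show the pipeline recovers known event times under these artifact
classes, not that it matches human-data error statistics.

## Preprocessing

GRF: 4th-order Butterworth low-pass at 20 Hz applied forward-backward
(zero phase, effective 8th-order attenuation) with reflective padding of
3× the filter's taps, so startup transients do not corrupt the first
strides.  Heel: 5th-order smoothing spline with a fixed residual budget
of 0.5 mm RMS — mild noise suppression that preserves a clean synthetic
arc within 1 mm RMS — then piecewise-linear resampling to the common
rate (marker data is typically 100 Hz against 1000 Hz GRF).  Filter
order and padding are not dictated by the method and are package
defaults common in biomechanics.

## Benchmark problem sizes

The shipped end-to-end benchmark simulates 40 trials of 180 s at 100 Hz
(simulation seeds 1–40, drag and cross-plate rates 0.05), trains the
iGRF and iHeel detectors with the desk preset on trials 1–2 (four
increments: two trials × two sides), fuses with (0.3, 0, 0.01), decodes
(min height 0.3, min interval 1000 ms), and scores trials 3–40 against
ground truth — roughly 27,000 pooled events.  One run takes on the order
of ten minutes on a single CPU; the full-size preset (1000 Hz, 540
hidden units, 500 epochs per increment) is preserved verbatim but is a
GPU-scale computation and is not exercised by the test suite.

## Known limitations

* The detectors are causal (unidirectional LSTM): output at time t sees
  only samples ≤ t.  Event anticipation therefore rests on learned
  stride timing; a small reactive lag (fractions of one sample period)
  remains in the decoded events, which matters at 100 Hz where one
  sample is 10 ms.
* The fusion exponent c = 0.01 makes the heel term a near-binary sign
  gate (see above); occasional extra events from noise amplification are
  inherent to the formula.
* `tune_weights` scores candidates jointly over all trials; it does not
  cross-validate.
* The threshold baseline's contact-count monotonicity in the threshold
  holds for unimodal contact bumps; an M-shaped cross-plate artifact can
  split into two contacts when the threshold passes above its dip.
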
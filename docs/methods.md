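# Methods

This note documents the models, conventions, parameters and design
decisions behind `tailkin`, and what the synthetic-data tests do and do
not establish about real data.

## Problem setting

Detection dogs search a three-zone scent wall (a target-odour area, a
distractor area and a no-odour area, re-randomised every trial) and alert
by holding the nose at a hole for at least 4 s. Overhead 60 fps video is
reduced by a markerless pose detector to per-frame coordinates of six body
landmarks (nose, front head, shoulders, tail base, tail middle, tail tip)
plus a detector confidence. The package answers three questions from that
representation: (1) what are the tail kinematics in each search segment,
(2) can a classifier tell from tail motion alone whether the dog is in the
target area, and (3) how does that classifier compare with human experts
judging the same clips?

## Segmentation and alert excision

Behavioural event logs (BORIS tabular exports) code four mutually
exclusive behaviours: `area1`–`area3` occupancy and `alert`. Trials are
split into per-area search segments on a half-open convention
`[start, stop)`: a frame exactly on a boundary belongs to the later
interval, so no frame is ever double-assigned. Around every alert, frames
from 1.0 s before onset through alert end are removed — the pre-alert
buffer is clock-based (1.0 s of wall time, not a frame count) — and
whatever follows a completed alert inside the same area visit is discarded
as reward/handler interaction rather than search. The excision window is
half-open at its upper edge like every other interval here; a closed edge
would swallow the first frame of the following area visit whenever an
alert ends exactly on an area boundary. Segments shorter than 0.5 s (or
with fewer than two frames) after excision are dropped: angular velocity
needs at least two frames, and clips that short carry no usable wag cycle.

## Body frame and tail angle

The body-centred frame has its origin at the tail base B and its +y axis
along the shoulders→tail-base direction (S→B). In y-down overhead image
coordinates the dog's-right unit vector is `r = (-b_y, b_x)`; a
`handedness` switch negates it for mirrored footage, making the sign
convention reversible without touching data. The tail angle is

    theta = atan2(BM . r, BM . b)   (degrees, in (-180, 180])

with M the tail-middle landmark: 0 when the tail points straight back,
positive to the dog's right. The tail middle, not the tip, defines the
angle: the tip is unstable frame-to-frame and misleading in curly-tailed
breeds. theta is invariant to rigid rotation, translation and uniform
scaling of the image, which the tests verify to below 1e-6 degrees.

Frames with detector confidence below 0.5 (configurable), a degenerate
body axis (|B - S| <= 1 px) or missing landmarks are masked. Masked runs
of at most 5 frames are bridged by linear interpolation *of theta over
time* — never of raw coordinates, which would interpolate through the
dog's body — and longer runs stay masked and are excluded from every
statistic.

Angular velocity is the wrapped consecutive-frame difference of theta,
divided by dt by default (`per_second`, frame-rate independent); a
`per_frame` mode reports raw per-frame differences for fixed-rate footage.
Wrapping maps differences into (-180, 180], so a crossing from 179 to
-179 degrees counts as +2, not -358.

## The six kinematic features

Per segment, over valid frames: mean signed angle; maximum positive
(rightward) excursion of theta; |minimum| negative (leftward) excursion;
mean absolute angular velocity; fraction of frames with theta > 0; and
fraction with theta < 0. Amplitudes are referenced to zero (the body
axis), not to the segment's mean, and an amplitude is 0 when that side is
never visited (an extremum over an empty set is otherwise undefined). The
mean angle is computed over signed theta. The two occupancy fractions plus
the fraction of exactly-zero angles sum to 1 exactly. A polar occupancy
histogram over the rear semicircle [-90, +90] complements the scalar
features; the default is 18 sectors of 10 degrees, and angles beyond the
semicircle are clipped into the terminal sectors rather than wrapped (a
tail bent past +/-90 is still extreme lateral, not medial).

A useful closed form for validation: for theta(t) = A sin(2 pi f t) the
mean absolute angular velocity is 4Af, which 60 fps sampling reproduces
within 1% at A = 45 deg, f = 4 Hz.

## Detector evaluation metrics

RMSE is the root mean squared Euclidean distance between predicted and
true landmarks, pooled over (image, landmark) pairs; a per-coordinate
variant (pooling squared x/y errors separately) is available behind a
flag because the scalar notation used for this metric is ambiguous across
toolkits. PCK@k is the percentage of predictions within k·D of truth,
with D the per-image shoulders–tail-base distance; the boundary counts as
correct, and the default pools over all pairs (a per-image mean is
available). These metrics validate upstream detectors and the synthetic
degradation model; the package does not ship a detector.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every default chosen once as the study condition it stands for:

- **Wag waveform**: theta(t) = bias + A(t) sin(2 pi f t + phi) + eps,
  A(t) alternating between `amp_right` on positive half-cycles and
  `amp_left` on negative ones — an asymmetric sinusoid, because left and
  right wag reach are measured separately. Square and triangle waveforms
  are available in the design config. White jitter eps (SD ~2 deg) stands
  for postural noise.
- **Dog profiles** (random effects): bias 0 +/- 8 deg, amplitudes
  28 +/- 6 deg, frequency 3.0 +/- 0.6 Hz (dog wagging is a few Hz),
  body scale 110 +/- 12 px and tail scale 65 +/- 8 px at 720p overhead.
- **Target effect**: in the target area the wag parameters shift by an
  additive per-dog delta scaled by `effect_scale` (the odour-concentration
  proxy). The default population effect is a left-amplitude increase
  (+18 +/- 4 deg) with a small leftward bias shift (-5 +/- 2 deg) —
  the group-level lateralisation signature the analysis is designed to
  detect; the sign is configurable for sensitivity studies.
- **Durations**: per-segment search durations are log-normal truncated
  below at 1.0 s, with (mu, sigma) solved numerically so the *truncated*
  distribution has mean 3.34 s and SD 3.45 s (matching the clip-length
  summary the pipeline is calibrated to). Solving the untruncated moments
  and then truncating would inflate the mean to ~3.85 s.
- **Geometry**: heading follows an Ornstein–Uhlenbeck walk (drive
  0.4 rad/sqrt(s), reversion 1/s) and the body drifts smoothly, so the
  body frame is exercised under rotation; landmarks are placed by
  inverting the kinematics body-frame geometry; the tail tip leads the
  middle by `lag * dtheta/dt` (lag 30 ms), mimicking its excess mobility.
  No quantitative data exist for heading dynamics or inter-area transit;
  these defaults are placeholders and are flagged as such in the config.
- **Detector noise**: isotropic jitter (1.5 px), per-frame dropout (2%)
  that degrades confidence (drawn near 0.3 instead of 0.92) and blanks
  tail landmarks, applied after geometry.
- **Trial structure**: test 1 runs sessions of trials at the trained
  concentration with one target / one distractor / one no-odour area
  rotating pseudo-randomly; test 2 runs one session per dilution step
  (10^-3 … 10^-6, class-effect multiplier 1, 0.5, 0.25, 0.1) with one
  target and two distractor areas. Dogs alert in the target area with
  probability 0.98 at full effect, decaying linearly toward 0.5 as the
  effect shrinks (mirroring the dogs' own threshold behaviour); false
  alerts occur at 1%. Alerted target visits gain a 1 s pre-alert buffer
  plus a 4–6 s alert span, both excluded from the search segment exactly
  as the excision rule would.

Because the generator inverts the same geometry the extractor uses, the
extracted angle reproduces the generating one to float precision at zero
noise — the inverse-pair oracle at the heart of the test suite.

**What passing synthetic tests does not show**: real tail kinematics are
not stationary sinusoids; real detector errors are structured (occlusion,
motion blur), not white; real dogs' target responses need not be additive
parameter shifts. The synthetic results validate the *pipeline machinery*
(geometry, segmentation, training protocols, statistics), not the
biological effect sizes.

## Classifiers

**Recurrent model** (test-1 protocol): per-frame 7-vectors — the three
tail landmarks in the body frame divided by the shoulders–tail-base
distance, plus detector confidence — feed GRU(32) → GRU(16) → FC 16/8/4
(ReLU) → dropout 0.1 → 1 sigmoid unit. The network is implemented
directly in numpy (forward and backpropagation through time), which keeps
training exactly reproducible on one CPU thread; the test suite validates
the gradients against numerical differentiation. Variable-length clips
are padded with a mask; the recurrent state carries over padding so the
last state is the final valid one. The clip representation fed to the
dense head is a mask-aware *mean* of the second GRU's per-timestep
outputs (default), not the final state: with final-state readout, folds
that hold out an entire dog intermittently collapse — training fits
perfectly while the held-out dog's probabilities cluster
indistinguishably around 0.5, because the terminal state's scale is
dog-specific — whereas time-averaged features are amplitude-sensitive
and stable across individuals. A `readout="last"` option retains the
final-state variant. Series are decimated to 30 fps and capped at 20 s
for memory predictability, and each channel is z-scored with
training-set statistics before entering the network (the body-frame
channels are small and near-constant, which otherwise leaves the pooled
state almost identical across clips at initialisation and training prone
to chance plateaus). Loss is binary cross-entropy with inverse-frequency
class weights (w_c = n/(2 n_c); per-sample mean weight exactly 1),
optimised by Adam at 1e-3, batch 32, up to 100 epochs with early
stopping (patience 10, never before epoch 15 — with few batches per
epoch a plateau-at-chance would otherwise freeze an untrained model) on
a 15% stratified validation split. Dropout sits after the dense stack as
a single layer.

Networks this narrow have two well-defined failure modes at unlucky
initialisations, both detected and handled deterministically: the 16/8/4
ReLU stack can die wholesale (gradients exactly zero, loss frozen at
ln 2 — ReLU biases therefore start at +0.01), and the 4-unit layer can
code one class as all-zero activations, pinning that class's logit at
the output bias so the loss falls while every decision lands on one side
of 0.5. Training that ends on the chance plateau (best loss >= 0.67) or
with a broken threshold (loss < 0.6 yet training accuracy <= 0.6) is
restarted with a seed derived from the config seed, at most twice, so
the procedure remains exactly reproducible.

**Feature ensemble** (test-2 protocol, where clips are too few for the
recurrent model): gradient-boosted trees (depth 9) plus an RBF-kernel SVM
on standardised features, over the six kinematic features. Prediction is
a weighted majority vote with weights proportional to each member's own
small-CV accuracy on the training data (the vote weights are otherwise
unidentified); ties resolve to non-target, the conservative choice since
false alerts are the costly error. A weighted mean of member
probabilities is exposed for ROC/AUC use.

**Protocols**: stratified 5-fold CV (pooled result = mean over folds);
leave-one-dog-out (one fold per dog, train/test strictly dog-disjoint,
asserted every run — performance then reflects generalisation to unseen
individuals); and train-high/test-low concentration generalisation with
per-dilution accuracy and no cross-validation. Both 5-fold and LODO are
first-class and reported separately. Training sets keep only target
segments from trials with a correct alert (a miss means the dog may never
have been in odour); non-target segments pass through, and the default
protocol subsamples them to match the positive count so chance accuracy
is 0.5 for every protocol.

## Evaluation statistics

AUC uses the rank (Mann–Whitney) formulation with mid-ranks for ties.
The paired DeLong test compares two correlated AUCs on the same videos
via the structural-components variance estimator with a two-sided normal
reference; an exactly-degenerate variance is reported as undefined rather
than inflated. Expert surveys are analysed per participant over answered
videos only (skips are neither right nor wrong), stratified by paid
experience; pooling across participants uses the vote fraction — the
share of responders calling a video "target present" — as the per-video
expert score, the standard crowd-scoring choice where no pooling rule is
otherwise specified. Correlations (per-dog model-vs-expert accuracy,
clip-length vs accuracy) default to Pearson with a rank option.

In place of mixed-model fits (available externally through the exported
feature tables), the in-repo area-effect procedure is a dog-stratified
permutation test: statistic = mean over dogs of (dog-mean feature in the
target area - dog-mean in a comparison area); null built by permuting
area labels within dog × session strata, so dog identity and session
drift can never masquerade as an odour effect; p = (1 + #{|stat*| >=
|stat|})/(n_perm + 1), valid under the null by the +1 correction.
Single-segment strata cannot contribute and are logged.

## Numerical and degenerate-input choices

Angles are degrees at every interface. Wrapped differences live in
(-180, 180]. Ties in the ensemble vote go to non-target; ties in ranks
use mid-ranks. Degenerate body frames, missing landmarks and
low-confidence frames are masked, never zero-filled. Feature extraction
on fewer than two valid frames is a recorded failure, not a silent NaN.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical datasets,
models and reports.

## Problem sizes used in the shipped tests

The test suite and acceptance script run the pipeline at desk scale,
chosen as the smallest sizes at which each statistical check is stable:
studies of 2–8 dogs with 1–3 sessions of 4–10 trials (a few hundred
segments), 500-replicate calibrations for the DeLong and permutation
tests, and 20-replicate monotonicity checks for concentration
degradation. The leave-one-dog-out recovery check uses the named
construction `PopulationSpec.strong_lateralization` — a shared
left-amplitude effect of +35 +/- 2 deg on a 25 +/- 3 deg baseline with
the lateral-bias channel quiet: recovery oracles must be separable by
construction, and under the default moderate effect the between-dog
overlap itself — not the pipeline — caps out-of-dog accuracy near 0.7,
which is worth knowing but tests the biology the generator emulates
rather than the code.

## Known limitations

Tail elevation is invisible from a single overhead view; the analysis is
strictly 2-D. Nose and front-head landmarks are carried through I/O but
unused. The generator does not render video, model odour plumes, or model
the alert posture beyond emitting alert events. The GLMM/beta-regression
analyses of area effects are deliberately out of scope; the permutation
test answers the narrower exchangeability question.
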
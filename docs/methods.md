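# Methods

This note documents the models, conventions and numerical choices behind
`engagekit`, and what the synthetic benchmark does and does not show.

## Problem setting

A child interacts freely with robots in a room; a camera records the session.
An upstream 2D pose estimator turns the video into per-frame keypoints
(25-point body model, 70-point face model, each point x, y, confidence in
image pixels). Separately, human coders log six target behaviors — eye-gaze
focus, vocalization, smiling, self-initiated interaction, triadic
interaction, imitation — as (start, stop) intervals. The task is to map the
keypoint stream to the child's engagement level, a 7-class label defined as
the number of concurrently active behaviors divided by six.

## Track construction

**Subject tracking.** Multi-person frames are resolved by greedy positional
continuity: the first detected frame seeds with the highest-confidence
candidate; each later frame picks the candidate whose mean keypoint position
is nearest the previous selection. The estimator's own person IDs are not
used — in cluttered scenes they switch identity too often to be trusted.

**Gap policy.** The upstream estimator drops frames. Holes of at most 15
frames (0.5 s at 30 fps) are filled by per-coordinate linear interpolation,
flagged in `gap_mask` and given confidence 0; longer holes split the track
into segments. The cutoff is deliberately half the 30-frame feature window:
interpolating across longer holes would synthesize most of a window from
fabricated data. Individual keypoint dropouts (conf ≤ 0, coordinates 0)
inside otherwise detected frames are interpolated the same way within a
segment. A point with conf ≤ 0 but nonzero coordinates (e.g. an interpolated
frame) still counts as detected. `fill_gaps` is idempotent.

**Units.** Coordinates stay in raw pixels; an optional normalization by
median inter-shoulder distance exists but is off by default, since the
classifiers are personalized (per subject, per camera setup) and raw
coordinates preserve the facial-position features' meaning.

## Laban effort features

Three Effort qualities of Laban Movement Analysis are computed from the
upper body. "Hands" are the wrist keypoints; there is no reliable finger
tracking in this data.

* **Space** — with a⃗ (left shoulder→left wrist), b⃗ (right→left shoulder),
  c⃗ (right wrist→right shoulder), d⃗ (left→right wrist):
  `space = ½|a⃗||d⃗|sin θ₁ + ½|c⃗||b⃗|sin θ₂` (θ₁ between a⃗ and d⃗, θ₂
  between c⃗ and b⃗), the sum of the two triangle areas — equivalently the polygon area of the convex arm
  quadrilateral (property-tested against the shoelace formula). Degenerate
  (zero-length) vectors contribute 0. Units px².
* **Weight** — `Σᵢ Lᵢ² ωᵢ² sin θᵢ · massᵢ` over four joints: both shoulders
  (angle between the torso vector neck→mid-hip and the upper arm) and both
  elbows (angle between upper arm and forearm). L is the segment length
  distal to the joint (px); all masses are 1 (no anthropometric data is
  available, and any constant rescaling is absorbed by the classifiers).
  Every summand is ≥ 0 since θ ∈ [0, π].
* **Time** — `Σᵢ |ω̇ᵢ|`, the total angular-acceleration magnitude. The
  source equations are ambiguous between velocity and acceleration here; we
  read the dotted symbol as acceleration (urgency of movement) and expose
  `time_mode="velocity"` as the alternative.

**Differentiation.** θ is unwrapped modulo 2π, then differentiated by central
differences at fps (one-sided at segment endpoints), twice for ω̇. On
noiseless synthetic trajectories the errors are O(Δt²), verified against
closed forms. Segments need ≥ 3 frames.

**Windowing.** Instantaneous features are averaged over a trailing 30-frame
window (1 s at 30 fps — long enough to smooth estimator jitter, short enough
to follow movement changes), restarted at each segment boundary; the first
frames of a segment average what is available. NaN frames (missing
keypoints) are skipped by the window mean and dropped at assembly.

## Feature matrix and windows

The classifier input per frame is 71-dimensional: x, y of the 34 eye/lip/
pupil facial keypoints (indices 36–47 eyes, 48–67 lips, 68–69 pupils of the
70-point face model — the unique eyes+lips+pupils subset of size 34),
then space, weight, time. Frames are cut into stride-1 windows of length 5
inside contiguous segments only; each window takes the engagement class of
its **final** frame (a causal convention compatible with streaming
prediction). The alternative reading of the network's "5 channels" as 5
feature channels would contradict the 71-feature design, so 5 is the
sequence length; it is a config knob (`CnnSpec.seq_len`).

Annotation times are mapped to frames by evaluating each frame at t = i/fps
against closed–open intervals; alignment between features and labels is by
original video frame index, which survives dropped frames.

## Classifiers

The convolutional model is Conv1D(64, k=3) → ReLU → Conv1D(128, k=3) → ReLU
→ dropout 0.2 → flatten → dense 256 → ReLU → dense 256 → ReLU → dense 7,
≈139k parameters, trained with softmax cross-entropy and Adam (lr 1e-3). It
is implemented directly on NumPy (im2col convolutions, manual backprop),
which keeps the full train→predict path bit-for-bit reproducible under a
seed. Choices the source architecture leaves open:

* **Epochs/batch.** Defaults 100 epochs, batch 64, early stopping with
  patience 12 and best weights restored. The stopping monitor is validation
  *accuracy*, not the weighted validation loss: with inverse-frequency
  weights a handful of rare-class windows carries enormous sample weights,
  making the weighted loss so noisy across epochs that loss-based patience
  aborts runs long before convergence.
* **Loss weighting.** Engagement levels are heavily imbalanced (mid levels
  dominate; 0 and 6 are rare), so the loss uses inverse-frequency class
  weights by default (`CnnSpec.class_weighting`). Note the degenerate limit:
  on label-uninformative features a weighted learner balances its
  predictions (accuracy ≈ the balanced rate), while an unweighted learner
  falls to the majority-class rate. Negative-control experiments therefore
  use `class_weighting=False`.
* **Input standardization.** The network standardizes each feature channel
  internally using training-set statistics. The raw features mix pixel
  coordinates (~10²) with effort features spanning several orders of
  magnitude; without this, gradient training stalls at chance. This is a
  numerical property of the model, not dataset preprocessing — the stored
  datasets remain unscaled (an optional `zscore` exists, off by default).

Baselines (scikit-learn, windows flattened to 355-vectors): SVC (RBF, C=1),
random forest (100 trees), decision tree (unlimited depth), k-NN (k=5) —
standard defaults, stated in `make_baseline`.

## Evaluation protocol

All metrics are class-support weighted: weighted accuracy is the
support-weighted mean of per-class recall (algebraically identical to plain
accuracy — asserted against an independent confusion-matrix implementation),
weighted F1 the support-weighted mean of per-class F1.

Per subject, the protocol repeats a random 80/20 train/test split 10 times
(config `reps`), carving 10% of the training part into a validation set,
with a fresh logged seed per repetition; every split is audited for being a
disjoint, exhaustive partition. The "10-fold cross-validation with 0.8/0.2
split" convention this mirrors is internally inconsistent (10-fold would be
0.9/0.1); repeated random 80/20 splits match the printed fractions. Group
models pool all windows of a group before splitting. Report tables round to
4 decimals (detailed tables) or 2 (comparison tables), and group means are
unweighted arithmetic means of per-subject rows — conventions pinned by
recomputing the published study tables' summary rows from their per-subject
rows, cell-exactly.

Note that random splits of stride-1 windows put temporally adjacent,
near-identical windows in train and test; held-out accuracy under this
protocol is therefore optimistic relative to temporal generalization. A
`blocked=True` split (by time) is provided for leakage-free evaluation; the
random split remains the default protocol.

## Synthetic data

The study's recordings are unavailable, so the generator emulates their
structure. Behavior events are drawn per behavior from an alternating
renewal process (exponential on/off durations; defaults 8–30 s on,
12–120 s off, chosen so each behavior's duty cycle mirrors coded sessions
and the engagement level changes ~0.2 times/s — slow relative to the 1-s
feature window, which the separable-regime construction requires). The
per-frame active-behavior count selects the kinematic regime: sinusoidal
arm-swing with amplitude doubling per engagement class (0.05…3.2 rad, the
lowest still several pixels of wrist motion, i.e. above the 1-px coordinate
noise), rising swing frequency (0.5–1.7 Hz), and facial keypoint motion
scale doubling per class. Active smiling widens the lip x-spread by 1.3.
Phase is continuous through regime switches; iid Gaussian pixel noise
(σ = 1 px) and Bernoulli frame drops (p = 0.01) emulate estimator error and
processing loss. `SyntheticConfig.collapsed()` equalizes all regimes — the
negative control with no feature–label signal.

What passing these benchmarks shows: the pipeline's stages compose
correctly, the features carry the constructed signal, and the classifiers
recover it (and find nothing when there is nothing). What it does not show:
performance on real children, where the engagement–kinematics link is far
noisier, behavior-specific, and non-stationary; no biomechanical realism is
claimed for the motion synthesis.

Problem sizes: tests use subjects of 3,000–6,000 frames; the acceptance
script uses 3 subjects × 10,000 frames (about the middle of the study's
9,300–30,508 datapoint range) with single splits, sizes chosen to keep a
desk-scale run in minutes. The parameter-recovery benchmark generates at
σ = 0.5 px — the small-noise regime its separability construction assumes —
while the generator default stays at the more realistic σ = 1 px; at σ = 1
the two lowest regimes (2.75 vs 5.5 px wrist amplitude) are partially
noise-masked and recovery accuracy drifts toward the mid-0.8s.

## Degenerate inputs and tie-breaks

Zero-length geometry vectors flag the frame degenerate (space contribution
0, angles NaN). Missing required keypoints raise a named error per joint.
Single-class training sets warn and fit a constant predictor where the
estimator requires ≥ 2 classes. Splits use floor rounding (N=100 →
72/8/20). Empty prediction inputs return empty outputs. All randomness
(splits, initialization, dropout, event draws) flows from explicit seeds;
per-subject seeds derive from a master seed.

## Known limitations

* 2D kinematics only; out-of-plane movement aliases into the effort
  features.
* The engagement index weighs all six behaviors equally; no intensity
  grading within a behavior.
* Inter-coder disagreement is upstream: a single merged annotation track is
  consumed.
* The weighted-accuracy convention equals plain accuracy; it counters
  imbalance only through the paired weighted F1 and per-class tables.
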
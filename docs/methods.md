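# Methods

This note documents the models, algorithms and design choices behind
`trocartrack`: a three-stage pipeline for recognizing, from extra-abdominal
cameras, which laparoscopic trocars are present in the close-up view and
whether each currently holds an instrument.

## Problem setting

During laparoscopic surgery, up to four trocars (ports through the abdominal
wall) are visible to cameras mounted outside the body — a close-up camera C1
over the surgical field and a distant camera C2 viewing the whole scene.
Each trocar, at each time step, is in one of three occupancy states:

* `empty` — no instrument inserted,
* `occupied` — an instrument is inserted,
* `not_visible` — the trocar cannot be seen in C1 (occluded or out of view).

The pipeline is: per-frame trocar **detection** → **capped-identity centroid
tracking** (persistent IDs 1–4) → per-trocar crops plus both full frames
encoded and fused into one feature vector per time step → a **temporal
model** (LSTM, GRU or MS-TCN) classifying every trocar's state at every
frame. Real surgical recordings of this kind are private; the package
therefore ships a synthetic dual-view scene simulator so that every stage is
testable and every experiment is reproducible from a seed.

## Synthetic scenes

The simulator emulates the *structure* of the real data, not its appearance:

* **Geometry.** Up to four bright discs on a dark body-surface background,
  placed in the four frame quadrants after the standard port layout; IDs 1–2
  render with a larger radius than IDs 3–4 (10 mm vs 5 mm ports). Default
  frame sizes are 320×180 (C1) and 160×90 (C2) at 6 fps — the rate at which
  real recordings are annotated; the full 1920×1080 @ 30 fps geometry is a
  config change.
* **Occupancy dynamics.** Per trocar, an independent renewal (semi-Markov)
  chain: each new segment's state is drawn with probability ∝ π_j / d_j and
  lasts a geometric dwell with mean d_j frames, so the long-run fraction of
  time in state j is exactly the stationary probability π_j. The default π
  is the recorded class imbalance — empty 10.72 %, occupied 65.35 %, not
  visible 23.93 %.
* **Dwell means** default to (2, 4, 3) frames for (empty, occupied,
  not_visible). These are deliberately time-compressed relative to clinical
  instrument-exchange timescales, in proportion to the desk-scale scene
  lengths (tens of seconds rather than hours): scenes then contain many
  state transitions for the temporal models to learn from, and the chain's
  mixing time stays far below the 10⁴-frame horizon used for calibration
  checks, so empirical state frequencies concentrate tightly around π
  (within ~3 binomial standard errors; dwell autocorrelation inflates the
  variance of occupation frequencies by roughly (2d−1)× over i.i.d.
  sampling, which is what makes short dwells necessary for tight
  calibration).
* **Camera jitter.** A bounded random walk in translation (±2 px/frame steps,
  clamped to ±8 px) and rotation (±0.5°/frame, clamped to ±2°) applied to
  all trocar positions about the frame center.
* **Illumination.** A multiplicative brightness factor following a bounded
  random walk in [0.9, 1.1], applied uniformly per frame.
* **Occlusion.** A trocar becomes `not_visible` by moving under a rendered
  occluder bar at the top of the frame (a cable/lamp-edge stand-in) — not by
  deletion — so trackers must survive disappearance and reappearance.
  Ground-truth boxes are absent exactly while a trocar is `not_visible`.
* **Occupancy rendering.** An `occupied` trocar carries a dark instrument-
  shaft segment entering its disc from above; `shaft_contrast` scales this
  cue, and 0 renders `occupied` identically to `empty` (used for the
  constructed-signal ablation below).
* **C2 content.** The real distant view is only qualitatively described
  (another viewpoint on the scene), so its informational content here is a
  design choice: a deterministic correlate cue (a bright patch) that is
  present either when any trocar changes state within ±2 frames
  (`c2_cue="transition"`, the default — giving the fusion model a learnable
  reason to use the XC2 block) or when trocar 1 is occupied
  (`c2_cue="occupancy"`, used in the ablation experiment).

What the simulator does **not** model: photorealistic appearance, surgeon
hands and instrument types, 3D geometry, motion blur, or correlated
occlusions. Passing tests on synthetic scenes therefore demonstrate the
correctness and stability of the algorithms (tracking, fusion, training,
evaluation), not clinical-grade recognition accuracy on real video.

Conventions everywhere: pixel coordinates with origin top-left, x right,
y down; axis-aligned half-open boxes `[x_min, y_min, x_max, y_max)`;
0-based frame indices.

## Detection

The production-grade detector for real video is a learned single-stage
object detector behind a pluggable contract (anything emitting scored boxes
works). The intended training configuration for such a plug-in, retained
here for reference, is: 30 epochs, SGD, learning rate 1e-3, batch 16,
inputs resized to 640×640, with flip/affine/color augmentation. Training
such a detector requires the private surgical data and is out of scope.

The bundled reference detector is classical and exact on synthetic scenes:
threshold at the midpoint between the background level (frame median) and
the frame maximum — a background-relative rule, so a uniform brightness gain
(the `brighten` preprocessing op) cannot move the decision boundary —
followed by connected-component labeling, a minimum-area filter (default
20 px²), and a fill-ratio score (component area / box area; a disc scores
≈ π/4). A frame whose maximum is below 1.35× the background level (plus a
small absolute guard) is reported empty. Detector metrics use greedy
one-to-one matching by descending IoU at threshold 0.5 (the matching rule is
a package choice) with counts pooled over frames.

## Tracking

The tracker encodes the prior that at most four trocars exist:

* **Cost.** For track T and detection D within the gate g,
  `cost = ‖c_T − c_D‖ + w_area · |A_D − A_T| / max(A_D, A_T) · g`,
  i.e. centroid Euclidean distance plus the relative area difference scaled
  to distance units. The area term (weight default 0.5) stabilizes
  identities under camera shifts; the exact formula is this package's
  definition — only the ingredients (distance, box areas) are given by the
  problem. Pairs farther than the gate are unmatchable. Gate default: 10 %
  of the frame diagonal.
* **Assignment.** The minimum-total-cost, maximum-cardinality one-to-one
  matching (Hungarian algorithm on the gated cost matrix). With ≤ 4 tracks
  this equals exhaustive enumeration, which the test suite uses as an
  independent oracle. Optimal assignment was chosen over greedy
  nearest-centroid because it is strictly better on crossing tracks and
  directly testable against the oracle.
* **Lifecycle.** Unmatched detections create new identities only while
  fewer than `max_tracks` exist; afterwards they are discarded with a
  warning (the alternative — treating a far-away detection as a new trocar —
  is unsupported by the four-port prior). Unmatched tracks become invisible
  and are **frozen, never deleted**; a track missing longer than
  `max_frames_missing` (default 10) can only be revived inside a larger
  re-acquisition gate (default 2× the match gate). IDs are therefore stable
  for the scene's lifetime.
* **ID semantics.** By default new tracks take IDs in birth order; the
  `position` mode (`--id-by-position`) assigns the quadrant-based functional
  ID (1 top-left, 2 top-right, 3 bottom-left, 4 bottom-right), mirroring the
  anatomical port roles. The pipeline experiments use position mode so that
  track slot i aligns with ground-truth trocar i.
* **ID-switch metric.** Tracker output is matched per frame to the
  ground-truth trocar of maximal box IoU; a track's reference identity is
  its majority match. Reported are both the switch-frame count (frames spent
  on a non-majority identity) and the event count (identity transitions);
  a permanent swap counts once as an event.

## Feature fusion

Per time step the fused vector is the in-order concatenation
`[X1, X2, X3, X4, XC1, XC2]`:

* **Crops with adaptive padding.** Each visible trocar's box is expanded
  symmetrically along its shorter side to a square — preferring real frame
  content as padding, zero-filling beyond the borders — then resampled
  (bilinear) to the encoder's input size. Content is centered and never
  stretched. "Adaptive padding" has no published definition in this
  setting; aspect-preserving square padding with context pixels is this
  package's interpretation.
* **Invisible slots** contribute all-zeros vectors (zero-fill was chosen
  over omission so the concatenated dimension is constant; a learned
  placeholder could be substituted via the encoder contract).
* **Full frames** of C1 and C2 are resized (bilinear) to the encoder input
  and encoded like crops.
* **Encoder.** The contract is: deterministic map from a square patch to a
  fixed-dimension vector. A deep backbone (e.g. an 18-layer residual
  network) is one admissible plug-in with its native dimension; the bundled
  `ReferenceEncoder` (default D = 64) is a two-layer CNN with *fixed seeded
  weights* — conv3×3/stride2 (8 ch) → ReLU → conv3×3/stride2 (16 ch) → ReLU
  → adaptive 2×2 average pooling → optional fixed linear projection. Each
  patch is first divided by its mean intensity, so the multiplicative
  illumination drift of the simulator cancels exactly. The encoder is never
  trained: random convolutional features preserve the geometric cues
  (shaft edges, disc size) that the trained temporal model needs, and a
  fixed encoder keeps the whole pipeline deterministic and fast on one CPU.

Sliding windows of L consecutive time steps (default L = 12, stride 1)
carry per-frame labels; windows never span scene boundaries.

## Temporal models

All three classifiers share one trunk and one joint head producing 4×3
logits per time step (softmax over the 3 states per trocar) — every frame of
the window is classified, which is the natural mode for the convolutional
model and gives the recurrent models dense supervision.

* **LSTM / GRU**: single recurrent layer, hidden width 128.
* **MS-TCN**: S stages (default 2); each stage is a 1×1 input projection,
  then ℓ dilated residual layers (default 4; kernel 3, dilation 2^l,
  symmetric zero padding, ReLU + 1×1 + residual), then a 1×1 head. Stage
  s > 1 takes stage s−1's probability output as input and refines it. The
  per-stage receptive field with kernel 3 and ℓ doubling dilations is
  1 + 2(2^ℓ − 1) frames (31 for ℓ = 4). Training supervises every stage
  (deep supervision, mean of stage losses); prediction uses the final stage.
  Stage/layer counts are package defaults, exposed in config.
* **Focal loss.** `FL(p, y) = −α_y (1 − p_y)^γ log p_y` with γ = 2 and α
  defaulting to the normalized inverse of the recorded class frequencies,
  countering the dominance of `occupied`. With γ = 0 and unit α it reduces
  exactly to cross-entropy (a test oracle). `p_y` is clamped at 1e-8 inside
  the log; padding cells (label −1, e.g. ID slots beyond the scene's trocar
  count) are excluded from the batch mean. Labels always follow ground
  truth, even on frames where the tracker's visibility disagrees with the
  annotation — the mismatch is part of what the model must absorb.
* **Training.** Hyperparameters not fixed by the problem: Adam, lr 1e-3,
  ≤ 50 epochs with early stopping on validation macro-F1 (patience 5),
  batch 32, sequence length 12. One training scene is held out for early
  stopping (window-level split when only one scene is available). Training
  is deterministic given the seed — the models and their gradients run on a
  small in-repo reverse-mode autodiff over numpy, single-threaded-safe, with
  no stochastic ops beyond seeded batch shuffling.
* **Prediction.** Probabilities of all windows overlapping a frame are
  averaged before the argmax. Frames near scene edges are covered by fewer
  window phases; streams shorter than one window are right-padded by
  repeating the last frame.

## Evaluation

Per trocar, the three states are scored one-vs-rest and macro-averaged
(micro available by option); classes absent from both truth and prediction
are excluded; F1 := 0 where P + R = 0. Cross-validation partitions whole
scenes (surgeries), never frames, into k folds of sizes differing by at most
one; reported spreads are sample standard deviations over folds (n−1
denominator — the ± convention is a documented package choice). Mean F1 is
the mean of per-fold F1, deliberately *not* the harmonic mean of mean-P and
mean-R. The same training seed is used in every fold, so identical scenes
yield identical models and zero spread. The `not_visible` class is scored
like any other.

The ablation harness retrains with the XC1 and/or XC2 block removed (the
input dimension shrinks by D per block) on the same folds and seeds, and
reports ablated − full deltas; an empty drop set yields exactly zero deltas.

### Constructed-signal ablation experiment

To demonstrate that the fusion model actually uses the distant camera, the
benchmark includes scenes engineered so XC2 is the *only* signal separating
`empty` from `occupied`: one trocar, `shaft_contrast = 0` (the two states
render identically in C1) and `c2_cue = "occupancy"` (the C2 cue fires iff
the trocar is occupied). With the full feature vector the temporal model
separates all three states almost perfectly; with XC2 dropped, `empty` and
`occupied` are indistinguishable in principle and held-out macro-F1 falls by
tens of percentage points.

## Problem sizes used in the shipped experiments

The default benchmark runs on one CPU in minutes: recovery experiments use
eight 100 s scenes (600 frames each at 6 fps; 6 train / 2 test, window
stride 2), the ablation experiment four 50 s single-trocar scenes with
2-fold CV, the tracker stability check twenty 15 s scenes with one scripted
occlusion episode each, and calibration checks a 10 000-frame timeline.
Longer scenes (the generator is O(frames)) and stride 1 are config changes.

## Numerical and degenerate-input choices

* Gated (infeasible) assignment pairs get a large finite sentinel cost; the
  Hungarian solution then maximizes the number of feasible matches before
  minimizing cost, and sentinel pairs are dropped afterwards.
* A detector frame with no above-threshold structure returns an empty list,
  never an error; empty scenes round-trip as header-only annotation files.
* Feature streams shorter than one window yield empty training sets with a
  warning; `predict` pads instead.
* All artifact formats carry schema versions; readers reject unknown
  majors and report malformed lines by line number. NPZ artifacts are
  written with fixed zip timestamps so reruns are bit-identical.
* JSON floats round-trip exactly, so truth files are lossless.

## Known limitations

* The reference detector assumes bright convex blobs on a darker
  background; it is not meant for real video (plug in a learned detector).
* The fixed random-weight encoder has no semantic invariances beyond
  illumination normalization; real deployments should plug in a pretrained
  backbone.
* Occupancy labels follow ground truth even when the tracker disagrees, so
  tracker failure modes propagate into temporal-model training as label
  noise rather than being masked.
* The simulator's C2 cue makes the two-camera fusion *demonstrably* useful
  by construction; it says nothing about how informative a real distant
  view is.
* With four independent per-trocar chains the simulator cannot express
  correlated events (e.g. instrument exchanges between ports).
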
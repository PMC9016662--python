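# Methods

## The divergence statistic

For a frame of one video, let the two groups' valid gaze positions be
`x₁…x_m` and `y₁…y_n` (screen pixels, origin top-left). Each group's centre
is its coordinate-wise mean; each member's divergence is the Euclidean
distance to their **own** group's centre, the member's own sample included.
The two distance samples are compared with a classic pooled-variance
two-sample Student *t* (two-sided, df = m + n − 2). The *position* variant
applies the same *t*-test to the raw horizontal or vertical coordinates.

Choices the method leaves open, and how this package resolves them:

- **Pooled vs. Welch.** "Student's *t*-test" is read as the textbook pooled
  test; pooled and Welch agree closely at these nearly equal group sizes.
- **Self-inclusion.** Group centres include the tested member. Leave-one-out
  centres would remove a small dependence between the distance samples but
  change the statistic's meaning; the exploratory statistics keep the plain
  definition, and the classification features avoid the leak differently
  (see below).
- **Missing data.** A frame is *testable* only if each group has at least
  `min_n = 3` valid samples (blinks, off-screen and sentinel-coded samples
  are invalid) and the pooled variance is positive. Untestable frames carry
  no *t* or *p* and are excluded from every summary.
- **α = .05, uncorrected.** Per-frame tests are exploratory markers. With
  thousands of frames per study the family-wise error is enormous by
  construction; the statistic is used to *rank and select* material, never
  to conclude significance.

Small-sample calibration: with ~20 viewers per group the distance samples
are skewed (norms of near-Gaussian deviations) and weakly dependent through
the estimated centre, so under an exact null the test flags ≈5.5% rather
than 5.0% of frames. The test suite asserts the observed rate on null
synthetic data inside a 4–6% band.

Per-video summaries report the percentage of testable frames with p < α and
the share of frames on which group A diverges more. Run-length detection
returns maximal runs of consecutive flagged frames, merging near-significant
frames (α ≤ p < `near_alpha`, default .10) into a run only when their
divergence has the same sign; runs never span a sign change, and
near-significant frames alone never start a run.

## Selection and features

Selection is computed **only from training participants**: videos whose
percent of significant frames strictly exceeds `threshold_pct` (default
10%), and/or the significant frames themselves; four regimes combine the two
choices. If no video clears the threshold the pipeline falls back to all
videos with a warning rather than emitting an empty model.

The classification feature for participant *p* and video *v* is the mean
over the included, valid frames of *p*'s distance to the **training** group
centres. Because a held-out participant has no group label at prediction
time, the default `leak_free_two_centres` mode emits two features per video
— distance to the training group-A centre and to the training group-B
centre — computed identically for training and test rows. A
`paper_faithful_own_centre` mode (one feature: distance to the participant's
own group's training centre) is retained for reproducing the original
single-feature analysis; it requires labels for all rows and mildly leaks
group information, which is why it is not the default. Cells with zero
usable frames are imputed with the training-column mean and flagged.

## Validation protocol

Participants are split 80/20, stratified by group, with per-group test
counts rounded half-up (21 + 23 participants → 4 + 5 in test). For each of
18 repetitions (seed = base_seed + r): split → frame statistics and masks
from training rows only → features for everyone → four classifiers scored
by fivefold cross-validation on training rows (fold count falls back to the
largest stratifiable value on tiny datasets) and by accuracy on the test
rows. Chance level is the majority-class share (52% for 21/23).

"Default parameters" of classification libraries are not portable, so the
hyperparameters are fixed and recorded in every report: logistic regression
(L2, C = 1, lbfgs), k-NN (k = 5), CART with cost-complexity pruning (alpha
chosen by internal fivefold CV, ties toward stronger pruning), random forest
(500 trees, √p features per split). Variable importance for the random
forest is permutation importance — mean decrease in held-fold accuracy over
5 stratified folds × 5 shuffles per column — which is
implementation-independent, unlike impurity-based importance.

## Synthetic data generator

The generator emulates a two-group video-viewing study at the scale of the
motivating design: groups of 21 and 23 viewers, 20 clips of 16 s at 30 fps
on a 1280 × 900 px display. Gaze for participant *p* at frame *t* of a video
is

    gaze_pt = a_t + w_pt + ε_pt  (+ effect terms for group B)

- **Attractor `a_t`** — one shared trajectory per video (the locus of
  attentional synchrony), a Gaussian random walk (step sd 20 px/frame)
  reflected inside a central content region (margin 15% of each screen
  dimension). The margin encodes the strong central bias of filmed content
  and of viewers' gaze; it also keeps the edge-folding of gaze samples (the
  safety net that guarantees on-screen positions) a rare event, which
  matters because folding skews the distance distribution near borders.
- **Wander `w_pt`** — a per-participant stationary AR(1) (discretised
  Ornstein–Uhlenbeck) deviation, sd 80 px, correlation time 30 frames
  (≈1 s, the time scale of fixation-to-fixation idiosyncrasy). Wander is
  what keeps per-video mean-distance features noisy between participants:
  with only i.i.d. frame noise, averaging 480 frames would shrink feature
  noise to ~σ/22 and any group effect, however small, would classify
  perfectly under every regime — unlike real data.
- **Sample noise `ε_pt`** — i.i.d. isotropic Gaussian, sd 40 px
  (oculomotor jitter plus tracker noise; ≈1° at a 65 cm viewing distance).
- **Group effect** — on designated effect videos, inside one contiguous
  window covering 40% of the frames (random position per video), group B's
  wander and noise are scaled by `dispersion_ratio` and/or its mean is
  shifted by `offset`. The window reflects that group differences in real
  footage are time-localised (specific scenes, not whole clips); it is also
  what gives frame selection something to gain: averaging over all frames
  dilutes the effect 2.5-fold while selection concentrates it.
- **Blinks** — per frame, with probability 0.01 a blink starts and lasts a
  geometric number of frames with mean 8 (~270 ms at 30 fps); blink frames
  are invalid. The gap model is memoryless because no blink statistics
  beyond "coded as missing" are assumed.

Everything is deterministic given the config seed; identical configs yield
bit-identical datasets.

What the generator does **not** emulate: saccadic main-sequence dynamics,
fixation/saccade event structure, smooth pursuit of moving targets,
calibration drift, participant-level trait differences in overall
dispersion, and stimulus-driven salience (scene cuts, faces, text). Passing
tests therefore show that the pipeline recovers dispersion-type group
differences embedded in temporally correlated, centre-biased gaze — not
that it handles every artefact of real recordings.

## Numerical and engineering notes

- Frame alignment uses index arithmetic (first sample of each frame
  period; 60 Hz → 30 fps keeps samples 0, 2, 4, …), not timestamps.
- Off-screen samples are invalidated, never clamped — clamping would drag
  group centres toward the screen edges.
- The per-frame statistics are computed vectorised (NaN-aware means and
  variances over the participant axis) for whole datasets; the scalar
  per-frame functions share the same formula and the tests cross-check the
  two paths and an independent textbook implementation to 1e-10.
- Distance-method statistics are invariant under any common rotation and
  translation of all gaze points (to floating-point tolerance); the
  coordinate convention is therefore observable only in heatmaps.
- Zero variance in one group is fine (pooled sd > 0); zero in both makes
  the frame untestable. Exact mean ties report sign "tie".
- Heatmaps: valid points are binned (default grid 160 × 112 over
  1280 × 900) and smoothed with an isotropic Gaussian of sd 40 px
  (≈1° at 65 cm), then normalised to total mass 1.
- The problem sizes used by the test suite (tiny 6–16 participant fixtures
  for unit tests; the full 21 + 23 × 20 × 480 design for the end-to-end
  checks; 18 repetitions for the validation experiments) match the
  motivating study design while keeping a complete run of the suite within
  a few minutes on one CPU.

## Known limitations

- The per-frame test is anti-conservative by ~0.5 percentage points at
  n ≈ 20 per group (self-inclusive centres, skewed distances); interpret
  percent-significant values relative to an empirical null, not to the
  nominal α.
- Selection thresholds (10% videos, α frames) are conventions, not tuned
  values; at small training sets the video selection can be unstable.
- The paper-faithful feature mode requires labels for test rows and leaks
  group information by construction; use it for reproduction only.
- With heavy blink loss (`min_n` violated on many frames) videos can become
  unsummarisable and are dropped from selection with a warning.
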
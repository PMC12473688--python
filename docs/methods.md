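# Methods

This note documents the models and procedures implemented in
`bovigait`, the tunable parameters and their defaults, what the
synthetic gait generator does and does not emulate, the numerical
choices, and known limitations.

## Coordinate conventions

All analysis runs in one canonical frame: the cow walks rightward and
the vertical axis increases upward, with the ground near zero. Raw
detections arrive in image coordinates (y down) and possibly as leftward
passages; `canonicalize` flips the vertical axis about the track-wide
maximum bounding-box bottom edge (a per-frame reference would leak box
jitter into the kinematics) and mirrors leftward passages about the
track-wide maximum right edge. Both maps are isometries, so within-frame
geometry is untouched. In this convention the head normalization
references the *lowest* hoof (nearest the ground) and the *highest*
spine point (the back line), which keeps the scaling self-consistent.
Coordinates are 0-based pixel centers; boxes are corner-coded
`(x1, y1, x2, y2)` with `x1 < x2`, `y1 < y2`. When a file does not state
the walking direction it is inferred from the sign of the median
per-frame displacement of the box center, which is robust to keypoint
noise.

Missing keypoints (occlusions) are linearly interpolated per point when
the gap is at most `io.max_gap` frames (default 3, i.e. 100 ms at
30 fps) and flagged `imputed`; longer gaps and gaps touching the track
ends stay missing, and frames that still lack a required point are
flagged invalid per indicator rather than zero-filled.

## Step detection

The head and leg indicators are only meaningful around steps, so a
stance/swing segmentation is computed per hoof: the hoof's x-speed
(central difference, then a 5-frame moving average) is compared against
`gait.speed_frac` (default 0.15) times its track-wide 95th-percentile
speed; runs of slow frames shorter than `gait.min_run` (default 3
frames at 30 fps, scaled by fps/30) are reassigned to swing. The
threshold is relative, making detection invariant to spatial scale. A
step is a swing→stance transition; its touchdown is the first stance
frame; a stance run at the very start of a track has no touchdown and
yields no step. A step's *initial phase* — the loading reference for the
head drop — is the first `ceil(0.2 × stance length)` frames of its
stance interval (`gait.initial_phase_frac`). On noiseless synthetic gait
the detector recovers the true stance boundaries within ±2 frames; the
comparison is part of the test suite.

## Indicators

**Spine curvature** is computed on the five spine points after
normalizing coordinates to the cow's bounding box. The *distance ratio*
is the chord Neck–Spine_4 over the polyline length of the chain, in
(0, 1], equal to 1 exactly for a straight monotone chain. The *angle
ratio* fits a circle to the five points — the algebraic Kåsa least
squares, minimizing Σ(x²+y²+Dx+Ey+F)², solved on centred, rms-scaled
coordinates for conditioning — then projects Neck, Spine_2 and Spine_4
radially onto the fitted circle and takes the angle at the projected
Spine_2, divided by 180°. The projection uses all five points for noise
robustness while agreeing with the raw three-point angle in the
noiseless limit; `indicators.angle_mode = raw` selects the raw angle
directly, and the raw angle is also the fallback when the fit is
degenerate (collinear points: normal-equation condition number above
1e8, or fitted radius above 10⁶ × point spread). Both ratios are
similarity-invariant, so the bounding-box normalization only matters
under noise (it rescales the two axes unequally); it is kept because the
curvature is then measured relative to the animal's apparent proportions
rather than its distance to the camera.

**Head height** uses the eye — the only cranial keypoint in the
skeleton — scaled between the lowest visible hoof and the highest
visible spine point; the value is unclamped and recorded only on frames
inside a detected step's stance window (pooled over all four hooves).
Frames where the back is not above the ground reference are flagged
invalid as anatomically implausible.

**Leg track-up distance** is the |Δx| of a same-side hoof pair divided
by cow height. Height defaults to the anatomical proxy (lowest hoof to
highest spine point); `indicators.height_mode = bbox` selects box height
instead. Because the indicator asks where the *rear* hoof lands relative
to the front hoof's print, each pair is gated on its rear hoof's
touchdowns, in a ±`indicators.leg_window` frame window (default 10 at
30 fps, scaled by fps/30).

## Aggregation

Per-frame series are collapsed per passage as follows. Smoothing is a
centred moving average (`aggregate.window`, default 5 frames ≈ 167 ms at
30 fps, odd) with reflect padding, computed over valid frames only —
invalid frames neither contribute nor receive values. Local minima are
frames below both valid neighbours; a constant plateau flanked by larger
values yields one index at the floor of its centre; endpoints never
qualify. The spine aggregate is the mean of each channel's smoothed
local-minima values (the global minimum when a short or monotone passage
has no interior minimum — the average-of-minima must still exist),
blended as `aggregate.spine_blend` × angle + (1 − blend) × distance,
default 0.5 since no canonical ratio exists. The head aggregate is the
pair (global minimum of the smoothed step-gated head height; mean over
steps of initial-phase mean minus within-stance minimum). The legs
aggregate is the per-step minimum distance in the touchdown window,
averaged over steps, then averaged over the two pairs (one pair alone is
used, with a warning, when the other has no data). Passages with no
detected steps carry `None` sentinels for head and leg features: the
expert tree then takes the healthy branch at head nodes and the grade-3
branch at the legs node (absence of evidence of pathology), and the ML
backend imputes training-fold medians.

## Scoring backends

**Expert tree.** Fixed structure: (1) head drop at or above
`theta_head_7` → grade 7; (2) spine value at or above
`theta_spine_12_36` → the 1–2 side, where at or above `theta_spine_1_2`
→ 1 else 2; (3) legs value at or below `theta_legs_3_46` → 3; (4) head
drop at or above `theta_head_45_6` → 6, else the merged 4–5 leaf.
Grades 4 and 5 are emitted as one class because they are clinically hard
to separate; the merged leaf is the ordinal 4.5 by default
(configurable), which sits within the ±1 relaxed margin of both true
grades and contributes 0.25 to the ordinal MSE. Equality always takes
the branch written above. Threshold values are farm-specific and
calibrated from labeled features: each threshold is the midpoint between
the class-conditional medians of the two grades adjacent to its split
boundary (e.g. grades 3 and 4 for the legs split), which is
deterministic and errors loudly when a side has no data. Routing is
monotone: increasing head drop never lowers the grade, increasing spine
straightness never raises it, increasing track-up shortfall never lowers
it (verified on a dense grid).

**Classical ML.** Feature vector (spine_value, head_min, head_drop,
legs_value) — the head algorithm produces two values and both are
passed. Families: decision tree, random forest, AdaBoost, gradient
boosting (backed by XGBoost, with a scikit-learn fallback), k-NN, and
SVR whose regression output is rounded half-up onto the valid grades.
Library-default hyperparameters with a fixed seed; evaluation is
leave-one-out, with per-fold median imputation so a row's own values
never enter its training fold.

**Sequence model.** Per passage, the five indicator channels are
linearly resampled onto `dl.sequence_length` = 120 uniform time points
(≈4 s at 30 fps; resampling rather than padding keeps batch shapes
static), invalid frames interpolated first. The network is three
same-padded 1-D convolutions (kernel 3, ReLU, filters 128/192/320
rising), a sequence-returning bidirectional LSTM of 256 units per
direction, a summarizing bidirectional LSTM of 512 units, and a dense
softmax over the 7 grades; categorical cross-entropy with Adam
(lr 1e-3, batch 16, 30 epochs, dropout 0.1 after the first recurrent
layer). Inputs are standardized per channel with training-set statistics
stored in the model. The network is implemented directly on numpy with
hand-derived backpropagation, validated against finite-difference
gradients in the test suite; training is deterministic given the seed.
Time-series augmentation (Gaussian jitter, optional moving-average
smoothing, random time-point dropout with linear re-interpolation) is
available and seeded. Default evaluation at desk scale is a held-out
split; leave-one-out retraining is supported but costly.

## Metrics

Balanced accuracy (unweighted mean per-true-class recall), relaxed
accuracy (|pred − true| ≤ 1), ordinal MSE, and class-frequency-weighted
recall/precision for the 7-grade task — the precision of a class never
predicted counts as 0, logged, so degenerate predictors stay scoreable.
The binary protocol maps 1–3 → healthy, 6–7 → lame and excludes grades
4–5 (lowest inter-observer agreement); it reports plain and balanced
accuracy and positive-class (lame) recall/precision. Inter-rater
agreement uses unweighted Cohen's kappa — grade tolerance is already
carried by relaxed accuracy — with κ = 1 by convention when both raters
are constant and identical. All metrics are implemented directly so the
merged 4.5 ordinal is handled uniformly; scikit-learn implementations
are the independent oracle in the tests.

## Synthetic gait generator

The generator emulates a single cow crossing a 960×540 px field of view
at 30 fps: back height 270 px, spine chord 360 px, walking speed
8 px/frame, stance = swing = 15 frames (a 1 s stride), four gait cycles
per passage by default, Gaussian keypoint noise of 2 px, and a tight
per-frame box with a 5 px margin. Three signals scale with grade 1–7:
arch sagitta as a fraction of the spine chord (0.00, 0.02, 0.05, 0.08,
0.11, 0.14, 0.18), head-bob amplitude as a fraction of cow height (0
below grade 6, then 0.08 and 0.25), and the track-up shortfall of the
affected rear hoof as a fraction of height (0.00, 0.02, 0.06, 0.12,
0.18, 0.26, 0.35). These maps are calibration constants of the
simulator, not claims about real cows. The affected limb is BR by
default (configurable to BL); one affected limb suffices to create the
designed signals.

Two design choices make the generator a sharp oracle on noiseless data.
Limbs are phased as diagonal pairs (FR+BL together, FL+BR together), so
every hoof touches down at the same phase modulo a half-cycle, and the
rear hoof lands exactly when its same-side front hoof lifts off — the
minimum same-side hoof gap within a rear-touchdown window then equals
the injected shortfall exactly. The head dip is a flat-bottomed pulse
once per half-cycle (trough mid-stance of the affected limb, zero within
two frames of every touchdown), so after the default 5-frame smoothing
the per-step drop equals the injected amplitude exactly. A real cow bobs
once per stride rather than per half-cycle and walks with four-beat
phasing; the generator trades that realism for exact recoverability.

What the generator does not emulate: perspective and lens distortion,
detector confidence structure (noise is isotropic Gaussian, real pose
errors are heavy-tailed and correlated), occlusions and missing points
(all points are emitted visible; the gap-interpolation path is tested on
constructed tracks), multi-cow interactions, speed/stride variability
within a passage, and label noise. Passing tests on synthetic cohorts
therefore demonstrate that the pipeline recovers the signals it is built
to measure, not field performance on farm video.

A consequence of noiseless replication worth flagging: all passages of a
grade simulated with zero keypoint noise are bit-identical, so a
70-passage noiseless cohort carries only 7 distinct sequence matrices.
For the sequence model's permuted-label control this matters — with so
few distinct inputs, a *single* label shuffle retains high-variance
residual input-label association (Monte Carlo of the shuffle null puts
roughly 3% of single-draw held-out accuracies above 0.45 even though the
null mean sits at chance, ≈0.14). The control is therefore computed as
the mean over three independent label shuffles, a lower-variance
estimator of the same no-signal accuracy, and is asserted against the
unchanged band.

A known estimator effect, visible in the noisy-cohort tests: at a
perfectly straight spine the angle ratio is at its upper bound, so
keypoint noise can only bend the apparent spine away from 180°, and the
minima-based aggregation preferentially samples those frames. Grade-1
passages therefore score slightly *below* grade-2 passages under 2 px
noise (both remain far above grade 3). The rank correlation between
grade and spine value stays ≥ 0.95 in magnitude, the learners are
unaffected (the inversion is consistent), and noiseless calibration of
the expert tree is unaffected; threshold calibration on noisy cohorts
would need to account for it.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale cohorts chosen to
exercise every code path: 20 passages per grade with 2 px noise for the
monotonicity and leave-one-out checks, 5 per grade noiseless for
expert-tree calibration, and 70 passages (10 per grade, noiseless,
sequence length 120, 30 epochs) for sequence-model smoke training with a
permuted-label control. Every source of randomness flows from explicit
seeds (per-passage seeds are derived from (seed, grade, replicate) via
`numpy.random.SeedSequence`), pipelines are pure functions of (inputs,
config, seed), and reruns produce byte-identical prediction files.
Indicator values are reproducible across platforms to 1e-9.

## Limitations

The pipeline consumes keypoint tracks; detector and pose-estimation
quality is out of scope, as are multi-cow association, free-range
scenes, and real-time constraints. The expert-tree thresholds shipped by
calibration on synthetic data are not farm thresholds. Sequence-model
hyperparameters (layer count within the stated filter range, learning
rate, dropout placement, epochs, batch size) are documented defaults,
not tuned optima. Per-limb lameness lateralization, stride-length and
speed traits, and confidence intervals on the aggregates are not
implemented.
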
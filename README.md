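# bovigait

Locomotion scoring of dairy-cow lameness from video keypoint tracks.

Lameness is among the costliest cattle diseases, and the standard
detection method — visual locomotion scoring by trained assessors — is
slow and subjective. `bovigait` implements the analysis stages of an
automated side-view video pipeline *downstream of the vision models*: it
consumes per-frame detections of a single cow crossing the field of view
(a bounding box plus 22 named anatomical keypoints per frame, as a
detector/pose-estimator stack would produce) and scores lameness on a
7-grade ordinal scale (a half-step refinement of the 5-level Sprecher
locomotion score) or a binary healthy/lame scale.

The package is aimed at researchers in precision livestock farming who
have keypoint tracks and want interpretable gait indicators and
reproducible scoring backends, without access to any particular farm's
raw video.

## Method

Three veterinary-motivated indicators are computed per frame from the
canonicalized track (cow walking rightward, y up):

* **Spine curvature.** With the five spine points p₁..p₅ (Neck,
  Spine_1..Spine_4) normalized to the bounding box, an *angle ratio*
  θ/180° — where θ is the angle at Spine_2 between rays to Neck and
  Spine_4, read off a least-squares (Kåsa) circle fitted to the spine —
  and a *distance ratio* ‖p₅−p₁‖ / Σᵢ‖pᵢ₊₁−pᵢ‖. Both equal 1 for a
  straight back and fall as the arch deepens.
* **Head height.** h = (y_eye − y_ground)/(y_back − y_ground) with
  y_ground the lowest hoof and y_back the highest spine point, evaluated
  only while a step is in stance. Severe lameness shows as a per-step
  drop of h phase-locked to loading of the affected limb.
* **Leg track-up distance.** |x_front hoof − x_rear hoof| / cow height
  for the same-side pairs FR–BR and FL–BL, read in a ±10-frame window
  around rear-hoof touchdowns. A sound cow steps into the front hoof's
  print; the shortfall grows with lameness.

Steps are detected from hoof-speed stance/swing segmentation. Per
passage, the indicator series are smoothed, minima-aggregated and fed to
three interchangeable scoring backends: a rule-based expert decision
tree with calibratable thresholds, classical learners
(decision tree, random forest, AdaBoost, gradient boosting/XGBoost,
k-NN, SVR) under leave-one-out validation, and a CNN-BiLSTM sequence
classifier over the per-frame series (three kernel-3 convolutions of
128–320 filters, a sequence-returning 256-unit and a summarizing
512-unit bidirectional LSTM, softmax over the 7 grades; implemented
directly on numpy). Scoring uses balanced accuracy, relaxed (±1 grade)
accuracy, ordinal MSE, weighted recall/precision and Cohen's kappa;
the binary protocol maps grades 1–3 → healthy, 6–7 → lame and excludes
the borderline grades 4–5.

A synthetic gait simulator generates 22-keypoint passages with
grade-controlled pathology (back-arch sagitta, head-bob amplitude,
track-up shortfall) and known ground truth, so every stage is testable
offline. See `docs/methods.md` for modelling details and limitations.

## Worked example

```bash
bovigait simulate --n 3 --seed 3 --noise-sigma 0 --out data/
bovigait pipeline --tracks data/ --backend expert --out run/
```

which prints the evaluation report of the expert backend on the 21
simulated passages (3 per grade, noiseless):

```json
{
  "task": "grade7",
  "balanced_accuracy": 0.7142857142857143,
  "accuracy": 0.7142857142857143,
  "recall": 0.7142857142857142,
  "precision": 0.7142857142857142,
  "n_evaluated": 21,
  "n_excluded": 0,
  "relaxed_accuracy": 1.0,
  "mse": 0.07142857142857142
}
```

Every passage lands within half a grade of its label (relaxed accuracy
1.0, MSE = 6·0.5²/21): the six grade-4 and grade-5 passages are emitted
as the merged 4–5 class (ordinal 4.5), which the exact-match metrics
count as misses — hence 15/21 exact accuracy — while all other grades
route to their own leaf. The same stages are available as library calls
(`simulate_passage`, `compute_indicator_series`, `build_features`,
`classify_expert`, `fit_predict_loo`, `train_cnn_bilstm`, `evaluate`).

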
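# Methods

This note records the models, algorithms and design choices behind
`measurenet`, in the spirit of a statistical software methods appendix. The
toolkit is fully synthetic and self-contained: it generates its own bodies,
images and ground truth, trains an image-based regressor for body
circumferences and waist-to-hip ratio (WHR), and evaluates it with the
agreement statistics standard in digital anthropometry.

## 1. Procedural body model

Real pipelines in this area fit a licensed statistical body model (e.g. SMPL)
to laser scans. This package instead uses a **generalized-cylinder body**: a
stack of elliptical cross-sections with smoothly varying semi-axes for the
torso, each leg, each arm and the neck, plus an ellipsoidal head, assembled in
a canonical frame (y up, feet at y = 0) in an A-pose with 20° shoulder
abduction. Each of the seven solids is a closed triangulated surface; the
solids interpenetrate at the joints, so mesh closure holds per connected
component.

The parameterization was chosen so that ground truth is *analytic*: a named
circumference (hip, waist, chest at fixed normalized heights 0.53/0.63/0.72;
thigh and calf on the left leg at 0.46/0.18; bicep at 22% down the left arm
axis) corresponds to an elliptical cross-section whose width semi-axis `a`
and depth/width aspect `ρ` give a Ramanujan perimeter

    P(a, ρ) = π a [ 3(1+ρ) − √((3+ρ)(1+3ρ)) ].

`shape_from_measurements` inverts this in closed form at fixed per-part `ρ`
(default 0.75, per-subject jitter sd 0.04), and mesh stations are inserted
exactly at the landmark heights, so a built mesh realizes requested
circumferences up to the polygonal approximation of the ellipse: about 0.07%
at 48 angular segments, 0.13% at the 36 segments used for bulk dataset
generation — an order of magnitude inside the 1% round-trip tolerance.
Between control stations the semi-axis profile is monotone-cubic (PCHIP), so
changing the waist control leaves the hip value exactly pinned.

Body weight is derived from the mesh itself (volume via the divergence
theorem, summed over closed components, times a whole-body density of
985 kg/m³), which keeps the height/weight/sex scalars consistent with the
geometry the camera sees.

## 2. Population model and cohort sampling

A `PopulationSpec` holds sex-specific marginals for height (normal) and for
weight and the six circumferences (log-normal, moment-matched), coupled by a
Gaussian copula with a shared "size" factor (equicorrelation 0.55 among
girths and weight, 0.30 for height). Defaults give mean WHR ≈ 0.90 for men
and ≈ 0.85 for women — the magnitudes reported for North American adult
cohorts — with WHR sd ≈ 0.12. The observed spread in clinic datasets
(≈ 0.20) is reachable by widening the waist/hip marginals; it is a
configuration knob, not a default.

Cohort generation mirrors the bootstrap-and-match recipe used with scan
libraries:

1. sample a measurement table from a *scan population* (the target with waist
   +5%, hip −2%: an opportunistic library is never exactly the population you
   want);
2. fit a sex-specific Gaussian mixture over the 8-dimensional measurement
   space, choosing the component count by BIC (full covariances by default,
   covariance floor 1e-6 for degenerate clusters);
3. **importance-sample** the mixture toward the target: self-normalized
   weights w ∝ target density / mixture density with the target taken as the
   product of its marginals, followed by multinomial resampling. An effective
   sample size below 10 raises an error naming the most discrepant marginal.

The proposal pool is 8× the requested cohort size. With the default specs the
resampled cohort matches target marginal means within ~1% at n = 10,000.

## 3. Virtual tape measure

A physical tape pulled taut bridges concavities, so a tape circumference is
defined as the **perimeter of the 2D convex hull** of the body cross-section
in the measurement plane. Slicing is an exact vectorized triangle/plane
intersection over label-filtered faces; unordered crossing segments are
chained into closed loops, each loop carrying the label that contributes the
greatest intersected length. Planes that would pass through mesh vertices are
nudged by 1e-7 of the bounding-box diagonal along their normal (deterministic,
and far below measurement tolerances). Loop selection is by label group and
descending enclosed area, which disambiguates multi-loop slices near the
crotch and armpits. Torso and leg planes are horizontal; arm planes are
perpendicular to the arm's medial axis, as in manual anthropometry.

The **dense profile** comprises 112 rings: 56 on the torso spanning
hip-to-chest ± 20% (clamped inside the torso), 20 per leg spanning
calf-to-thigh, and 8 per arm from the bicep station down. The grids are
constructed piecewise so the six named stations are grid points; the named
and dense values at a shared station come from the same computation.

Geometry is carried in meters; circumferences are reported in millimeters.

## 4. Capture simulation

Cameras are sampled per view (front / side / back = 0°/90°/180° azimuth)
with orientation offsets uniform in ±15° about each axis, distance
2.3–3.2 m, optical-center height 0.85–1.55 m and focal length 0.82–1.10 of
the image size, rejection-sampled until the crown and both knees project
strictly inside the frame (the head-to-knees validity rule). Rendering is a
pinhole projection with a depth-buffered rasterizer that writes per-face
part labels directly — the regressor's input is the segmentation label map
itself, deliberately free of lighting, texture and background information;
background is class 0 of a 23-class taxonomy (head, neck, four torso bands,
shoulders, hip junctions, upper/lower limbs, hands, feet). Renders are
deterministic: fragments are stably sorted far-to-near.

A *repeatability session* re-renders one body with fresh cameras and a ±3°
shoulder-pose jitter; targets are extracted once from the canonical-pose
mesh, so a session measures capture-induced prediction spread only.

## 5. The regressor

Each view is one-hot encoded over the 23 classes and featurized by a small
residual convolutional backbone (5×5 stride-2 stem, three stride-2 residual
blocks with squeeze-excitation channel gates; Swish activations throughout —
at initialization the fraction of hidden units with zero local gradient is
0% for Swish vs ≈ 50% for ReLU). Two ingredients proved important at desk
scale:

* **Body-centric cropping**: each label map is isotropically rescaled so the
  body's vertical extent fills the frame before encoding. This removes the
  camera's distance/focal scale ambiguity (a pixel width then corresponds to
  a physical width via the subject's known height) and spends the full 64×64
  resolution on the body.
* **A per-view profile branch**: row sums of the one-hot image per class — a
  fixed anisotropic pooling — converted to meters with the subject height and
  passed through a linear layer. This hands the trunk well-conditioned width
  evidence that a strided backbone represents only diffusely at this size.

Per-view features (convolutional + profile) are concatenated with normalized
height, weight and sex and passed through a four-block residual
fully-connected trunk, a single-head self-attention block over six learned
feature tokens, and task heads: the 112-ring dense profile, the six named
circumferences, WHR by direct regression, WHR by soft-binned classification
(60 bins on [0.6, 1.2], cross-entropy against a two-bin linear soft target,
decoded as the expectation over bin centers), and a 9-dimensional shape
vector (six landmark semi-axes + three aspect ratios) that acts as a
regularizer and as the decoder input for the reconstruct-then-measure
baseline. Optional pose and camera heads are available as additional
regularizers and are off in the default configuration. The default model has
~0.5 M parameters on 64×64 inputs.

The total loss is the uncertainty-weighted multi-task sum

    L_total = Σ_i  L_i / w_i + log(1 + w_i),      w_i = softplus(θ_i) > 0,

with one learned weight per task, so relative task importance is tuned by
gradient descent rather than by hand. Training uses Adam (base rate 2e-3,
cosine decay to 10%, decoupled weight decay 1e-4 on kernels) on a compact
reverse-mode automatic-differentiation engine written for this package
(dense numpy tensors, im2col convolutions through BLAS); every operation is
gradient-checked against central finite differences in the test suite.
Training is bit-deterministic given the config seed. Divergence (a
non-finite task loss) aborts training and restores the last epoch-end
checkpoint.

**WHR ensemble.** The final WHR is the mean of three members: the regression
head, the classification-head expectation, and the ratio of the predicted
named waist and hip. A non-positive predicted hip drops the ratio member
with a warning. Because a freshly trained classification head is typically
under-confident at desk scale, its raw expectation decode is shrunk toward
the prior mean — which would both bias the ensemble and understate that
member's true spread — so after training the head is calibrated on the
training set: standard temperature scaling (one scalar minimizing the
soft-binned cross-entropy) followed by an affine debias of the decoded value
(least squares of the training WHR on the decoded expectation). No held-out
data is used. Averaging helps the ensemble only to the extent that member
noise is decorrelated; at desk scale the members share one trunk, so their
render-to-render noise is strongly correlated and the ensemble's session
repeatability hovers at, rather than clearly below, the best member's.

**Prediction modes.** `direct` reads circumferences off the regression
heads. `shape-decode` decodes the predicted shape vector to a mesh and tape-
measures it — the reconstruct-then-measure baseline that direct prediction
is expected to beat (reconstruction squeezes the answer through a low-
dimensional bottleneck first).

**Sex-specific models.** One model per sex is the default; examples are
routed by their sex label at prediction time.

## 6. Evaluation statistics

* Accuracy: MAE = Σ|G−P|/n, MAPE = (100/n)·Σ|G−P|/|P| — the prediction in
  the denominator, kept exactly as the source formulation prints it, though
  the ground truth would be the conventional choice — and P90, the 90th
  percentile of absolute errors (linear interpolation between order
  statistics by default; nearest-rank available).
* Repeatability: per session, deviations |pred − session mean|, pooled over
  sessions; reported as mean and P90.
* Noise: paired repeat measurements are differenced in both directions
  (d and −d), which forces a zero-mean sample by construction; a zero-mean
  Gaussian density is least-squares fitted to the Freedman–Diaconis
  histogram and its σ reported alongside the plain sample sd.
* Agreement: Bland–Altman bias = mean(P−G) with 95% limits at ±1.96 sample
  sd (ddof = 1).

All of these are checked against independent brute-force implementations in
the test suite.

## 7. Desk-scale protocol and problem sizes

The package's reference experiment (also what `scripts/acceptance.py` runs)
is a parameter-recovery study on synthetic cohorts, scaled to a single CPU:

* training cohort 650–800 subjects (one sex) at 64×64, three views, 12–15
  epochs (the full-scale protocol this emulates uses a few thousand subjects
  and ~10 epochs; accuracy improves monotonically with both);
* held-out cohort 150–160 subjects, accuracy from one render per subject;
* repeatability over 8-render sessions on 16–18 held-out subjects;
* success is measured relative to the cohort's own spread: a useful
  regressor must beat the cohort-mean predictor decisively (MAE well below
  the cohort sd; the package targets MAE < 0.5 sd per measurement).

What the synthetic protocol does and does not show: it exercises the full
geometry-to-image-to-regression loop with exact ground truth, so it validates
the method's machinery (shape recovery from segmentations, multi-task
training, ensemble behavior, repeatability accounting). It does not model
clothing, segmentation-network errors, lighting-dependent segmentation
drift, real camera optics, or the synthetic-to-real domain gap, so passing
desk-scale recovery bounds says nothing quantitative about accuracy on real
photographs.

Known desk-scale limitations:

* At 64×64, thin parts (calf and bicep are ~4–5 px wide) are strongly
  quantized. The calf combines the fewest pixels with the smallest cohort
  coefficient of variation (≈ 7.6%), so its recovery ratio sits near the
  information limit of a single render (a linear probe given ideal
  scale-corrected per-class width profiles plateaus around MAE ≈ 0.6 × sd)
  and it is the one measurement that does not beat the 0.5 × sd bar.
* The direct-vs-reconstruct comparison is nearly a tie here by construction:
  the procedural body's 9-dimensional shape vector determines the six named
  circumferences almost exactly, so decoding it to a mesh imposes hardly any
  bottleneck — unlike a full statistical body model, where reconstruction
  compresses through global shape space and direct prediction wins clearly.
  At desk scale the direct/decode MAE ratio therefore scatters around 1.0.

## 8. Numerical choices and degenerate inputs

* Covariance floor 1e-6 in mixture fits; BIC over k = 1..max_clusters with
  3 EM initializations per k, seeded.
* Importance-sampling ESS guard at 10; all-zero weights raise the same
  marginal-naming error.
* Slicing tolerance: endpoints quantized at 1e-9 of the bbox diagonal when
  chaining loops; open chains (non-closed meshes) raise.
* Convex hulls via scipy's Qhull on the 2-D projection; loops with < 3
  points fall back to the raw polyline length.
* Camera sampling gives up after 1,000 rejections with a geometry report.
* The rasterizer's far-to-near stable sort makes z-fighting deterministic.
* All randomness flows through explicit numpy Generators; the CLI fans a
  single master seed out to per-stage streams by hashing stage names.
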
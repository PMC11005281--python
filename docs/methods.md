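# Methods

`limbalign` measures lower-limb alignment from anteroposterior long-leg
radiographs (LLRs) the way a surgeon does: locate ten anatomical landmarks
per limb, connect them into axes and joint lines, and read off five
clinical angles. The package contains the full pipeline — a landmark
detector, the angle geometry, a synthetic phantom generator with exact
ground truth, and the agreement statistics used to compare automatic
against manual measurements.

## Landmarks and angle constructions

Ten landmarks per limb (v1 femoral head centre, v2 femoral diaphysis
centre, v3/v5 lateral/medial femoral condyle, v4 knee centre femoral side,
v6/v8 lateral/medial tibial plateau, v7 knee centre tibial side, v9 tibial
diaphysis centre, v10 ankle centre). The axes are the only two-point
constructions the landmark set supports:

| measure | construction | convention |
|---|---|---|
| HKA | femoral mechanical axis v1→v4 vs tibial mechanical axis v7→v10 | signed; varus (knee apex lateral) negative |
| JCLA | femoral joint line v3–v5 vs tibial joint line v6–v8 | signed; medial convergence (lateral opening) positive |
| AMA | femoral shaft axis v2→v4 vs mechanical axis v1→v4 | unsigned |
| mLDFA | lateral angle, femoral mechanical axis vs femoral joint line | interior angle in (0, 180) |
| mMPTA | medial angle, tibial mechanical axis vs tibial joint line | interior angle in (0, 180) |

All geometry is computed in image coordinates (y down). Lateral/medial are
resolved from the `side` label, never from the x-ordering of landmarks, so
a mislabelled side fails loudly instead of silently flipping mLDFA/mMPTA.
On a conventionally displayed AP radiograph the patient's left limb appears
on the image right; lateral is +x for a left limb and −x for a right limb.
The alignment classes use inclusive boundaries: varus iff HKA ≤ −2°,
valgus iff HKA ≥ +2°.

v9 participates in no angle; it is detected and scored (its radial error
enters the MRE) but unused by the five measures, mirroring how such
landmark sets are evaluated in practice.

### The closure identity

The five angles are not independent. Writing the femoral/tibial mechanical
axis tilts and the two joint-line inclinations as four free directions, the
map to (HKA, JCLA, mLDFA, mMPTA) has rank 3 and forces

    JCLA = mMPTA − mLDFA − HKA

in this package's sign conventions. The phantom generator therefore draws
HKA, AMA, mLDFA and mMPTA and derives JCLA from the identity; a
`PhantomSpec` with an inconsistent JCLA is rejected at construction.
Clinically the identity loads severe HKA deformity onto joint-line
convergence, which is consistent with joint-space collapse dominating
late-stage osteoarthritic varus.

## Heatmap codec

Landmarks are encoded as 2D Gaussians, `exp(−((x−xk)² + (y−yk)²)/(2σ²))`,
σ = 2 heatmap pixels by default, truncated beyond 3σ and peak-normalised so
every in-frame channel attains exactly 1 at the grid point nearest the
landmark (peak-1 normalisation, not unit mass). Out-of-frame landmarks get
an all-zero channel and a cleared visibility flag, never an exception.

Decoding takes the per-channel argmax (first in row-major order on ties)
and shifts a quarter pixel towards the strictly larger neighbour along each
axis. For a peak-1 Gaussian this bounds the round-trip error by 0.25 px
per axis (0.36 px Euclidean) anywhere in the sub-pixel unit cell; the
refinement can be disabled to recover the bare argmax.

Edges between landmarks are encoded as unit direction vectors
`(p_b − p_a)/‖p_b − p_a‖`; degenerate edges yield the zero vector with a
flag. The supervised edge set is the skeleton chain v1–v2–v4, v4–v3,
v4–v5, v7–v6, v7–v8, v7–v9–v10 plus the trans-articular link v4–v7 —
every angle-defining segment appears — and is configurable.

## Detector

A two-branch network over a two-stream backbone: after a stride-2 stem, a
high-resolution stream (1/2 scale, width `w`) and a low-resolution stream
(1/4 scale, width `2w`) run in parallel and exchange information in
`n_stages` fusion stages (low→high by 1×1 projection + nearest upsampling,
high→low by stride-2 convolution), so high resolution is maintained
throughout rather than recovered at the end. A 1×1 head predicts the K=10
heatmaps at 1/2 scale; a global-pooling + dense head predicts one unit
vector per supervised edge. The edge branch acts as a geometric
consistency constraint during training only; inference uses the heatmaps
alone. Two normalised coordinate channels are appended to the input so the
small backbone can resolve landmarks that are positionally defined but
locally ambiguous (the diaphysis centres look identical anywhere along the
shaft).

The network is written in NumPy (im2col convolutions over BLAS matmul,
hand-written backward passes verified against numerical differentiation,
Adam). Both output heads are zero-initialised so training starts from the
all-zero background prediction regardless of seed; this removes
init-dependent spurious peaks that can permanently trap individual
landmark channels at desk-scale step budgets. Training is fully seeded:
the same seed reproduces the loss curve bitwise.

**Loss.** Squared error on both branches. The heatmap term is
peak-weighted, `mean((1 + β·target)·residual²)` with β = 80: plain MSE
over the overwhelmingly zero background leaves the Gaussian peaks
essentially unlearned at desk-scale step budgets (a few hundred Adam
steps), converging to the dataset-mean blob. The edge term is plain MSE
scaled by `edge_loss_weight` (default 0.1); setting it to 0 recovers pure
heatmap regression.

**Preprocessing.** Bilinear resample to the model frame — to the target
physical spacing (0.79 mm/px at the reference operating point) when the
source spacing is known, to fit otherwise (portable-photo mode) — centred
with zero padding, intensities standardised per image. The affine between
original and model coordinates is recorded and exactly invertible. Angles
are scale-invariant, so unknown-spacing inputs still yield valid angles;
radial errors are then only reportable in model pixels.

**Operating points.** The full-scale reference configuration is
640×320 input, width 32, 200 epochs, batch 32, lr 1e−3 stepped to 1e−4 and
1e−5 at epochs 120 and 170. The package's tests and acceptance runs use
`DetectorConfig.tiny()`: 128×64 input, width 16, 3 fusion stages, 30
epochs, batch 2 (small batches buy more Adam steps inside the epoch
budget), lr 2e−3 stepped at epochs 24 and 28 — sized so a full
train/evaluate cycle completes in a few minutes on one CPU core.

**Augmentation.** Horizontal flip with lateral↔medial relabelling
(v3↔v5, v6↔v8), ±5° rotation (image and landmarks transformed with the
same affine), ±10% intensity scaling, mild Gaussian noise; each
toggleable. **Detection.** A limb counts as not-detected when any
landmark's peak confidence falls below `detection_threshold` (default
0.3), or when the decoded points are anatomically implausible — vertical
limb topology violated, condyle or plateau pairs not straddling their
knee-centre landmark, diaphysis centres outside their bone segment. This
is reported as a value, never raised, mirroring how unidentifiable joints
are excluded and counted in clinical evaluation.

## Phantom generator

The generator emulates the study conditions the pipeline is meant for:
per-limb AP LLR crops of knee-OA cohorts. Alignment class is drawn with
weights 54.5% varus / 30.7% neutral / 14.8% valgus; HKA uniform within the
class band (varus −12…−2°, neutral −2…2°, valgus 2…12°); AMA ~ N(6°, 1°),
mLDFA ~ N(88°, 1.5°), mMPTA ~ N(87°, 1.5°) (conventional normative
centres), each clipped to plausible ranges; JCLA from the closure
identity; 35.8% of joints carry a knee prosthesis (rendered as
high-intensity implant silhouettes replacing the condylar margins).
Default sensor noise sd is 0.02 on the [0,1] intensity scale.

Landmarks are placed by inverting the angle definitions (the HKA deformity
split evenly between femoral and tibial axis tilt), then bones are drawn
as capsule/disc silhouettes around them. `measure_limb` on the returned
landmarks reproduces the spec angles to well under 0.01°, which ties the
generator and the measurement engine together as mutual oracles.

"Photo" capture mode emulates re-photographing film with a handheld
device: a rigid similarity pose jitter (rotation ≤ 2°, small translation)
applied identically to pixels and landmarks — similarity transforms
preserve relative angles, so the ground-truth angles are untouched —
plus vignetting, mild blur and sensor noise. A projective (perspective)
jitter was deliberately not used: it would change the ground-truth angles
and break the generator-measurement closure; at tripod-like capture
distances the perspective component is small compared to the pose jitter
modelled.

What the phantoms do **not** emulate: anatomical bone morphology,
osteophytes and joint-space narrowing texture, exposure inhomogeneity,
bilateral full-pelvis scenes. Passing desk-scale tests therefore
demonstrates that the pipeline's machinery is correct and trainable, not
that the tiny model reaches clinical accuracy on hospital radiographs.

## Evaluation statistics

* MRE = (1/n)·Σ Rᵢ over the Euclidean landmark errors Rᵢ, unit-tagged
  (model pixels, optionally converted to mm via the pixel spacing).
* MAD = mean |prediction − reference| per angle, reported with the sample
  standard deviation of the absolute differences.
* AD rates: fraction of limbs with |difference| strictly below 1° and 2°
  (differences above 2° being the conventional bar for clinical
  relevance).
* Bland–Altman: bias = mean signed difference; 95% limits of agreement =
  bias ± 1.96·sd with the n−1 sample standard deviation.
* Pearson chi-square on accuracy/inaccuracy contingency tables without
  continuity correction (scipy's `chi2_contingency`), p from the upper
  tail; no multiplicity adjustment.

## Numerical choices and edge cases

* Angle kernel: `atan2(cross, dot)` in (−180°, 180°]; zero-length
  directions raise a geometry error naming the degenerate axis.
* Heatmap decode ties break to the first maximum in row-major order.
* Degenerate edges are flagged, not raised; out-of-frame landmarks clear
  the visibility flag, not raised.
* A constant image cannot be standardised and is rejected at
  preprocessing.
* The uniform-prediction MRE baseline (used to judge whether a trained
  model is informative) is computed exactly as the mean distance from each
  true landmark to every pixel centre of the model frame — the expected
  error of a predictor that picks a uniformly random pixel.

## Known limitations

* The desk-scale detector is a demonstration of the training and
  measurement machinery; its accuracy on real radiographs is untested and
  the full-scale operating point is untrained here.
* Single-limb crops only; the full-frame two-limb variant is out of the
  tiny model's scope.
* The phantom cohort draws mLDFA/mMPTA independently of HKA, so severe
  deformity loads onto JCLA (see the closure identity) rather than being
  distributed across bone deformity as in some real cohorts.
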
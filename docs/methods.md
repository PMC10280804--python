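# Methods

`cardiomotion` forecasts the apparent 2D motion of contrasted vascular
structures in X-ray-angiography-like image sequences. The motion of the
visible tree between consecutive frames is summarized as a single 2D
affine transform, the sequence of transforms becomes a 6-channel time
series, and a small recurrent network trained on the first part of one
sequence predicts that same sequence's future transforms. Everything is
patient-specific (per-sequence): no pooling across sequences, no
pretraining.

## Motion representation

All geometry uses points `(x = column, y = row)` with the origin at the
top-left pixel centre and homogeneous 3×3 matrices acting on column
vectors `(x, y, 1)ᵀ`. A geometric parameterization with scales
`(s_x, s_y)`, rotation `θ` about a centre `(c_x, c_y)` and translation
`(x, y)` maps to the six free entries

```
A00 = s_x cos θ     A01 = s_y sin θ
A10 = −s_x sin θ    A11 = s_y cos θ
Tx  = x − c_x s_x cos θ − c_y s_y sin θ
Ty  = y + c_x s_x sin θ − c_y s_y cos θ
```

The per-frame transformation-parameter (TP) vector is
`(Tx, Ty, A00, A01, A10, A11)`; row `t` of a TP series is the transform
mapping frame `t` onto frame `t+1` (motion forward in time). The reverse
direction is available via a flag on `register_sequence`. Recovered
matrices are *not* decomposed back into `(s_x, s_y, θ)` — the
decomposition is non-unique once shear is present, and every downstream
consumer needs only the six raw entries.

**Learning origin.** The pipeline re-expresses transforms about the image
centre before building the TP series (`tp_origin="image_center"`;
conjugation by the centre translation, linear part unchanged). About the
remote top-left origin, a rotation/scale perturbation of order `ε`
produces a compensating translation of order `ε·‖c‖` (tens of pixels),
so registration noise in the linear entries aliases into enormous,
anti-correlated `Tx, Ty` noise that poisons both the normalization
factors and the forecaster. Predictions are mapped back to the global
convention before any geometric scoring, so the CSV schemas and the
evaluation contract are unaffected.

## Segmentation and centerline extraction

Per frame: multiscale Frangi vesselness (Hessian-eigenvalue tubularity)
with scales σ ∈ [1, 6] px in steps of 0.1, `β = 0.5`, and the
structureness constant `c` set per scale to half the maximum Hessian
norm; the response is thresholded at 2% of its per-frame maximum,
8-connected components below 64 px are dropped, and the mask is thinned
to a one-pixel skeleton whose foreground pixels form the centerline
point set. Vessels are assumed bright-on-dark (the simulator's
polarity); a flag inverts for raw angiography. All parameters are
per-sequence configurable, since vessel calibre and contrast vary
between acquisitions. The 2% threshold was calibrated so the mask covers
the rendered tube (Dice ≥ 0.9 against the quarter-amplitude isophote of
the noise-free rendering) while the skeleton stays within ~0.4 px of the
true polylines.

## Affine coherent point drift

Consecutive centerline point sets are registered with the affine variant
of coherent point drift: the source set parameterizes Gaussian-mixture
centroids moved by an affine map `B, t`, the target set is data, and a
uniform outlier class of weight `w` (default 0.1) absorbs spurious
points. EM alternates soft correspondence with closed-form weighted
least-squares updates of `B, t` and the shared variance σ².

Three numerical choices matter; all were driven by failure modes
observed on skeleton data:

1. **Coordinate normalization.** Both sets are shifted to zero mean and
   scaled by the target RMS radius before EM (transform denormalized
   afterwards). Without this, any `w > 0` lets the uniform class swallow
   the probability mass while σ² is large.
2. **Bounded annealing.** σ² may shrink by at most a factor
   `anneal_rate = 0.9` per iteration. The unconstrained ML update lets
   σ² collapse onto a correspondence slid by one sample along a
   uniformly spaced curve — a self-consistent local optimum that even
   hard-assignment (ICP-style) polishing cannot escape. Since the capped
   value still lies on the descent side of the likelihood in σ², the
   objective remains monotonically non-increasing (asserted in tests).
3. **Coarse-to-fine gating.** While normalized σ² > 0.0625 (σ larger
   than ¼ of the target RMS radius), only the translation is updated.
   With near-uniform responsibilities the unconstrained affine M-step
   collapses the model set to a near-singular squash, from which EM
   anneals into reflected local optima; only the coarsest degrees of
   freedom are identifiable at high blur.

Convergence: relative objective change below 1e−8 once annealing is no
longer binding, cap 300 iterations. σ² is initialized from the mean of
all pairwise squared distances (the standard `Σ‖x−y‖²/(D·M·N)`).
Degenerate inputs (fewer than 3 source points, collinear sources,
non-finite σ²) raise instead of returning garbage.

On noise-free data the registration recovers generating affines to
machine precision; on rendered skeleton pairs the recovered transform
fits the *data* better than the generating motion does (skeletons are
re-rasterized and re-thinned every frame, so the best affine between two
extracted skeletons differs from the true motion by a few tenths of a
pixel at the centre). This residual is genuine measurement noise in the
TP series, not an algorithmic error, and exact ground-truth recovery is
asserted only for integer-pixel translations, where rasterization is
exactly equivariant.

## TP normalization and windowing

Each TP column is divided by its maximum absolute value over the
*training* rows only (columns identically zero keep factor 1), stored
for denormalization. Per-column rather than per-vector scaling is used
because translations (pixels) and linear entries (near 1) differ by
orders of magnitude. Supervised samples are all stride-1 windows of `W`
consecutive TP rows paired with the next `P` rows; with defaults
`W = 15`, `P = 5` a 74-transform series yields 55 windows. The 80/20
split is chronological at the window level — every test window starts
after every training window — so the held-out tail is genuinely unseen,
including by the normalization factors.

`W = 15` at the default 7.5 frames/s spans two cardiac cycles and was
chosen so a window always contains at least one full beat; `P = 5` is
one third of the window.

## Forecaster

A single LSTM layer (default 500 hidden units, stacking configurable)
reads the `W × 6` normalized window; the final hidden state feeds a
linear regression head emitting all `P × 6` future values at once (the
many-to-many model). A many-to-one baseline treats the six parameters as
independent univariate series predicting one step each. The cell is the
standard formulation (input/forget/output gates, tanh candidate), built
directly on numpy with full backpropagation through the window and
RMSProp updates; gradients are verified against numerical
differentiation in the test suite, and every fit is bit-reproducible
for a given seed.

Defaults and their reasons:

| parameter | default | why |
| --- | --- | --- |
| hidden units | 500 | network capacity of the reference design; generous for 6-channel series |
| epochs | 200 | ~75-frame sequences; use ~500 for ~150-frame sequences |
| optimizer | RMSProp, lr 1e−3, ρ 0.9, ε 1e−7 | standard regression choice for recurrent nets |
| loss | MSE (MAE selectable) | evaluation is MAE; MSE trains more smoothly |
| batch size | 32, shuffled, seeded | ~7 optimizer steps per epoch; full-batch gives one step per epoch, far too few at lr 1e−3 |
| head bias init | training-target mean | several TP channels sit at large offsets (A00 ≈ 1); gradient steps alone need hundreds of epochs to reach them |
| kernel init | Glorot uniform / per-gate orthogonal recurrent, unit forget bias | standard LSTM initialization |

RMSProp's effectively constant step size leaves a noise floor of about
0.01 (normalized) around an optimum; tests asserting exact recovery of
constant signals use enough epochs to settle within it.

## Evaluation

**Per-parameter MAE** between predicted and registration-derived TP
vectors over all held-out windows and horizon steps, in the learning
representation (translations in pixels at the image centre).

**Distance-transform (DT) error.** The Euclidean distance transform of
the reference centerline image assigns each pixel its distance to the
nearest centerline pixel. The last observed frame's extracted centerline
is pushed through the composition of the predicted per-step transforms
(horizon h uses h accumulated predictions), the DT of the *target*
frame's extracted centerline is sampled at the transformed points
(nearest-pixel lookup by default, bilinear by flag), and the mean is
converted to millimetres by the pixel spacing. The reference is the
extracted — not the simulator-true — centerline, matching what is
observable on real data; the headline number averages over the full
P = 5 horizon, with a per-step breakdown in the report. Points pushed
outside the image are clipped to the border and counted in the report.
Pixel spacing must be declared explicitly for real data (the simulator
embeds its own, 0.35 mm/px); no silent default exists because the method
cannot know the detector geometry.

## Synthetic phantom

No public angiography sequences with per-frame affine ground truth
exist, so the generator produces a surrogate: a seeded random branching
tree of cubic-spline polylines (5 branches by default, each child
rooted on a parent, connectivity by construction) rendered with a
Gaussian tube profile (width 3 px) onto a 256×256 canvas at 0.35 mm/px,
plus flat or textured background and i.i.d. Gaussian noise (σ = 0.01 of
the intensity range).

Motion is the composition `respiratory ∘ cardiac` (cardiac applied
first; order configurable) of two similarity transforms about the tree
centroid, each sinusoidal in time with phase zero at frame 0:

* cardiac: period 1 s; peak 5 mm translation along a fixed oblique
  direction, 2° rotation, 2% scale (an optional signed-squared-sine
  waveform sharpens the systolic phase);
* respiratory: period 5 s; peak 10 mm translation dominantly
  cranio-caudal, 1° rotation, 1% scale.

The 1 s / 5 s periods are normal resting physiology; rate abnormality is
simulated by changing them. Translation amplitudes follow the stated
study conditions; rotation/scale amplitudes are small values typical of
in-plane coronary motion, chosen once. Aperiodic "patient movement" is
available as smooth translation bursts (onset, duration, magnitude).
Modes `cardiac_only` / `respiratory_only` / `both` zero out the inactive
component; the two active components are deliberately not phase-locked.
The default 7.5 frames/s puts 7.5 frames in a cardiac cycle, so the
75-frame default sequence spans 10 beats and 2 breaths and the combined
pattern repeats every 37.5 frames.

Ground truth per sequence: absolute transforms at every frame, relative
transforms `M(t+1)·M(t)⁻¹` (telescoping to the absolute motion within
1e−9), sub-pixel centerline polylines, and their rasterized binary
images.

What the phantom does **not** emulate: X-ray physics (scatter, beam
hardening), contrast washout, vessel foreshortening or out-of-plane 3D
motion, non-affine deformation of the tree (branches move rigidly
together), catheters and other devices, and frame-rate jitter. Passing
the synthetic suite therefore demonstrates the pipeline's correctness
and its accuracy under affine motion with realistic amplitudes and
noise — not clinical performance on patient data, where segmentation
quality becomes the dominant error source.

## Scale of the shipped experiments

The headline check runs the full chain on three seeds of the default
75-frame both-motion phantom (about 2.5 min per seed on one CPU core,
dominated by the 51-scale Frangi filter). Sequence length 75 and the
200-epoch budget follow the stated study conditions for combined-motion
sequences; single-motion experiments at 150 frames with 500 epochs are
supported by configuration but not exercised by the default suite.

## Known limitations

* Affine-only motion: deformable (non-affine) CPD is out of scope, so
  genuinely non-rigid vessel deformation is approximated by its best
  affine fit.
* The DT error is asymmetric (predicted points against the reference
  DT); a symmetric variant would penalize missing branches differently.
* The per-sequence model cannot extrapolate rhythms it has not seen:
  training windows must cover at least one full combined-motion period,
  which caps `P` and floors the usable sequence length.
* RMSProp's noise floor (~1e−2 normalized) bounds achievable precision
  on constant signals; switching to a decaying learning rate would
  trade this against slower offset learning.
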
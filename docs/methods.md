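# Methods

## The registration model

`freept` registers two unordered 3-D point-sets — a *source* (e.g. points
grid-sampled from a preoperative MR prostate segmentation) and a *target*
(e.g. points from an intraoperative TRUS segmentation, possibly only a few
slices of it) — without any point-to-point correspondence and without a
parametric deformation family.

Two modules are trained end to end:

1. **Global feature extraction.** A single weight-sharing encoder maps each
   set to a K-vector. Points are lifted to homogeneous coordinates and
   multiplied by a learned 4×4 transform (initialized at the identity) so
   that translations between the two sets are representable in the features;
   shared per-point layers (64, 64), an optional learned 64×64 feature
   transform, then (64, 128, K) with ReLU activations feed a max-pool over
   the point axis. There is deliberately **no batch normalization** anywhere:
   normalizing activations across a batch would cancel exactly the
   translational offsets the registration must perceive. Max-aggregation
   makes the per-set feature exactly invariant to point order and to point
   duplication; the concatenation g = [g_source; g_target] (length 2K) makes
   the pair feature *order sensitive* — swapping the sets reverses the
   direction of registration.

2. **Model-free point transformation.** An L-layer MLP maps [g; p] (width
   2K+3) to a 3-vector displacement d, added to the point: p' = p + d. ReLU
   on all layers but the last; no smoothness penalty and no deformation
   family, i.e. the displacement field is constrained only by what the
   training distribution makes the network learn. Because the weights are
   shared across points, the MLP is mathematically identical to a width-1
   convolution over the point axis; both realizations exist in the code and
   are asserted equal in tests. Any point in the source frame can be
   transformed — not just the network's input points — so a model driven by
   256-point inputs can move an 8192-point cloud or a handful of landmarks.

The **G-RBF comparator** keeps the same encoder but replaces the free
displacement head with a parametric one: an MLP maps g to N_c control
points (tanh-bounded into the normalized cube) and a 3×N_c coefficient
matrix α; a query point moves by α·k(p) with Gaussian kernel entries
k_c(p) = exp(−‖p_c − p‖²/(2σ²)). Its displacement field is a smooth spline
by construction, which is exactly the contrast the comparator exists to
exhibit.

### Losses

Both objectives compare the transformed source A to the target B in
normalized space:

* **Chamfer loss** (training form): mean over B of the squared distance to
  the nearest point of A, plus the same with the roles swapped. Symmetric;
  zero iff the supports coincide. Nearest-neighbour ties break to the lowest
  index, which affects only the subgradient, not the value.
* **GMM negative log-likelihood**: B is scored under an isotropic Gaussian
  mixture with centres A (equal weights, variance σ², default 0.001) plus a
  uniform outlier component of weight u (default 0.1). Computed with
  log-sum-exp stabilization; at σ² = 0.001 a naive exponential underflows
  for any mm-scale separation, whereas the stabilized form stays exact and
  finite even at u = 0.

The evaluation-time Chamfer **distance** is the non-squared two-way mean
nearest-neighbour distance (halved across directions) so values are in mm
and comparable to gland dimensions; the squared form remains the training
loss. Both are exposed.

### Training

Unsupervised: no ground-truth transforms, only pairs. Per step, each set is
normalized to [−1, 1]³ by its own bounding box (an implicit coarse
pre-alignment; registered outputs return to mm through the *target's*
normalization, since the moved source lives in the target frame), shuffled,
subsampled to a fixed cardinality (without replacement; with replacement
only if the request exceeds the set), and the source is augmented with a
random rotation (±45° per axis, composed x→y→z about the centroid), random
displacement (±1 normalized units) and mild scaling ([0.9, 1.1] — a range
kept small so augmented sets do not leave the cube catastrophically).
Optimization is Adam.

**Partial-data protocol.** When the target is only two or three slices, the
network input target is the slice set normalized by its *own* bounding box
(exactly what would be observable at inference), while the loss compares
the transformed source against the *full* target mapped into that same
frame — stronger supervision during training than the partial observation
alone provides. Classical baselines get no such help; they see only the
slices.

**Presets.** The full-scale preset (K = 1024, widths 1024/512/256/128/64/3,
2000 epochs, lr 1e-5, minibatch 8 for Chamfer and 2 for GMM, cardinalities
1024–8192) is retained in configuration. The package's study conditions are
the *desk preset*: 30 synthetic pairs (70/30 split at the subject level,
with any multi-acquisition subject forced into training), K = 128, widths
256/128/64/32/16/3, 256-point inputs, 150 epochs at lr 1e-3. At a few
hundred optimizer steps the full-scale learning rate moves the loss
negligibly, so the desk preset uses the larger rate; this is a property of
the scaled-down schedule, chosen once. Training runs in single precision;
oracle comparisons and all closed-form checks run in double precision.

Under the desk preset the trained model reaches a held-out mean TRE of
about 4 mm against an unregistered ~18 mm, and the loss falls to under 10%
of its first-epoch value.

## The synthetic cohort

No clinical MR/TRUS cohort is redistributable with this package, so a
generator stands in for one. Each case is a bumpy ellipsoid "gland"
(semi-axes 18–25 mm, four smooth radial lobes of ±2 mm) voxelized at
2.5 mm and grid-sampled into a volumetric point-set; the target applies a
sum of six Gaussian-RBF displacements (≤3 mm each, 15 mm length-scale),
then a rigid perturbation (±20° per axis, ±20 mm per axis), and re-samples
the deformed volume on a fresh grid so that source and target share no
correspondence — as two independent segmentations would not. Eight interior
landmarks carry the exact forward map, so ground-truth TRE is available to
machine precision. The rigid and deformation amplitudes were chosen once so
that the unregistered landmark error is in the tens of millimetres,
comparable to an uninitialized clinical fusion problem.

Membership of the deformed volume is tested by fixed-point inversion of the
forward map (40 iterations); the field is a contraction (worst-case
Jacobian norm ≈ 0.7 at the defaults), so the inversion converges well below
sampling resolution.

What the generator does **not** emulate: ultrasound fan geometry and probe
pressure, biomechanically realistic tissue deformation, segmentation noise
and inter-observer variability, and intensity data of any kind. Passing
tests therefore demonstrate the machinery — losses, invariances, training
dynamics, relative robustness of methods — on organ-scale geometry, not
clinical accuracy.

### Slice scenarios

Partial targets are parallel slabs (default thickness one voxel) along one
lateral axis: scenario 1 places three slabs at 10/50/90% of the extent
(even coverage), scenario 2 at 40/65/90% (biased to one side), scenario 3
two slabs at 64/76% (close together, poor coverage), each with ±2% jitter
and a random left/right mirror. Two descriptors characterize them: the
*slice centroid distance* ‖c_gland − c_slices‖ and the *slice span*, the
mean of squared distances from the gland centroid to each individual slice
centroid. The span as defined is an mm² quantity; an rms (mm) variant is
provided for unit-consistent reporting. The placements were chosen so that
both intended orderings hold simultaneously under the mm² definition —
centroid distance scenario 1 < 2 < 3 and span 1 > 2 > 3 — which constrains
scenario 3's slabs to sit close together at a moderate offset (by Jensen's
inequality the span can never fall below the squared centroid distance, so
a far-offset two-slab scenario could not have the smallest span).

## Classical baselines

* **ICP** (rigid): centroid-alignment initialization, k-d-tree nearest
  neighbours (ties to the lowest index), closed-form SVD/Procrustes update
  with the determinant sign corrected so the rotation is always proper; up
  to 25 iterations with a secondary stop when the RMS change falls below
  1e-6. Degenerate (collinear) configurations fall back to a
  translation-only update with a warning. The recorded RMS history is
  non-increasing.
* **CPD** (non-rigid): EM on a Gaussian mixture centred on the moving set
  with outlier weight w = 0, Gaussian coherence kernel β = 2 and
  regularization λ = 2 (the published defaults), up to 250 iterations,
  run in the method's internal zero-mean/unit-scale standardization.
  The history records the penalized objective (NLL + coherence penalty),
  which the EM steps keep non-increasing; a σ² collapse to machine epsilon
  is treated as clean convergence. To transform points that were not part
  of the fitted set (landmarks), the fitted displacement field is extended
  by nearest-fitted-point lookup.

## Numerical and design choices

* **Autodiff.** The environment this package targets is plain scientific
  Python, so the networks run on a small in-repo reverse-mode autodiff core
  (`freept.autodiff`): numpy arrays, broadcasted arithmetic, batched
  matmul, ReLU/tanh, reductions with subgradient routing to the first
  arg-extremum, and Adam. Gradients are verified against central finite
  differences in the test suite.
* **Feature width bookkeeping.** The per-set feature length is K; the pair
  feature is 2K; the displacement MLP input is 2K+3. The first entry of the
  width tuple U is the first *hidden* layer.
* **T-net initialization.** Zero weights with an identity bias on the
  regression head, so every learned transform starts at the identity.
* **Encoder interior widths** follow the established per-point scheme
  (64, 64 | 64, 128, K); no orthogonality regularizer is applied to the
  feature transform.
* **Voxel convention**: masks are sampled at voxel *centres*,
  mm = origin + index · spacing, 0-based — centres keep grid point-sets
  symmetric about the volume.
* **Normalization of each set independently** (rather than jointly) gives
  the implicit pre-alignment described above; whether joint normalization
  would help is untested and flagged as a sensitivity question.
* Degenerate normalization axes (zero extent) map to 0 with unit scale and
  invert exactly.
* Checkpoints are a single `.npz` with a JSON architecture header;
  save→load→register round-trips bit-for-bit up to storage precision.

## Known limitations

* Desk-scale accuracy numbers characterize the synthetic cohort only; no
  clinical claim follows from them.
* The model-free head guarantees nothing about field smoothness or
  invertibility; that is a feature under test, not an oversight.
* CPD's landmark transform uses nearest-fitted-point extension rather than
  re-evaluating the Gaussian kernel field; at volumetric point densities
  the difference is below the evaluation resolution.
* The G-RBF head conditions on the global feature alone (not on per-point
  context), matching its role as a global-spline comparator.
* Binary PLY files are not parsed (ascii only); NIfTI masks are accepted
  only through the optional reader when available upstream.
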
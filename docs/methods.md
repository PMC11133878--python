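# Methods

## Problem and model

A cone-beam CT scan of a breathing subject acquires projections
`p_t, t = 0..N_p-1`, one per gantry position, while the anatomy moves.
Dynamic reconstruction asks for one volume per projection — resolving the
motion instead of averaging over it — which is hopeless as an unconstrained
inverse problem (one 2-D view per 3-D state). The model here makes it
tractable with three nested assumptions:

1. **Joint reconstruction–registration.** The anatomy itself does not
   change during the scan; every frame is a deformation of a single
   reference volume, `I(x, t) = I_ref(x + d(x, t))` (pull convention:
   the value at `x` is looked up at the displaced position).
2. **Low-rank motion.** The displacement field factorizes per Cartesian
   direction `k` into `L = 3` spatial basis fields with time-varying
   weights: `d_k(x, t) = Σ_i w_{i,k}(t) · e_{i,k}(x)` (motion basis
   components, MBCs).
3. **Compact parameterizations.** `I_ref` is a coordinate network — a
   multiresolution hash encoding feeding a small sine-activated MLP — and
   each `e_{i,k}` is a tensor-product cubic B-spline over a uniform control
   grid whose resolution grows with the basis index (coarse bulk motion to
   finer local motion). The weights `w_{i,k}(t)` come from a second, 1-D
   coordinate network in the frame index. No prior 4D-CT/4D-CBCT, motion
   model, phase sorting or surrogate signal is used; everything is fitted
   to the projections of the scan itself.

Training minimizes projection-domain mean-squared fidelity plus two
regularizers: anisotropic total variation of the reference rendering
(weight `lambda_tv`) and an orthonormality penalty on the basis fields
(weight `lambda_mbc`), computed with plain voxel-sum inner products on the
image grid so fields of different control resolutions are comparable.

## Five-stage schedule

Optimization runs in five stages across two resolution scales (the high
scale doubles the grid of the low scale), with fresh Adam moments and the
published learning rates per stage:

| stage | scale | trains | loss | epochs | lr |
|---|---|---|---|---|---|
| I.1 | low | spatial INR | image fit to the motion-averaged FDK volume | 600 | 4e-4 |
| I.2 | low | spatial INR | projections + TV | 700 | 4e-5 |
| II  | low | temporal INR + one MBC level at a time (earlier levels freeze), then all levels 50 epochs | dynamic projections + MBC orthonormality | 100/level + 50 | 2e-3 |
| III | low | everything | dynamic projections + TV + MBC | 3000 | 1e-5 spatial, 2e-3 motion |
| IV.1 | high | spatial INR | image fit to the 2x-upsampled stage-III reference | 1000 | 1e-3 |
| IV.2 | high | spatial INR (motion frozen) | dynamic projections + TV | 1000 | 4e-4 |
| V | high | everything | dynamic projections + TV + MBC (norm target rescaled by the voxel-count ratio, 1/8 in 3-D, 1/4 in flatland) | 200 | 1e-4 |

An "epoch" is one pass over all frames in random batches of 32 (image-domain
stages use one full-grid step per epoch). `epoch_scale` multiplies every
epoch count (rounded up, minimum 1) so the full pipeline runs at desk scale;
1.0 reproduces the printed schedule.

## Parameters that matter

* `lambda_tv` (default 4e-4, dimensionless): image-gradient sparsity of the
  reference. The default suits the digital-phantom regime; noisier
  thorax-phantom/patient-like data call for ~1e-4.
* `lambda_mbc` (default 1): resolves the scale/mixing ambiguity of the
  `w · e` factorization by pushing the gridded basis fields toward unit
  voxel-sum norm and pairwise orthogonality.
* Spatial encoder: 8 levels, 2 features/level, base resolution 16 growing
  geometrically to the largest axis of the reconstruction grid, table cap
  2^23 entries (levels small enough are indexed directly, larger ones
  through the XOR-prime spatial hash). Temporal encoder: 12 levels, cap
  2^19, finest resolution = number of frames.
* MLPs: 3 layers (in→32→32→1) for the spatial field; one
  (in→32→32→1) MLP per basis component and direction for the temporal
  field. All non-final layers use `sin(omega0 · z)`, `omega0 = 30`. The
  spatial MLP uses the SIREN initialization including its small final-layer
  bound and a zero output bias — attenuation is ~1e-2/mm, and a
  default-uniform output bias (~0.2) would dominate it and stall the early
  image fit. The temporal MLPs use the uniform fan-in rule throughout.
* Motion control grids: 6, 12 and 24 control points per axis for the three
  basis levels (configurable). Control values are displacements in
  **normalized box units** (fraction of the reconstruction extent per
  axis), converted to mm only at the interface. Under the voxel-sum unit
  norm the basis fields have RMS ~1/sqrt(N_voxel); in physical units the
  temporal weights would then have to reach O(10^2–10^3), which the
  published learning rates cannot deliver, whereas in normalized units the
  weights stay O(1). (This also matches the normalized-coordinate
  convention of the B-spline interpolant the motion model follows.)
* Projector: Joseph-style ray marching, linear interpolation, step = half
  the smallest voxel pitch (configurable smaller). Its adjoint scatters the
  identical weights, so the dot-product identity holds to rounding. A
  Siddon mode (exact ray–voxel intersection lengths) is the geometric
  reference. FDK/FBP: cosine weighting, Ram-Lak filtering (frequency
  domain, power-of-two zero padding), distance-weighted backprojection,
  angular-spacing weights for non-uniform angles; half-fan sets run through
  plain FDK with the offset detector — its artifacts are acceptable in the
  only place FDK is used, the stage-I initializer.

## Differentiation engine

Training runs on a small reverse-mode tape over numpy arrays
(`tomoinr.autodiff`). Dense linear algebra goes through BLAS; the hash
encoder, B-spline interpolation and projector are numba kernels, each with
a hand-written vector–Jacobian product (the projector's VJP is its exact
adjoint; the hash encoder also returns coordinate gradients, which is how
the projection residual reaches the motion model through the warp). The
working dtype is configurable; float32 by default for speed, float64 in the
gradient-check tests. Kernels accumulate in float64 regardless.

Numerical conventions: world coordinates in mm, voxel-center, 0-based;
gantry angle 0 puts the source on +y, rotating counter-clockwise about z.
Flatland (2-D) mode treats the slice axes as (x = left–right,
z = superior–inferior) with the source rotating in-plane, so the dominant
breathing direction stays visible; all operators are dimension-parametric.
Encoder queries outside [-1, 1] clamp (warped coordinates may exit the
box); clamped coordinates get zero coordinate-gradient. B-spline queries
outside [0, 1] clamp likewise. Attenuation is stored in 1/mm;
`HU = 1000 (mu - mu_w)/mu_w` with `mu_w = 0.0192/mm` (a nominal CBCT
effective-energy value; display-only, never fitted).

## Synthetic study conditions

The digital thorax phantom is an analytic stand-in at the scale of a
thoracic CBCT: body, two lungs and a spine surrogate as ellipsoids, a
spherical tumor (default 30 mm) in the lower right lung. The ground-truth
deformation is a spatially weighted translation — the full breathing
displacement inside the lungs, cosine-decaying over a 20 mm band to zero at
the body surface and over the spine — so rendered frames, masks and
displacement fields are exact closed forms at any time. Six breathing
scenarios mirror the usual taxonomy: X1 quasi-periodic (~5 s period,
13 mm SI excursion, small jitter), X2 with a ~5 mm baseline step near 30 s,
X3 amplitude variation + baseline shift, X4 period and amplitude drifting
upward, X5 exactly one cycle over the scan, X6 combined irregularity; AP
and LR components default to 0.3 and 0.1 of SI (the transverse amplitudes
are not pinned by any reference, so they are explicit parameters). A
physical-phantom analog moves only the tumor inside a static body
(programmed trajectory, 24–30 mm SI peak-to-peak class). Scans are 60 s,
360 degrees, uniform rotation, noiseless by default (optional Poisson noise
with configurable photon count).

What this phantom does **not** emulate: heterogeneous lung texture, cardiac
motion, scatter/beam hardening/detector physics, hysteresis between inhale
and exhale paths, and real anatomical complexity. Passing the test suite
therefore demonstrates that the algorithm recovers motion and anatomy under
clean, exactly-known conditions at reduced scale — not clinical-grade
performance.

**Desk-scale problem sizes.** The full-pipeline tests and the results
script use a 96 x 96 flatland phantom at 2 mm, a 128-pixel detector, 96
frames over the 60 s scan and `epoch_scale = 0.1` (float32) — the
package's operating point for complete runs on a single CPU core in a few
minutes; the scan duration, arc, breathing dynamics, tumor size and the
published hyperparameters are unchanged. Two experiments deviate
deliberately: the physical-phantom analog (tumor-only 25 mm motion) runs
at `epoch_scale = 0.05`, where it measurably converges better (prolonged
joint training slowly degrades that localized-motion solution), and the
seed-robustness recovery check runs on a 64^2 grid. Quality saturates
near this operating point: halving the schedule costs real accuracy on the
breathing scenarios, doubling it roughly doubles runtime for marginal
gains. 3-D mode is exercised by the operator and shroud tests at small
grids.

## Design choices at open points

* **Stage IV.1 target.** Rendering the low-scale result at the doubled grid
  through the INR itself would make step IV.1 an exact no-op (the INR
  cannot move toward its own output) and would carry the fine hash levels'
  untrained entries along as checkerboard noise. The target is therefore
  the low-scale render up-sampled by cubic interpolation, which initializes
  the high-scale rendering smoothly before projection fine-tuning.
* **Reference frame.** Not anchored: the optimizer is free to place the
  reference anywhere in the breathing cycle (the phantom's truth uses
  end-exhale, but all motion metrics compare absolute per-frame positions,
  which are gauge-free).
* **Orthonormality bookkeeping.** The unit-norm target applies to voxel-sum
  norms on the current grid; at the high scale the norm is rescaled by the
  voxel-count ratio. The cross terms follow the printed form and are not
  rescaled.
* **Shroud trajectory extraction.** Divergent beams blur a moving interface
  over a few detector rows, so the per-frame position is the
  gradient-energy centroid within the user band (sub-row precision) rather
  than the bare extremal row, median-filtered over 5 frames.
* **Template tracking** replaces the sample-consensus feature pipeline of
  full clinical evaluations: one template from the first frame of the
  measured set, tracked by normalized cross-correlation along the
  craniocaudal axis in both the measured and re-projected sets; frames
  below a correlation threshold are marked missing and excluded from the
  localization error. The localization error itself is the root of the
  doubly averaged squared SI differences, reported in detector-plane mm
  (an optional flag divides by SDD/SAD for iso-plane mm).
* **Tumor contouring on the solved reference** (for center-of-mass/Dice
  scoring) stands in for manual contouring: threshold midway between lung
  and tumor attenuation inside the host-lung region, keep the connected
  component closest in size to the known tumor.

## Known limitations

* Convergence at desk scale is the binding constraint: with ~3% of the
  published optimization steps the reconstruction reaches sub-voxel mean
  tumor localization but not the sub-half-voxel accuracy a fully trained
  run attains; the residual shows up mainly at end-exhale plateaus and as
  residual softness of the reference (relative error floor ~0.12 for a
  static scan at this grid; edge partial-volume alone contributes ~0.1).
* The image-fit capacity of the field (published rate, Adam defaults)
  crosses 10% relative error at roughly 120–200 full-grid epochs on
  piecewise-constant targets, not 60.
* No redundancy (Parker) weighting for half-fan FDK; acceptable for an
  initializer only.
* No scatter/beam-hardening modeling; raw-intensity preprocessing is
  air-normalization + log with dead pixels overridden to one.
* The temporal weights and basis fields retain a residual gauge freedom
  (sign/mixing within the orthonormality tolerance); only composed
  displacement fields are physically meaningful.
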
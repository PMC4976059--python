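# Methods

This note documents the models, numerical choices and limitations behind
`pmctseq`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`, not asserted from
memory.

## The measurement chain

The package implements a semi-automated pipeline for quantifying the lateral
cerebral ventricles (LCV) in a sequential post-mortem CT series — repeated
scans of the same unmoved subject over the first post-mortem day:

1. **Seed construction.** An observer supplies one rough trace of the
   ventricles on a reference acquisition (in this package, the phantom's
   simulated mouse trace). The trace is smoothed by morphological closing
   then opening with a ball structuring element, eroded inward to produce
   foreground (CSF) seeds, and surrounded by a background shell between two
   dilations of the trace. All radii are physical (mm) and implemented with
   Euclidean distance transforms, so anisotropic voxels (e.g. a 1.3 mm slice
   thickness over 0.5 mm in-plane pixels) are handled exactly. Defaults:
   2 mm erosion, 4–8 mm shell — far enough from the boundary that seeds
   avoid partial-volume voxels.
2. **Seed propagation.** Because the subject is not moved between scans, the
   default policy propagates seeds by identity. When inter-scan deformation
   exists, a cubic B-spline free-form deformation is estimated (below) and
   seeds are warped through it with nearest-neighbor resampling; warped
   foreground is eroded one voxel as a guard, and any voxel claimed by both
   classes is removed from the background.
3. **Appearance model.** Per acquisition, 1D Gaussian mixtures are fitted by
   EM to the HU samples under each seed class: one component for CSF
   (near-homogeneous), three for the background (brain, bone, air). EM uses
   a deterministic quantile-split initialization — no random restarts, so
   the pipeline is exactly reproducible — and a variance floor of 0.25 HU²
   for degenerate samples. The log-likelihood is non-decreasing across
   iterations (asserted in tests). Mixture densities are floored at 1e-300,
   so the per-voxel negative log-likelihood maps are finite (≤ ~690.8).
4. **Graph cut.** The binary labeling minimizes the seeded energy
   `E(L) = Σ D_p(L_p) + λ Σ w_pq [L_p ≠ L_q]` with
   `w_pq = exp(−(I_p−I_q)²/2σ²)/dist_mm(p,q)` over a 6-neighborhood
   (26 optional). Defaults: λ = 1, σ set to the mean absolute neighbor HU
   difference of the image. Seeds enter as large terminal capacities. The
   min-cut is solved exactly (details below); components not 26-connected to
   a foreground seed are discarded.
5. **Measurement.** Volume is the voxel count times the physical voxel
   volume (both ventricles as one region); mean HU is the arithmetic mean of
   the stored voxel values under the labels. A measurement below the
   collapse threshold (default 2 ml) is flagged `collapsed`; an empty
   segmentation is `failed` with zero sentinel values, never NaN.
6. **PMI models.** Per case, ordinary least squares of volume and of mean HU
   against hours post-mortem over the quality-controlled time points; a
   single linear model over the whole observation window, no sigmoidal
   refinement. Inverting a fit maps a new measurement to a PMI estimate
   `t̂ = (y − b)/a` with a first-order interval that propagates the slope's
   standard error only (intercept uncertainty and measurement noise in `y`
   are ignored — a documented approximation). The combined estimator weights
   the volume- and HU-based estimates by inverse variance; since the volume
   slope is shallow relative to its scatter, the combination leans
   automatically on the attenuation trend.

## Synthetic phantom

No public scan data exist for this protocol, so the study conditions are
carried by a synthetic phantom with exact ground truth.

* **Geometry.** The ventricle pair is two mirrored curved, tapering tubes —
  a thick body arching over the midline structures with thin frontal and
  posterior horns — placed inside a brain ellipsoid, a 4 mm skull shell and
  air. The shape is voxelized through a normalized distance field
  `f(x) = min_i |x − c_i|/r_i` over centerline samples; thresholding `f < s`
  scales all tube radii by `s`. Bisection on `s` makes the voxelized volume
  match the linear model `V(t) = v0 + rate·t` to voxelization precision
  (within half a surface voxel layer), so the horns thin as the volume
  falls, qualitatively matching the observed narrowing pattern.
* **Intensities.** CSF at `hu0 + rate·t` (defaults 11.12 HU + 0.23 HU/h),
  brain 35 HU, skull 700 HU, air −1000 HU. All configurable.
* **Degradations.** Gaussian blur of 1.0 mm FWHM models the reconstruction
  point spread (partial volume), then i.i.d. Gaussian noise of 2 HU models
  reconstruction noise — noise after blur, as in a real reconstruction.
  The 1.0 mm default approximates a standard head kernel's in-plane PSF and
  is the widest PSF at which even the ground-truth mask measures the CSF
  mean within 1 HU; at 1.3 mm the partial-volume elevation of the boundary
  layer alone exceeds 1 HU, an irreducible bias of the arithmetic-mean
  measurement, not of the segmentation.
* **Inter-scan deformation.** Optionally, each non-reference time point is
  perturbed by a seeded smooth random displacement (5³ control lattice,
  cubic interpolation, amplitude `deform_amp_mm`); the volume bisection runs
  after warping, so ground-truth volumes still match the linear model.
* **Determinism.** One global seed, expanded per time point through
  `numpy.random.default_rng([seed, index])`; identical specs give
  bit-identical series.
* **Collapse.** If the linear model crosses zero inside the schedule the
  generator raises by default; with `on_collapse="clamp"` the affected time
  points carry an empty ventricle, which is how the downstream
  quality-control path (collapsed flags, fits on valid points only) is
  exercised.
* **Rough delineation.** The simulated observer trace dilates the ground
  truth by a configurable radius and randomly toggles a one-voxel boundary
  layer (20 % of boundary voxels by default), giving Dice ≥ 0.5 against the
  truth for dilations up to 3 mm.

What the phantom does *not* emulate: anatomical detail (choroid plexus,
septum, periventricular gradients), beam hardening and scanner physics,
intensity inhomogeneity, and any non-linearity of the post-mortem trends.
Passing tests therefore demonstrate the correctness of the measurement chain
under the stated linear-trend conditions, not clinical performance on real
post-mortem scans.

## Min-cut implementation

The energy is submodular, so the Boykov–Jolly construction (terminal data
edges, pairwise contrast edges, large capacities for seeds) yields the
global optimum via max-flow. The solver is
`scipy.sparse.csgraph.maximum_flow`, which requires integer capacities:

* per voxel, the smaller of the two data terms is subtracted from both
  (a constant energy shift that leaves the argmin unchanged and empties one
  terminal edge per voxel);
* capacities are scaled so that the hard-seed capacity — strictly larger
  than the sum of all finite capacities, hence never cut — lands just below
  2³¹, which bounds every capacity and the flow value inside int32;
* the labeling is read off as source-side reachability in the residual
  graph, making zero-cost ties deterministic.

On 100 random instances small enough to enumerate exhaustively (≤ 12 free
voxels, random data terms, λ, σ, neighborhood), the cut energy equals the
brute-force minimum exactly.

For production volumes the graph is restricted to the bounding box of the
seed masks plus a margin; voxels outside are labeled by their data terms and
their boundary smoothness terms are folded into the box as fixed-label
t-link offsets, so the solve is the exact optimum conditional on the outside
labels. The outside region lies beyond the background shell, where the
connected-component filter would discard any foreground anyway; a test
confirms the conditioned solve equals the full-grid solve on a phantom
instance.

## Free-form deformation registration

Same-subject, same-modality alignment with small motion, so the metric is
the mean squared HU difference. Displacements live on a 16 mm control
lattice and are interpolated by the tensor-product cubic B-spline basis
(zero coefficients = identity; uniform coefficients = exact translation).
The optimizer is gradient descent with a backtracking line search on the
analytic gradient, diagonally preconditioned by the Gauss–Newton curvature
`diag(JᵀJ)` so that low-contrast regions are not starved by the very strong
skull-edge gradients. Two further choices matter:

* both images are pre-smoothed with a fixed 2 mm Gaussian before metric
  evaluation — a capture-range measure (a symmetric blur leaves the optimum
  in place); this is a single-level smoothing, not a multi-resolution
  pyramid;
* a first-difference penalty on the control lattice (weight 10 HU²/mm²,
  normalized per control point) regularizes the field where the image has no
  contrast. The penalty is zero for any uniform field, so translations are
  recovered unbiased.

Displacement is only identifiable where the image has gradient (the aperture
problem); accuracy is therefore assessed over voxels with |∇I| > 5 HU/mm,
where a synthetic 2 mm translation is recovered to better than 0.5 mm.
The registration never returns a transform whose (smoothed) objective
exceeds the identity objective; that condition raises instead.

## Quality control and collapse

A time point is marked `collapsed` when any of three conditions holds: the
propagated foreground seeds are empty; the fitted CSF mean lies within
5 HU of the nearest background mixture component (with the ventricle gone,
the "CSF" seeds sample brain tissue and the two classes become
indistinguishable — the operational analogue of a ventricle too narrow to
measure); or the measured volume falls below 2 ml. Collapsed and failed
points are excluded from the PMI fits.

## Default study conditions

The three reference cases bundled in `pmctseq.cases` define the simulation
defaults: hourly schedules 2–20 h and 1–16 h, an irregular 9-point schedule
{1, 2, 3, 5, 6, 9, 12, 18, 24} h; volume trends −0.27 ml/h from 27.08 ml,
−0.16 ml/h from 37.45 ml, −0.16 ml/h from 53.39 ml; attenuation trends
0.23, 0.34 and 0.42 HU/h from intercepts near 11 HU. Measurement noise for
the parameter-recovery studies is 0.5 ml (volume) and 0.8 HU (attenuation);
these two scatter levels are this package's own choices of realistic
measurement error, not published values. `scripts/acceptance.py` re-derives
the mean recovered coefficients over 200 replicates per case and runs the
full pipeline on 128³ worked-example phantoms (26.8 ml and 21.8 ml); the
recovery studies use n = 200 and the pipeline runs use the full 128³ grid,
sizes chosen to keep the whole script under a minute.

## Known limitations

* The linear PMI models are per-case; with three reference cases there is
  deliberately no pooled or hierarchical model.
* The PMI confidence intervals propagate slope uncertainty only and are
  first-order; they understate the width for measurements far outside the
  fitted window and for uncertain intercepts.
* Identity seed propagation biases late-time measurements upward once the
  true structure shrinks well below the reference seeds (hard constraints
  force a minimum region); the collapse QC bounds, but does not remove,
  this effect.
* The graph-cut σ="auto" heuristic (mean absolute neighbor difference) is
  global; strongly inhomogeneous noise would warrant a local estimate.
* The first post-mortem hour, where attenuation jumps rather than drifts,
  is outside the fitted linear window by design.
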
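# Methods

This note documents the models implemented in `toothseg`, the parameter
choices, the numerical conventions, and what the synthetic phantom does and
does not establish about real micro-CT data.

## Coordinate and data conventions

All volumes are `(z, y, x)` arrays, 0-based, with z the slice axis; voxel
spacing is `(dz, dy, dx)` in millimetres and defaults to 1 mm isotropic
when a file carries no geometry. Intensities are min–max normalized to
[0, 1] before segmentation and classification, which is harmless because
the level-set force is scale-normalized by construction and the PCNN output
is normalized per slice; it makes the default parameters portable across
scanners. Labels are `{0: background, 1: pulp, 2: dentine, 3: enamel}`,
exported as 8-bit grays 0/96/160/255 (configurable; the mapping must stay
injective so exports round-trip).

## GFRLS level set

The evolution implemented is exactly the reduced form

∂φ/∂t = spf(I) · α · |∇φ|,

i.e. without the curvature term div(∇φ/|∇φ|) and without the ∇spf·∇φ
advection term of the general signed-pressure-force model. The
re-binarization (+1 where φ ≥ 0, −1 elsewhere; the tie φ = 0 counts as
inside, the surface belongs to the object) followed by Gaussian smoothing
after every step plays the role of both re-initialization and curvature
regularization, so those terms are deliberately absent rather than
approximated.

Numerical choices:

* **Region means.** Discretized domain integrals with the arctan-regularized
  Heaviside, ε = 1.5 on normalized intensities. The arctan profile has fat
  tails: with strongly unbalanced partitions the means are pulled a few
  percent toward the global mean. This is a property of the model, not a
  defect; it only shifts the spf midpoint slightly.
* **Gradient.** Central differences in the interior, one-sided at borders
  (`numpy.gradient`), in voxel units.
* **Gaussian regularization.** σ = 1 voxel, kernel truncated at 3σ,
  reflective boundaries (avoids a spurious interface at the volume border).
* **Time step and balloon force.** dt = 1, α = 20. Because φ is re-binarized
  every iteration, α·dt only needs to be large enough to flip the interface
  band; the contour then advances roughly one smoothing width per iteration.
  The defaults move a 48³–128³ contour onto the target in 20–50 iterations.
* **Convergence.** The fraction of voxels whose sign changed between
  iterations must drop to conv_tol = 1e-4 (φ is re-binarized each
  iteration, so sign changes fully describe the motion); cap 200
  iterations, returning the current mask with a warning rather than
  raising. A constant image (spf ≡ 0) exits immediately with the initial
  box: with no data force, further iterations would only let the
  binarize+smooth flow — effectively a curvature flow — erode the region.

Direction control follows from the spf sign alone: a seed inside a bright
object expands monotonically onto its boundary; a box enclosing the object
shrinks onto it. Both are verified on sphere phantoms, as is equivalence
(Dice ≥ 0.99) with midpoint thresholding on noiseless two-level images —
the analytic optimum there.

## PCNN classifier

Classical two-channel dynamics with exponential decays and 3×3 synaptic
kernels (0.1 edge / 0.07 diagonal weights, zero self-coupling, zero-padded
at borders), with one modification: the binary step pulse is replaced by
the graded hierarchical output Y = (U − θ)/max(U − θ) · k. The local
variation G (sum of |ξᵢⱼ − neighbor| over the 3×3 window) is computed and
returned as telemetry but does not enter Y; an optional edge weighting
(dividing ξ by 1 + λG before normalization) was considered and rejected to
keep the printed output rule authoritative. Neurons live on 2D slices;
slices are processed independently.

Update order within an iteration is L, F, U, Y, θ, each reading the
previous iteration's pulse; with Y and θ initialized to zero this
sequential loop reproduces the recurrences exactly, and the first
iteration has the closed form U(1) = S, Y(1) = S/max(S)·k.

Defaults: β = 0.2, v_F = 0.1, v_L = 0.2, v_θ = 20 (a fired neuron's
threshold jumps to a very high value and decays back over ~15 iterations),
α_F = 0.1, α_L = 0.3, α_θ = 0.2, Δt = 1, N = 10 iterations, k = 3 tiers.
Two dynamical facts matter for users:

* at N = 2 the freshly fired thresholds dominate ξ = U − θ, the signed
  normalization transiently inverts the scale, and the rounded labels
  collapse — single-iteration steps around N = 2 are not useful snapshots;
* from N = 3 on the output settles back into a calibrated [0, k] tier map
  *provided the slice contains near-zero stimulus* (true for every
  pipeline slice, which always carries masked-out background). On images
  without a dark tier the late-iteration output compresses toward k, and
  classification should use N = 1, where Y is exactly the normalized
  stimulus.

Labels are `round(clamp(Y, 0, k))` (banker's rounding at exact halves,
which real-valued stimuli never hit in practice); equal-intensity
neighborhoods receive equal classes. `firate` counts per-pixel iterations
with Y ≥ k/2 and is telemetry only.

## Pipeline composition

ROI crop (cube of half-width `block_radius` around a seed, clipped,
origin recorded) → GFRLS on the crop → cleanup → grayscale masking
(original intensities inside the mask, zero outside — "subtracting" the
background) → enamel by threshold (default 0.8 on normalized intensities;
`"auto"` = Otsu on the nonzero tooth intensities) → PCNN with k = 2 on the
non-enamel interior → composition (enamel wins; the PCNN class with the
higher mean original intensity is dentine, all darker classes are pulp,
since dentine is the brighter tissue) → paste back into full-volume
coordinates. The output is always a partition of the grid.

Cleanup is erosion (3×3×3 cross, 1 iteration) followed by morphological
reconstruction of the survivors inside the original mask, plus a
largest-26-connected-component filter. Opening-by-reconstruction was
chosen over plain erosion because the erosion's purpose here is speckle
removal; shaving a one-voxel layer off the whole tooth surface would
systematically delete ~1/thickness of the enamel shell and bias every
volume estimate low, which is inconsistent with near-zero enamel volume
errors being achievable at all. Plain iterated erosion remains available
(`reconstruct=False`).

Known limitation: a bracket stub inside the ROI that touches the root
survives the largest-component filter by construction (it is connected to
the tooth) and is classified as dentine; on the default phantom this is
the dominant residual error (dentine Dice 0.992, volume +1.6%).

## Halton volume estimator

Per-slice quasi-Monte Carlo: the radical inverse in bases 2 and 3
(deterministic, no seed; index starts at 1 so the degenerate origin point
is skipped), N = 100 000 points by default mapped over the target region's
per-slice bounding box, area = hit fraction × box area, volume = Σ areas ×
dz. A region that fills its box is measured exactly for any N; the
estimator converges to the voxel-count volume (the oracle used in tests)
with the usual low-discrepancy O(log N / N) behavior — on a radius-16
sphere the relative error is ~0.14% at N = 10³ and ~0.001% at N = 10⁵.
Note the estimator measures the *voxelized* region; against analytic solid
volumes the voxelization itself contributes O(1/r) error.

Statistics: signed relative error (computed − true)/true; MAD = mean
|computed − true| in mm³; a correlation coefficient with absolute-value
numerator (anti-correlation also scores 1, per its printed definition);
and Dice/sensitivity/specificity overlap indexes, where the Dice formula
restores the division implied by "total overlap = 1".

## Phantom: what it emulates and what it does not

The generator reproduces the geometry that makes single-tooth micro-CT
hard: three nested tissue tiers (means 0.35/0.65/0.95 against background
0.05), a pulp chamber plus root canal, slices containing one, two or three
structures depending on depth, weak effective boundaries via additive
Gaussian noise (sd 0.02, clipped to [0, 1]), and a bracket rod at 0.70 —
between dentine and enamel — touching the root, extending out of the ROI.
The default grid is 128³ at 1 mm spacing (a reduced-scale version of the
256³ clinical stacks; all sizes configurable), chosen so the full test
suite and the acceptance script run in well under a minute each. Labels
are the exact pre-noise geometry; determinism is guaranteed by a fixed
generator seed.

Not emulated: partial-volume effects at tissue boundaries, beam hardening,
ring artifacts, intensity inhomogeneity, anatomical surface texture, or
multiple teeth. Passing the phantom suite therefore demonstrates that the
algorithms are implemented correctly and behave as designed under
realistic contrast, noise and topology — not that the default parameters
transfer unchanged to any particular scanner's output. On real data the
enamel threshold and the GFRLS iteration budget are the parameters most
likely to need adjustment.

## Design choices that were genuinely open

* The feeding kernel M is not printed anywhere; it is taken equal to the
  linking kernel W (the standard simplification).
* The level-set convergence criterion is unspecified in the source
  formulation; sign-change fraction was chosen because re-binarization
  makes it exact and scale-free.
* Whether enamel is pre-thresholded or classified jointly by the PCNN was
  ambiguous; the flowchart order (threshold first, PCNN on the remainder
  with k = 2) is followed.
* "Subtraction" of segmented from original data is implemented as
  multiplicative masking: subtracting a binary mask from gray values is
  dimensionally incoherent, and masking produces the described grayscale
  tooth image.
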
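# Methods

This note documents the models, numerical choices and limitations behind
`vesseltrace`.  It is written for users who want to know what the code
actually computes and what the tests do and do not establish.

## Cost image

The tracking cost is `p = 1/(eps + m^alpha * s^beta)` with
`p~ = p + omega`.

* **Medialness `m`.**  An in-plane ray-casting circular filter: per voxel
  and per scale `r`, the mean over 16 equally spaced x–y directions of the
  inward radial intensity gradient sampled at distance `r` (central
  differences scaled by spacing, trilinear sampling, negative ray
  contributions clipped at zero).  The voxelwise maximum over scales is
  normalised by its global maximum, so `m` lies in [0, 1] and a constant
  image maps to zero.  Rays are cast in-plane only because the target
  vessels run roughly along the slice axis; the filter is a swappable
  function, so a Hessian-based vesselness could be substituted without
  touching the rest of the pipeline.  Scales must cover the expected
  vessel radii; `study_cost_params` derives a matched set (smallest
  branch radius, midpoint, trunk radius) for phantom work, while the
  generic default is {2, 2.5, 3, 3.5} mm.
* **Lumen similarity `s`.**  `s = exp(-(I - mu)^2 / (2 sigma^2))` with
  `mu`, `sigma` the intensity mean/SD over the union of the three seed
  spheres (3.5 mm at the common seed, 2.5 mm at the branch seeds).  With
  a degenerate ROI (`sigma = 0`), `s` is the indicator of `I = mu`.
* **Parameters.**  `alpha = beta = 1` (equal contribution of shape and
  intensity), `eps = 1e-6` (bounds p at 1e6, well above any lumen cost),
  `omega >= 0` in cost units per mm (0 by default; 1 in the phantom
  studies; the grid {0..10} is what the leave-one-out selector searches).
  Multispectral combination takes the voxelwise maximum of `m` and of `s`
  separately across sequences — adding a sequence can only lower the
  cost.  The working region is cropped to the seed bounding box padded by
  20 voxels in x–y and 3 in z.

## Eikonal solver

`||grad U|| = p~`, `U(p0) = 0`, discretised with the standard first-order
upwind quadratic on the 6-connected anisotropic grid and solved by fast
marching (binary min-heap, lazy decrease-key, ALIVE/TRIAL/FAR states).
Numerical choices:

* **Upwind solve.**  Per axis the smaller of the two frozen neighbour
  values enters the stencil; finite values are sorted ascending and the
  quadratic is solved over the largest prefix whose solution exceeds
  every included value.  Heap ties are broken by insertion order; the
  solution does not depend on it (asserted against the sweeping solver).
* **Source initialisation.**  A bare point source costs the first-order
  scheme ~18% relative error at 5-voxel radius along diagonals.  All
  voxels within `3 * max(h)` of the source are therefore initialised
  exactly to `cost(source) * distance` and held fixed.  On uniform-cost
  tests this makes the 1D chain exact to machine precision and bounds the
  3D point-source error at 7.5% beyond 5 voxels.  For spatially varying
  cost it introduces an O(ball radius * cost variation) approximation
  confined to a 2.7 mm ball — far below voxel-level discretisation error
  in practice.
* **Termination.**  The march stops when all requested stop voxels are
  frozen, plus a small extra shell (3 voxels' worth of local action) so
  the gradient is well defined around the endpoints.  `U` is +inf outside
  the frozen set.
* **Reference solver.**  `gauss_seidel_action_map` iterates the same
  upwind update in the eight axis sweep orderings until convergence, with
  the same source ball held fixed.  It is independent of the marching
  order and serves as the oracle: both solvers agree to better than 1e-9
  on random-cost grids.

## Backtracking

`dC/ds = -grad(U)/||grad U||`, integrated from the endpoint with RK4 at
`delta = 0.1` mm on a trilinearly interpolated, normalise-then-interpolate
field (central differences where both axis neighbours are alive,
one-sided otherwise, zero at non-alive voxels and at the source voxel).
Stopping rule: within `max(delta, min voxel size)` of the source, then the
source point is appended (subdivided at `delta` to keep the arc-spacing
contract).  A step cap of `10 * grid diagonal / delta` guards against
pathological fields.

Where fronts that wrapped around a blocking region collide, the
interpolated descent field can degenerate and push the trajectory into
the (never-frozen) blocked region.  An RK4 step is therefore accepted
only if the interpolated action does not increase; otherwise the tracker
takes one discrete descent step to the lowest-action alive voxel in the
26-neighbourhood (subdivided at `delta`).  On clean fields the path is
pure RK4; the fallback only engages at shocks, where no smooth descent
exists anyway.

## Cooperative correction

Single-pass, two-step correction: (1) extract both branch paths from one
action map; (2) the lower-average-cost path (`U(end)/length`; ties toward
the first argument) is the best path; (3) dilate its course from the
point closest to the bifurcation gap point by `rho = 1.75` mm (spherical
in world mm, hence ellipsoidal in voxel units), excluding a `rho`-ball
around the neighbour's target so it stays reachable, and set those voxels
to `K = 1e3 * max(p~)`; (4) recompute the neighbour on the blocked cost;
(5) build the analogous constraint around the corrected neighbour;
(6) recompute the best path.  No further iteration is performed — the
correction is not iterated to convergence by design.

`K` is finite so that the front can cross the constraint if genuinely no
alternative exists; a diagnostic flag reports when a returned path comes
closer than `rho` minus half a voxel diagonal (the voxelisation slack of
the mask) to the opposing constrained segment.  The guarantee the method
gives is exactly that: beyond the constraint start, the corrected paths
are at least `rho` (up to discretisation slack) apart.

The bifurcation-seed variants shift the annotated gap point `t = 5.1` mm
back along the extracted CCA-to-gap-point path and route both centerlines
through the resulting in-lumen seed; branch paths are concatenated with
the shared proximal segment at the junction point.

## Synthetic phantom

The generator emulates co-registered black-blood-like volumes of a
bifurcating artery: a straight trunk along z splitting into two branches,
each leaving along a tangent-continuous circular arc (radius 8 mm) and
continuing straight at half the branch angle; anisotropic voxels
(0.5 x 0.5 x 0.9 mm); bright lumen over darker background with a
one-voxel cosine edge; per-branch contrast multipliers; additive Gaussian
noise (two independent draws give the two "sequences").  Ground truth is
analytic; seeds sit at the centerline endpoints and the gap point at the
first axial slice where the two lumen cross-sections are disjoint —
midway between the branch axes, as an annotator would place it.

The **faint-branch preset** fixes the scenario in which independent
extraction fails: branch radii 1.5 mm (so the 1.75 mm constraint radius
covers a branch lumen plus its edge, mirroring the carotid calibre the
constraint diameter was chosen for), branch angle 16 degrees, bifurcation
at z = 6 mm in a 64 x 64 x 48 grid, lumen 100, background 40, faint-branch
contrast 0.45, noise SD 7.  With the faint lumen at 45 against background
40 under SD-7 noise, the branch is barely visible: both independent paths
run up the bright branch and cross to the faint seed only near the top,
while the visibility is still sufficient for the constrained re-extraction
to lock onto the faint branch.  These values were calibrated on the
package's own pipeline across many noise seeds and then frozen; they are
study conditions, not tunables.

What the phantom does **not** emulate: bias fields, flow artifacts,
partial-volume effects, wall/plaque appearance, inter-sequence
misregistration (inputs are assumed co-registered; registration and bias
correction are outside this package's scope), or stenosed/occluded
geometry.  Passing tests show the mechanism works where the cost is
locally misleading but geometrically consistent; they do not certify
performance on clinical MRI.

## Evaluation

Point-sampled distances (no segment projection): with both curves sampled
at 0.1 mm the sampling error is bounded by half the step, negligible
against the 3.5 mm failure threshold.  `CAD > 3.5` mm (strict) flags a
failure.  The omega selector minimises (failure count, mean CAD, omega)
over the training cases of each leave-one-out fold.  The McNemar test is
the exact two-sided binomial on discordant failure counts — appropriate
because discordant counts in studies of this size are small.

## Problem sizes and determinism

The test suite and acceptance script run phantoms of 64 x 64 x 48 voxels
(about 116k voxels after cropping), 41^3 uniform-cost grids, and
random-cost grids up to 13^3 for the solver-equivalence checks; these
sizes keep every check well-resolved while the whole suite completes in a
few minutes on one core.  The pipeline itself is deterministic: all
randomness lives in the phantom generator's seed.

## Known limitations

* Only axis-aligned volumes are supported; rotated/oblique NIfTI
  orientations are rejected rather than resampled.
* The medialness is in-plane; strongly tilted vessels would need the
  filter swapped for an orientation-adaptive one.
* The correction handles one branch pair; extending to N mutually
  constrained paths would reuse the same pairwise core but is not built.
* The discrete-descent fallback can make a path locally hug voxel centres
  near constraint boundaries; points remain within one voxel of the true
  geodesic corridor.
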
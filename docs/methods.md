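# Methods

## Model

A fiber is an ordered 3-D polyline resampled to `m` points equally spaced
in arc length (default `m = 20`; endpoints are preserved exactly).  All
geometry lives in continuous, 0-based voxel coordinates of the label grid
(voxel-center convention); world-to-voxel conversion happens only in I/O.
Sigma parameters and all metrics are therefore in voxel units.

A bundle connecting ROIs `(l1, l2)` — keys stored unordered with
`l1 < l2`; a same-ROI "bundle" does not exist — is an isotropic Gaussian
around its centroid curve.  One scale `sigma_bundle` is shared by every
point of every bundle: per-point or per-bundle covariances are deliberately
not estimated, because small bundles make those estimates (and their
inverses) unstable.  Fiber terminals are tied to ROIs through a Gaussian
in the Euclidean distance transform `phi_l`, with scale `sigma_ROI`; the
two possible terminal-to-ROI pairings are resolved by taking the more
probable one.  The product of the shape density (3m-dimensional) and the
terminal density (6-dimensional) is used as an unnormalized score, exactly
as the model defines it; since only ratios across bundles enter the
memberships, the mixed dimensionality is harmless.

Defaults `sigma_bundle = sigma_ROI = 2` voxels balance coherence against
anatomical attachment; `sigma_ROI -> 0` degenerates to closest-ROI-pair
labeling and `sigma_ROI -> inf` to pure shape clustering, both of which
are exposed as explicit modes (`roi_only`, `clustering_only`) and verified
as limits in the tests.

## Single-subject EM

Initialization assigns every fiber to the ROI pair nearest its terminals
(if both terminals are nearest the same ROI, the terminal with the larger
distance falls back to its second-closest ROI; distance ties break toward
the smaller label).  Centroids start as plain means of the member fibers,
oriented so the first point corresponds to the smaller label of the
winning terminal pairing.

The E-step normalizes joint log-likelihoods into memberships with the
log-sum-exp pattern — the product over 20 points underflows double
precision at moderate distances, so nothing is ever computed in linear
space.  Memberships are zeroed without evaluation when no terminal pairing
keeps both distances within `3 sigma_ROI` (configurable multiplier); a
fiber gated from every bundle is reported as unassigned and excluded from
centroid updates and metrics.  The candidate bundle set is the set of
pairs occupied at initialization — the full `L(L-1)/2` grid is never
materialized.  In `clustering_only` mode both the terminal factor and the
gate are dropped (the gate is a terminal-based device; a pure clustering
baseline has no terminal information).

The M-step is the membership-weighted mean of orientation-normalized
fibers; orientation per (fiber, centroid) pair is whichever point order
has the smaller mean corresponding-point distance.  Soft memberships are
used by default; a `hard` variant (argmax one-hot) is a config switch.
Hard assignments (argmax, ties to the smaller canonical key) drive
convergence counting only: iteration stops when assignment changes drop
to `change_threshold` (20, read inclusively) or at `max_iterations` (10).
After the loop one final E-step refreshes memberships against the final
centroids so reported assignments, memberships and centroids are mutually
consistent.  The trace records per-iteration change counts, the mixture
log-likelihood (the quantity EM ascends; the expected complete-data
objective differs from it by the membership entropy and is recorded
separately), the bundle count, and the unassigned count.

## Groupwise EM

Each subject's transform maps native to common space; the parcellation
and its distance fields live in the common space and are never warped.
Initialization rigidly aligns each subject to the template by Procrustes
fitting its initial bundle-centroid endpoints to the corresponding ROI
centers, weighted by bundle size.  The fit is accepted only when it
removes at least 75% of the weighted residual; otherwise identity is
kept.  Rationale: the rigid step exists to correct gross misalignment
(e.g. scanner positioning), and accepting noise-level "improvements"
would perturb already-aligned subjects, while anything smaller is handled
by the nonrigid updates inside the EM loop.

Each iteration then (1) computes memberships of the warped fibers against
the common centroids (terminal distances evaluated at warped terminals),
(2) updates common centroids as the membership-weighted mean of all
subjects' warped fibers with per-bundle normalization, (3) computes
per-subject native-space bundle centroids with their membership masses,
and (4) refits each subject's thin-plate-spline from its native centroid
points (every 3rd point of each centroid) to the common centroid points,
weighted by bundle mass.  The stopping rule is the single-subject one with
the change threshold scaled by the subject count (20 S), iteration cap 10.
The transform update optimizes a centroid-alignment surrogate of the full
objective, so monotonicity of the data log-likelihood is not guaranteed in
general; it is verified empirically on phantoms with regularization off.

The TPS uses the standard 3-D biharmonic kernel `U(r) = r`.  The
regularization weight defaults to 1% of the bounding-box diagonal of the
control points, which keeps the warp from folding when few bundles are
available; it is configurable, and `lambda = 0` interpolates exactly.
`lambda -> inf` degenerates to the weighted least-squares affine fit
(property-tested).  Weighted fitting is the default so that large bundles
dominate the alignment.

Baselines for comparison: `independent` bundles each subject alone (its
common centroids are the mass-weighted pooled means); `posthoc_tps` adds
one TPS pass aligning each subject's centroids to the pooled mean after
bundling; `pooled` treats all subjects' fibers as one fiber set.

Two printed forms of the groupwise update equations are internally
inconsistent (the common-centroid denominator would sum over bundles as
well as fibers, which does not reduce to a mean for a single bundle, and
the subject-centroid expression lacks normalization).  Both are
implemented in their normalized per-bundle form, which matches the
accompanying verbal description; the all-bundle denominator remains
switchable (`centroid_normalization="global"`) for comparison.

## Metrics and pruning

All metrics use the mean corresponding-point Euclidean distance after
orientation normalization — the distance implied by the isotropic shape
Gaussian.  MIV and MED average over assigned fibers (unassigned counts
are reported); MED uses the winning terminal pairing.  MBCD averages the
subject-to-group centroid distance over (subject, bundle) pairs present
on both sides, with subject centroids mapped to common space; GMIV
averages warped-fiber-to-common-centroid distances over all subjects.
Pruning retains a bundle iff it is present in every subject and its mean
per-subject centroid difference is at most 2.5 voxels (strictly above
discards, reading the rule literally).

## Synthetic phantoms

The generator emulates exactly what the model assumes: ball-shaped ROIs
at Poisson-disk-sampled centers (defaults: 48^3 grid, L = 12, radius 3.5
voxels), smooth quadratic-Bezier centroids between ROI centers with a
5-15%-of-chord perpendicular bow (keeping turning angles well under the
usual tracking threshold of 41 degrees), fibers sampled as centroid plus
i.i.d. isotropic Gaussian point noise (default 1 voxel), terminal jitter
applied at the endpoints (default 1 voxel, clipped at 3x its scale so
terminals stay attached to their ROIs), random point-order reversal with
probability 1/2, and per-subject misregistration as a fold-checked random
TPS with fixed-magnitude control displacements.  A single seed feeds
per-operation substreams, so changing the fiber count does not perturb
the parcellation geometry.

What the phantoms do not emulate: crossing/kissing fiber geometry,
partial-volume effects, outlier streamlines from tracking failures,
spatially varying noise, and ROI shapes more complex than balls.  Default
phantoms are separable — initialization is already essentially correct,
EM converges in one or two iterations, and MIV/MED are flat across
`sigma_ROI` (the sweep test therefore checks non-strict monotonicity).
Passing tests show the machinery is correct and that joint alignment
helps under misregistration; they do not quantify behavior under real
tractography ambiguity.

The groupwise comparison experiment uses 5 subjects, L = 10, K = 8, 25
fibers per bundle, ROI radius 2.5 voxels and 2-voxel misregistration:
misalignment comparable to ROI size is precisely the regime the joint
method targets (with very large ROIs all four methods coincide and the
comparison is vacuous), and these sizes keep one full four-method,
20-seed comparison around ten seconds.

## Numerical choices and degenerate inputs

Distance fields are exact Euclidean distance transforms per label queried
by trilinear interpolation, clamped at the grid boundary; near the ROI
surface the interpolation error can approach a voxel (the field is not
smooth there), away from it it stays below half a voxel.  Empty labels
raise at field-build time, naming the labels.  Zero-length fibers and
non-finite coordinates are rejected.  Bundles whose membership mass falls
below 1e-12 are dropped.  TPS systems are solved by least squares; a
degenerate (coplanar or too-small) control set raises with advice to add
points or increase the regularization.  Reruns with the same inputs,
config and seed are byte-identical.

## Known limitations

The sparsified E-step stores a dense fiber-by-candidate-bundle matrix
(candidates are the initialized pairs only); at whole-brain scale
(~40 000 fibers, ~1000 occupied pairs) this is workable but not tuned.
The rigid initialization assumes bundle-centroid endpoints approximate
ROI centers, which is right for terminal-constrained bundles but rough
for very curved or truncated ones.  Groupwise monotonicity is empirical,
not guaranteed, because of the centroid-alignment surrogate in the
transform update.
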
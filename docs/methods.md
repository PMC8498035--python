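# Methods

This note records the models, conventions and numerical choices behind
`canalpose`, and what the synthetic test bed does and does not establish
about real data.

## Input model

A subject is a set of ordered 3D polylines in millimetres (the inner-ear
centerline model, e.g. exported from a centerline-extraction tool) plus one
surface per eyeball (STL mesh or xyz point cloud).  Coordinates are used
exactly as read — no rescaling, deduplication or unit conversion.  Junction
coordinates are expected to repeat bit-identically across the polylines that
meet there; a weld tolerance (`weld_tol`, default 1e-6 mm) absorbs
text-format rounding only.

## Centerline topology

* **Junctions** are welded coordinates with at least three polyline point
  incidences.  Two post-filters guard against extraction artifacts, both
  configurable: junction pairs closer than `min_junction_separation`
  (default 1 mm) are merged, and junctions touched only by segments shorter
  than `min_arc` (default 2 mm) are discarded.  The anatomical bifurcations
  each carry at least one canal-scale arc, so real junctions survive both.
* **Segments** are maximal polyline runs between junction incidences.
  Splitting is exact: segment lengths sum to the original polyline length.
* **Ring identification.**  Per labyrinth, the three longest segments are
  the canal rings.  Labels come from midpoint position in the head frame —
  posterior = rearmost, superior = uppermost, lateral = outermost midpoint —
  and the expected length ordering posterior > superior > lateral is checked
  afterwards.  Position wins over length when they disagree (a warning is
  recorded, not an error), because the cochlea–utricle line and extraction
  noise can perturb lengths; a genuine tie in the position rules raises an
  ambiguity error naming the contested segments.
* **Key points.**  A is the endpoint shared by the posterior and superior
  arcs (top of the common crus; if two shared endpoints exist the more
  superior is taken), D and C are those arcs' far endpoints, B is the
  lateral arc's non-C endpoint (snapped to D when they coincide within the
  weld tolerance), and E is the endpoint shared by the links leaving D and C
  into the utricle.

## Orientation anchoring without image axes

The classical recipe starts the fundus search from the vertex with minimum
image z, which assumes the head was scanned approximately upright.  Through
the crus line there are *two* tangent planes to the eyeball — one below
(the fundus plane) and one above — and both are fixed points of the
iteration, so with arbitrary subject pose the image axes cannot be trusted
to pick the right one.  `canalpose` derives a superior-direction hint from
the anatomy itself: the crus bifurcation A is the *top* of the common crus,
so the links leaving A run inferiorly; the sum of (A − link far endpoint)
over both sides has a reliably positive superior component.  Because it is
built purely from junction coordinates, the hint is immune to centerline
point noise.  (A hint from ring-midpoint geometry was rejected: polygonal
arc lengths inflate under point noise by roughly 2σ²/Δ per step — about 10%
at 0.05 mm noise — and the posterior/superior length gap is under 1 mm.)

With the hint in hand, left and right are disambiguated by the eyeballs,
which lie anterior to the labyrinths: the crus assignment is chosen so that
Y = Z × X points toward the eye centroid.

## Head frame

* Fundus iteration: start from the eyeball vertex with minimum component
  along the superior hint; form the plane through it and both crus
  bifurcations; orient the normal along the hint; move to the vertex with
  the most negative signed distance; stop when no vertex is strictly deeper
  (ties within 1e-9 mm count as converged, which handles the symmetric
  two-eye tangency).  A cycle on the discrete mesh stops at `max_iter`
  (default 100) keeping the deepest vertex, with a warning.  After
  convergence the lowest pooled vertex index among depth ties is kept, which
  makes the selected vertex index stable under rigid motion of the subject.
* Axes: Z = fundus-plane normal (superior); X = unit vector from right to
  left crus, Gram–Schmidt-orthogonalized against Z (the crus line is not
  exactly parallel to the plane); Y = Z × X, anterior.  Origin = crus
  midpoint, chosen for left/right symmetry.  The default `las` convention
  gives component signs x-left / y-anterior / z-superior; `ras` flips X to
  point right.  The two conventions differ only in the sign of the first
  normal component.

## Canal plane fit

* **Resampling.**  Chord-length-parameterized interpolating cubic spline
  through the arc points, evaluated at `n_out` (default 200) equal
  arc-length steps (arc length measured on a dense refinement).  Endpoints
  are preserved exactly.  An interpolating rather than smoothing spline
  avoids an unstated smoothing hyperparameter; noise robustness is left to
  the plane fit, which averages over all resampled points.  On noise-free
  arcs the fitted normal changes by ~1e-6 degrees between `n_out` 100 and
  400; on noisy arcs the difference between 200 and 400 is below 0.01°.
* **Orthogonal least squares.**  The normal is the right singular vector of
  the centered point matrix with the smallest singular value; the fit RMS is
  that singular value divided by √N.  A total (perpendicular) fit is used
  instead of a functional fit z = f(x, y) because canal planes can be nearly
  vertical.  Degeneracy (collinear or isotropic point sets, detected as the
  two smallest singular values within 1e-12 relative) is an error.
* **Sign and angles.**  Normals are flipped to positive superior component
  (ties: anterior, then left positive) — matching the convention in which
  all six published standard normals have positive z.  Direction angles are
  arccosines of the components, kept in [0°, 180°] without folding, since
  obtuse plane angles are meaningful here.  `direction_angles` deliberately
  does not renormalize its input and accepts norms within 1e-3 of unity, so
  a vector quoted to three decimals reproduces exactly the angles implied by
  its printed components.

## Cohort statistics

Vector mean = normalized componentwise sum.  Angle mean = per-axis
arithmetic mean ± sample sd (n−1 denominator) of the direction angles; its
cosine vector is non-unit in general and is reported both raw and
unit-normalized.  Deviation range = mean ± sd of angles between individual
normals and the *vector* mean.  Method difference = angle between the vector
mean and the unit-normalized angle-mean vector.  All angles are handled in
degrees end to end; dot products are clamped to [−1, 1] within 1e-9 before
arccos.  With one subject, means are defined and sds are NaN with a warning.

## Synthetic labyrinth generator

The generator realizes the canonical centerline topology per side —
posterior ring arc A–D, superior ring arc A–C, lateral ring arc B–C, common
crus A–E, utricle links D–E and C–E, and a cochlea line from E — in standard
anatomical coordinates, then applies an arbitrary rigid pose.

Defaults (held fixed; they define the simulated study conditions):

| parameter | value | rationale |
| --- | --- | --- |
| ring radii (post/sup/lat) | 3.0 / 2.8 / 2.4 mm | human canal scale; arc lengths 12.6 > 11.7 > 10.0 mm preserve the anatomical length ordering |
| arc span | 240° | open rings with a vestibule-facing gap |
| crus bifurcations | (±30, 0, 0) mm | interaural placement of the labyrinths |
| eyeballs | radius 12 mm, centers (±31, 70, 12) | fundus (lowest point) level with the crus tops, 70 mm anterior — the premise that makes the crus–fundus plane horizontal |
| point noise | 0.05 mm sd, isotropic | sub-voxel centerline jitter; endpoints noise-free so junctions weld exactly |
| points per arc | 60, non-uniformly spaced | emulates dense-on-curves extraction output |
| population normals | the six published standard canal normals | cohort means |
| concentration κ | calibrated per canal to the published 5.26–6.94° mean deviations | inter-subject scatter |
| cohort size | 55 | the reference study size |

Per-subject canal normals are drawn from von Mises–Fisher distributions
(Householder construction over the inversion-sampled polar cosine).  The
κ ↔ mean-deviation mapping is computed by numerical integration of
E[θ] = ∫ arccos(1 − s/κ) e^(−s) ds / (1 − e^(−2κ)) and inverted with Brent's
method; a Monte-Carlo cross-check is part of the test suite.  Ring circles
are constructed through the shared landmark points, so junction coordinates
are bit-identical across polylines; a `b_equals_d` variant routes the
posterior ring through the lateral canal's far endpoint to realize the
known anatomical variant where B and D coincide.

**What the generator does not emulate:** segmentation artifacts, centerline
dropout or spurious branches, non-planar (twisted) canal ducts, asymmetric
eye geometry, and anatomically correlated deviations between canals (draws
are independent per canal).  Passing tests therefore establish correctness
of the geometry and statistics pipeline under realistic noise and pose, not
robustness to malformed centerline extractions.

## Problem sizes used in validation

Validation runs use 25-subject cohorts for labeling accuracy and 55-subject
cohorts for parameter recovery — the latter matching the reference cohort
size.  At κ ≈ 140–190 and n = 55 the sampling error of a cohort mean
direction is ≈0.8° (1σ), which dominates the pipeline's own measurement
error (< 0.1° against the empirical mean of the drawn normals).

## Known limitations

* Bilateral input is required: the frame needs both crus bifurcations, so
  single-ear centerline sets fail at frame construction by design.
* The min-arc/junction-merge thresholds stand in for an unspecified
  "fixed distance pattern" between labyrinth bifurcations; they are
  configurable but not learned from data.
* The fundus point is selected among mesh vertices (no sub-facet
  refinement); frame tilt from vertex discreteness is ≈0.01° at the default
  icosphere resolution.
* The VTP reader handles ASCII PolyData with line connectivity only.
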
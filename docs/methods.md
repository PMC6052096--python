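# Methods

`mtlseg` implements a hybrid surface/volume multi-template segmentation of
the three mesiotemporal-lobe (MTL) structures — hippocampus (HP), amygdala
(AM) and entorhinal cortex (EC) — together with a synthetic phantom cohort
that provides ground truth for testing. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Pipeline overview

All images are assumed pre-aligned in a common stereotaxic space (affine
normalization and bias-field correction are out of scope). A template
library holds, per template: the MRI, the manual label (codebook
0=background, 1=HP, 2=AM, 3=EC), a corresponded surface, and the "true"
vertex-wise texture features. Segmentation of a test image then proceeds:

1. **Initial subset selection (n_a).** Every template is scored with the
   hybrid similarity `O_total = O_volume + w_surface · O_surface` and the
   top n_a are kept.
2. **Boundary-weighted non-linear registration.** Each retained template is
   registered to the test image by maximizing
   `O_vol,reg + w_surf,reg · O_surf,reg − λ · O_smooth`.
3. **Subset restriction (n_b).** The hybrid similarity is re-computed on
   the warped data and the top n_b templates are kept.
4. **Global weighted averaging.** One simplex weight vector over the subset
   simultaneously drives the vertex-coordinate average and the weighted
   feature statistics; it is optimized by Nelder–Mead.
5. **Multi-level local weighted averaging.** Per-vertex weights are refined
   on nested icosphere samplings from the coarsest level l0 = 2
   (42 vertices) up to l_max, then interpolated to all vertices.
6. **Label synthesis.** The fused surface is rasterized back to a voxel
   label on the test grid.

## Surface correspondence by radial parameterization

Structures are represented as closed genus-0 triangle meshes sampled on a
shared icosphere. Subdivision level l carries `10·4^(l−1)+2` vertices (12,
42, 162, 642, 2562 for l = 1..5); vertex ordering is deterministic and
level-l vertices are a prefix of level-(l+1), which makes coarse-to-fine
weight refinement index-stable.

Instead of a spherical-harmonic point-distribution model, correspondence is
established by radial ray casting: for each icosphere direction, the vertex
is placed at the last inside→outside crossing of the binarized label along
the ray from the structure centroid, with sub-voxel position from linear
interpolation of the label indicator at 0.5. For star-shaped structures
(every centroid ray crosses the boundary exactly once — guaranteed by the
phantom generator) this provides the same contract: identical topology and
shape-inherent vertex-wise correspondence across subjects. Non-star-shaped
anatomy is explicitly out of scope.

The default correspondence level is 4 (642 vertices per structure,
`mtlseg.library.DEFAULT_LEVEL`); the cohort studies below use level 3
(162 per structure), which keeps the boundary sampling below the 1 mm voxel
scale for ~5–9 mm structures.

Rasterization back to voxels uses the inverse radial test: a voxel center
belongs to structure k when its distance from the structure center is below
the barycentrically interpolated surface radius along its direction. When a
voxel falls inside two structures, the structure whose boundary is nearer
wins; nearness is measured with the radial proxy `| ‖x−c‖ − r_surf(dir) |`,
which for radially parameterized star shapes agrees with the Euclidean
boundary distance to second order. Conflicts are rare boundary voxels
because the phantoms are built non-overlapping. Label→surface→label round
trips achieve Dice ≥ 0.95 at 1 mm resolution (tested).

## Spherical interpolation

Per-vertex quantities given at a coarse icosphere level are interpolated to
arbitrary unit directions by locating the containing spherical triangle and
forming the central-projection (gnomonic) barycentric combination of the
corner values: solving `p = x_a a + x_b b + x_c c` and normalizing `x` to
sum 1 is algebraically identical to projecting `p` along the ray through
the origin onto the triangle plane and taking planar barycentrics. The
weights are non-negative and sum to one (partition of unity), and corner
values are reproduced exactly. Face location uses the nearest icosphere
vertex's incident faces with an exhaustive fallback; a face only counts as
containing when the projection sum is positive (a negative sum identifies
the antipodal face).

Optimization hot loops use a cheaper piecewise-constant variant (radius of
the nearest icosphere direction via a dot-product argmax). This `fast`
inside test misplaces the boundary by at most the angular cell size (≈0.1–
0.3 mm at level 3 for these structure sizes); the exact barycentric path is
retained and is the one checked against the brute-force oracles. Whichever
variant is chosen must be used consistently for template ("true") features
and test ("estimated") features — the package threads one `fast_inside`
flag through both paths so the identity `test image = template ⇒ estimated
features = true features` holds exactly.

## Texture features

At each surface vertex, spherical neighbourhoods of 3, 5 and 7 mm radius
are split by the structure boundary into inner (IR) and outer (OR) regions.
Per radius:

* `NI = μ_IR / SD_IR` — normalized intensity of the inner region (tissue
  homogeneity). The inner region alone is used, which yields the printed
  9-feature total (3 NI + 3 RI + 3 IG); the alternative of averaging inner
  and outer NI was noted and not taken.
* `RI = 2(μ_OR − μ_IR) / (μ_OR + μ_IR)` — boundary contrast, antisymmetric
  under swapping the regions and bounded by [−2, 2] for positive
  intensities.
* `IG` — mean gradient magnitude `√(g_x²+g_y²+g_z²)` over the whole sphere,
  from central finite differences with spacing-aware denominators. Mean
  pooling over IR ∪ OR was chosen as the scale-stable summary.

Sampling policy: intensities are read at voxel centers (no sub-voxel sphere
integration); a sample whose center is within r of the vertex belongs to
the sphere; out-of-grid samples take fill value 0 and count as outside the
boundary. SDs are floored at 1e-6 before any division (homogeneous
synthetic regions would otherwise blow up NI and the normalized deviations).
For speed, each sphere can be restricted to a fixed pseudo-random subset of
its voxel offsets (`max_samples_per_radius`); the subset is cached and the
window anchor uses half-up rounding so the sampled voxel set is invariant
under integer-voxel translations (e.g. cropped grids). The window anchor
and subsampling must match between library construction and segmentation —
the cohort helpers enforce this.

Library feature statistics are the per-vertex, per-feature mean and
population SD (divisor N) across all N templates.

## Hybrid template selection

`O_volume` is the Pearson cross-correlation of template and test
intensities inside the template's label dilated three times (6-connected
element per iteration), or the normalized mutual information
`(H(A)+H(B))/H(A,B)` from a 32×32 joint histogram (range [1, 2]).
`O_surface ≤ 0` is the negative mean over all vertices and all 9 features
of `|F_true − F_est| / σ`, with σ the library-wide population SD floored at
1e-6. Dividing by the number of vertex–feature cells makes `O_surface`
independent of the surface sampling resolution and puts it on the same O(1)
scale as the correlation term, so the default `w_surface = 3.1` remains a
meaningful ratio. A test image identical to a template scores exactly
`O_total = 1.0` (correlation 1, deviation 0). Ranking is deterministic:
descending `O_total`, ties broken by ascending template id.

Since all images already share the common space, the template surface is
used at its native coordinates during selection; no per-template
pre-alignment happens at this stage.

## Boundary-weighted registration

The deformation is a regular control lattice of 3D displacement vectors
with trilinear interpolation — a deliberately self-contained free-form
model, since the contribution of interest is the hybrid cost, not the
deformation machinery. The field is parameterized backward: a test-space
point x samples the template at `x + d(x)`. Surfaces are carried forward by
fixed-point inversion of d (tolerance 0.01 mm, ≤ 20 iterations; a
non-convergent vertex keeps its last estimate and is counted).

Cost terms:

* `O_vol,reg` — Pearson correlation over the registration mask (the
  geometric union of all library labels, dilated five times). Optionally
  every k-th mask voxel is used (`mask_subsample`), trading correlation
  estimator variance for speed.
* `O_surf,reg` — Pearson correlation, across the concatenated surface
  vertices, of the relative-intensity feature on the true template surface
  (over the template image) with RI on the deformed surface (over the test
  image). RI is evaluated at the single middle radius (5 mm) — one scale
  keeps the per-sweep cost affordable; the radius is configurable. For this
  term RI is computed from a rigidly attached ball of trilinearly
  interpolated sample points rather than voxel-center windows: the feature
  is then continuous in the vertex position, which the optimizer needs —
  discrete window shifts create jagged spurious optima larger than the
  per-node intensity signal. The template-side RI vector can use a denser
  one-off quadrature (less noise in the correlation target); when both
  sides use the same quadrature, registering an image to itself is an exact
  fixed point of the term. A per-structure variant of the correlation and
  per-level surface weights are available as options.
* `O_smooth` — mean squared discrete 6-neighbour Laplacian of the lattice
  displacements. The weight λ defaults to 0.02: with the penalty normalized
  per node and correlation-valued similarity terms, λ = 0.1 visibly
  over-damps the field (a rigid 2 mm translation recovers only ~1.3 mm),
  while λ = 0.02 recovers it to better than 0.1 mm and still suppresses
  node-to-node oscillation.

Optimization sweeps the lattice nodes in deterministic raster order; each
node's three displacement components are optimized by derivative-free
Nelder–Mead with every other node frozen. The masked correlation and the
surface-feature correlation are maintained as running sums, so an objective
evaluation only recomputes the voxels in the node's trilinear support and
the RI of the vertices the node carries; the smoothness change is a closed
form quadratic in the node displacement. Surface RI features are refreshed
exactly once per sweep; within a node's optimization the nearby vertices
move with the local linearization of the forward map. A node move is
accepted only if it improves the objective, and a whole sweep is reverted
if the exact end-of-sweep cost decreased, so accepted cost is monotone and
the final cost never falls below the initial one. A level stops when the
sweep-to-sweep gain falls below the tolerance.

Node displacements are capped. For a single lattice level the cap is 0.4×
the lattice spacing, which bounds the displacement difference between
adjacent nodes by 0.8× spacing and keeps the trilinear field locally
invertible (sampled Jacobians stay positive — tested). In a coarse-to-fine
schedule each finer level is re-initialized by resampling the coarser field;
the cap is therefore tied to the coarsest scheduled spacing, otherwise a
fine level could not represent displacement legitimately recovered earlier
(a 2 mm shift exceeds 0.4×4 mm). The default schedule is (8, 4) mm with
60 Nelder–Mead iterations per node and up to 3 sweeps per level.

With `w_surf_reg = 0` the method reduces exactly to pure intensity-driven
free-form registration; this ablation is what the hybrid variant is
compared against. On the synthetic phantoms that comparison has a known
caveat: within-structure boundary contrast is spatially uniform by
construction, so the corresponded per-vertex RI variation that carries the
surface term's alignment signal on real MRI is nearly absent, and the term
contributes sampling noise that slightly lowers warped-label overlap
relative to the pure intensity cost. The hybrid cost remains the package
default — it demonstrably drives correct known-transform recovery, and its
value proposition targets real images, not these phantoms.

## Weighted fusion

After registration, templates are carried into test space (volume by
backward resampling, label with nearest-neighbour interpolation, surface by
the forward map) and their true features are recomputed on the warped data.
The hybrid similarity is re-evaluated on the warped templates and the top
n_b are retained.

**Global stage.** The printed formulation carries separate weight vectors
for surfaces and features, but its surface-average equation combines the
feature weights with features to define a surface — an apparent typo. One
simplex weight vector per stage therefore drives both the vertex average
`S̄ = Σ_j w_j S_j` and the weighted feature mean/SD; the two vectors are
optimized jointly anyway, and a single vector keeps the objective
well-posed. The subset similarity is `O_subset = −mean_v ||F̄_v −
F̂_v(S̄)|| / σ_v` with F̂ estimated on the test image along the averaged
surface. The simplex constraint is enforced by the squared-softmax
reparameterization `w_j = u_j²/Σ u_k²`; weights start uniform and
Nelder–Mead never returns a worse value than the uniform initialization.
A subset of identical templates makes the objective flat up to
floor-amplified rounding; that degenerate case is detected and the uniform
weights returned unchanged.

**Local stage.** For levels l = l0..l_max: every level-l sampling vertex
(the prefix of the icosphere ordering, per structure) gets its own simplex
weight vector, optimized on the local objective — the subset deviation
restricted to the full-resolution vertices whose nearest sampling vertex it
is, holding all other sampling vertices fixed (one deterministic sweep,
improving moves only). The feature mean and SD stay frozen at their
global-stage weighted values, so local weights drive only the surface
geometry; this keeps the decoupled local objectives well-posed. Optimized
sampling weights are interpolated to every vertex by the spherical
barycentric scheme, clamped at tiny negative values (an interpolated weight
below −1e-9 is an error) and renormalized per vertex to the simplex, and
the locally averaged surface is rebuilt as the per-vertex convex
combination. The level advances only while the subset similarity keeps
improving by at least the tolerance; a level that does not help is rolled
back, which makes the accepted similarity monotone from the global stage
through every accepted level. Coarser-level weights are not revisited
(refinement only). Defaults: l0 = 2 (42 sampling vertices), l_max = 5,
bounded above by the correspondence level of the surfaces.

Per-vertex weights stay on the simplex after every operation, and every
averaged surface lies in the per-vertex convex hull of its inputs.

## Synthetic cohort

The generator emulates the statistical structure the algorithm assumes:

* **Geometry.** HP is a mildly curved elongated ellipsoid (semi-axes
  5×9×4.5 mm), AM an adjacent ellipsoid (4.5×4×4.5 mm), EC a flattened
  curved slab (6.5×8×3.2 mm) placed inferior-medially, inside a 64³ 1 mm
  grid with a head-analogue ellipsoid of "tissue". Each structure is an
  analytic radial field r(direction) about its center — star-shaped by
  construction.
* **Population variability.** Radial perturbation by the first 9 real
  spherical-harmonic basis functions (l ≤ 2) with coefficient SD 6% of the
  radius, plus per-axis scale jitter U(±5%) and center shifts U(±2 mm).
  Draws that overlap another structure or break 6-connectivity are
  regenerated (up to 10 attempts, deterministically from the same seed
  stream).
* **Contrast and noise.** Structure means 70 (HP, AM) and 85 (EC) against
  tissue 100 and surround 30, plus Gaussian noise (SD 5). EC's weaker
  contrast deliberately makes it the hardest structure, reproducing the
  qualitative EC-hardest ordering.
* **Atrophy.** A volumetric target fraction is applied as a uniform radial
  shrink by factor^(1/3), which hits the target volume exactly for a radial
  shape; voxelized volumes land within 3%. Patients default to 0.70 for HP
  and 0.85 for EC. 40% of library templates are patient-like so the library
  spans both groups' shape range.
* **Determinism.** A master seed fixes every subject bit-exactly (per
  subject seeds derive from a CRC-based, process-independent hash).

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume, scanner/protocol differences), non-star-shaped or multi-component
anatomy, the collateral-sulcus morphology that makes real EC hard, and
inter-rater label noise. Passing cohort tests therefore demonstrates the
pipeline's mechanics — selection, registration, fusion, volumetry — under
known ground truth, not clinical-grade accuracy on real MRI.

## Evaluation

Dice is `2|M∩A| / (|M|+|A|)` per structure; two empty labels count as
agreement (1.0). Cohen's d is (mean controls − mean patients)/pooled SD, so
positive d means atrophy; a patient structure is flagged atrophic when its
volume z-score against the control distribution is strictly below −2.
Multiple-comparison corrections are out of scope — raw values only.

The library-size experiment draws seeded random sub-libraries at fractions
of N with control/patient proportions preserved, re-segments a fixed test
set per draw, and reports mean Dice per structure per fraction; fraction 1
is the deterministic full-library baseline. n_a and n_b are clamped when a
sub-library is smaller than the configured subset.

## Problem sizes and the desk-scale profile

The package defaults mirror the method's reference configuration
(w_surface 3.1, w_surf,reg 1.1, n_a 17, n_b 8, lattice (8, 4) mm, l_max 5,
correspondence level 4). Cohort studies in the test suite and the
acceptance script run a reduced "desk-scale" profile
(`PipelineConfig.desk_scale()`) chosen for single-CPU runs: 25
templates, correspondence level 3, n_a 6 / n_b 5 (a 25-template pool does
not support n_a 17), a (10, 6) mm lattice schedule with 2 sweeps and 8
Nelder–Mead iterations per node, every 4th mask voxel in the correlation,
100 samples per feature sphere, a 48-point registration-RI ball (512 on
the template side), and local weighting up to level 3 with the 1 mm
agreement shortcut. The finer second
lattice level matters most for EC, whose 3 mm thickness a 10 mm lattice
cannot follow. One full segmentation takes ~45 s; cohort experiments use
6-10 test subjects per group.

## Known limitations

* Star-shapedness is a hard requirement of the radial correspondence; real
  hippocampal anatomy violates it in places.
* The surface term of the registration is evaluated at a single radius and
  refreshed once per sweep; very large deformations (beyond the displacement
  cap) are out of reach by design.
* The restriction stage ranks whole templates; a template that is the best
  match for one structure but poor for the others can be dropped. The local
  weighting stage compensates only partially.
* Fusion objectives optimize feature similarity, which correlates with but
  does not equal overlap accuracy; stage-wise Dice is monotone at cohort
  level, not guaranteed per subject.
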
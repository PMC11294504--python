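# Methods

`cardioreorient` automatically reorients 3-D FDG-PET myocardial-metabolism
volumes into the short-axis (SA) frame and quantifies them as AHA 17-segment
polar maps. The pipeline has five stages — region division, myocardial
segmentation, ellipsoid fitting, rotation, polar-map quantification — each
exposed as a library function and a CLI subcommand. This note records the
model, the parameters that matter, and the design choices made where the
design was genuinely open.

## Coordinate and angle conventions

Volumes are held in a fixed semantic axis order (x left–right, y
anterior–posterior, z caudal–cranial), 0-based half-open voxel indexing,
voxel-center physical coordinates in millimetres. The left-ventricular (LV)
long axis is parameterized by two deflection angles: `alpha`, a rotation
about the x-axis, and `beta`, about the y-axis, with rotation matrices

    H1(a) = [[1, 0, 0], [0, cos a, -sin a], [0, sin a, cos a]]
    H2(b) = [[cos b, 0, sin b], [0, 1, 0], [-sin b, 0, cos b]]

The composition `R = H2·H1` maps the body z-axis onto the long axis; positive
`alpha` tips the apex toward −y, positive `beta` toward +x. The rotation
stage resamples the volume through `R` (pull-back, trilinear, zero fill) about
the LV mask centroid by default; both the composition order and the rotation
center are configurable, and the defaults are pinned by the closed-loop
phantom tests (build a phantom at known angles, recover them, reorient, check
the axis lands on z). No third in-plane rotation is estimated: the method
computes exactly two angles, which leaves the circumferential orientation of
the SA stack to the acquisition frame (a known limitation relative to
three-parameter SPECT reorientation methods).

## Region division (LVG-CED)

Canny edge detection runs per axial slice with hysteresis thresholds taken as
quantiles (0.80/0.90) of the gradient magnitude after a 1-voxel Gaussian
pre-smooth, which makes division invariant to global intensity scaling. Edge
components are closed, hole-filled, and replaced by their convex hulls — a
myocardial ring broken by noise or by a perfusion/metabolism defect is a C
shape whose interior cannot be hole-filled, but whose hull is still the
compact disk-like candidate the geometric priors expect. Candidates are
screened by LV priors: center inside the central 60% of the in-plane field,
equivalent diameter 30–110 mm, circularity (4πA/P²) ≥ 0.4, and mean intensity
at least 1.5× the slice median (the ventricle is the hottest structure; the
ratio form keeps scale invariance). The best admissible candidate per slice
is chained across slices, tolerating gaps of up to 3 slices; the chain with
the highest total score and at least 5 admissible slices wins, with ties
broken toward more caudal slices and then smaller x for determinism. The
chained region is refined per slice by a morphological Chan–Vese active
contour (iteration budget 30, early stop when the per-iteration area change
falls below 10⁻³ of the slice). The tight bounding box of the refined region
is padded by 15% in-plane and 20% along z — the apex extends a few slices
past the last admissible candidate, since slices whose section diameter drops
below the 30 mm prior are rejected by construction — then cropped and
resampled to the unified 80×80×64 grid with physical extent preserved.
Clinical-content failure (no admissible chain) is reported via a success
flag, never an exception, so batch summaries can count it.

## Myocardial segmentation

Segmentation treats the divided volume's 1-D intensity distribution as a
mixture of k = 3 classes (background, blood pool/soft tissue, myocardium).
K-means (Lloyd, k-means++ seeding) and fuzzy c-means (fuzzifier m = 2,
tolerance 1e-5, max 300 iterations) are implemented directly so their
objective traces can be asserted non-increasing; both can be seeded by
particle-swarm optimization of the corresponding objective (canonical PSO:
swarm 20, 100 iterations, inertia 0.9→0.4, c1 = c2 = 2, velocity clamped to
20% of the intensity range). We implement PSO-initialized FCM — PSO proposes
the centroid vector, FCM refines it — rather than PSO replacing the FCM
updates; the coupling is not standardized in the literature and the
initialization form preserves FCM's convergence guarantees. Centroids are
estimated on an intensity subsample (100 k values; the 409 600-voxel grid
heavily oversamples a 1-D distribution) and every voxel is then labeled by
its nearest final centroid, which is identical to the maximal-membership
rule. The myocardium is the brightest class, cleaned to the largest
26-connected component with per-slice small-hole filling (≤ 16 px). Full
per-slice hole filling would close the blood-pool cavity wherever the wall
forms a closed ring, silently converting the shell into a solid body and
biasing the fit, so only speckle-scale holes are filled. Maximum
radioactivity sampling (MRS) is provided as a clustering-free alternative:
the wall point is the intensity maximum along each of ~200 quasi-uniform
rays from the cavity center. Mask voxels are converted to physical
coordinates and centered (centroid at the origin) before fitting, so the
quadric's linear terms absorb only residual offset; the full mask is fitted
by default, with a surface-only option.

## Ellipsoid fitting and angle extraction

The myocardial cloud is fitted by the 10-coefficient quadric
a1x² + a2y² + a3z² + a4xy + a5xz + a6yz + a7x + a8y + a9z + a10 = 0, either
with a10 pinned to −1 (ordinary least squares on the inhomogeneous system)
or as the homogeneous SVD problem (unit-norm coefficient vector, smallest
right singular vector, sign fixed so a1 > 0). On noiseless data both agree
to well below 1e-6 degree in the extracted angles.

Two angle extractors:

- **Half-angle closed forms.** For a pure tilt about x,
  `alpha = 1/2·atan2(√2·b6, a2 − a3)` is exact when `b6` is the yz
  coefficient in the unit-norm convention whose design columns carry √2 on
  the cross terms (equivalently `1/2·atan2(a6, a2 − a3)` in the plain
  polynomial convention stored here — the √2 cancels the convention change).
  The companion form for a pure tilt about y is
  `beta = 1/2·atan2(−√2·b5, a1 − a3)`, built from the **xz** coefficient: an
  xy-based variant (`literal_xy_form=True`) is kept for comparison but cannot
  see a y-rotation, whose xy coefficient vanishes identically. These forms
  are exact only for single-axis tilts; combined rotations mix the cross
  terms (Euler composition), so they serve as a small-angle cross-check.
- **Eigen-axis (default).** The long axis is the eigenvector of the smallest
  eigenvalue of the sign-normalized quadratic form; the angles are the exact
  two-rotation factorization of that unit axis
  (`beta = atan2(ux, uz)`, `alpha = atan2(−uy, hypot(ux, uz))`, with
  `uz ≥ 0`). This route is convention-free, exact for combined tilts, and is
  what the pipeline and all ground-truth comparisons use. Near-spherical
  fits (two smallest eigenvalues within 1%) return zero angles with a
  warning rather than an arbitrary axis.

## Polar-map quantification

The SA volume is sampled with the hemisphere-plus-cylinder LV model: the
axis is the line through the mask centroid along z (apex at high z); axial
positions whose in-plane median mask radius is at least 80% of the overall
median belong to the cylinder, and the apex beyond that junction is sampled
as a hemisphere centered on the junction point. The fine map is 16 rings ×
36 angular bins = 576 sectors (ring bands: 6 basal, 5 mid, 4 apical, 1
apex); rings sit at band centers, not interval endpoints, so the open base
cut and the blur-rounded apex pole are not sampled directly. Each sector
takes the maximum interpolated intensity along its ray (radial maximum is
the standard for perfusion/metabolism maps; a mean would mix in cavity and
background), out to 1.6× the median wall radius. The 17 AHA segments average
their fine sectors (6/6/4/1 angular groupings; θ = 0 at the anterior wall,
increasing counterclockwise viewed from the apex), and the three coronary
territories are LAD {1,2,7,8,13,14,17}, RCA {3,4,9,10,15}, LCX
{5,6,11,12,16}.

Similarity between a reference map `p_r` and a method map `p_o` is
`m = |1 − (p_r − p_o)/p_o| × 100%` per segment, exactly in this form even
though it exceeds 100% when `p_r < p_o`; a bounded variant
(`1 − |Δ|/p_o`) is available behind a flag but is never the default.
Segments with `p_o = 0` are excluded from means and counted. The summed
metabolism score grades each segment's percent-of-maximum value on the
conventional 5-point scale (≥70% → 0, ≥50% → 1, ≥30% → 2, ≥10% → 3,
else 4); SMS is the sum over 17 segments and SMS > 2 flags a metabolic
defect.

## Synthetic phantoms

The phantom generator is the validation instrument: no public cardiac FDG
dataset with reference orientations accompanies the method, so every
accuracy claim in this repository is a phantom parameter-recovery result.
The LV is the region between two concentric prolate ellipsoids (outer
semiaxes (35, 35, 50) mm, wall 10 mm), truncated by a plane normal to the
long axis that removes the basal 30% of the −z semi-axis (ventricle length
85 mm; apex closed, base open), voxelized on a 128×128×96 grid at 2 mm.
Rotation by `H2(beta)·H1(alpha)` is applied to the analytic surfaces before
voxelization, so the ground-truth orientation carries no resampling error.
Three image classes mirror a clinical FDG population: clean shells; shells
with a wedge defect (60° wide, intensity fraction uniform in 0.1–0.4 —
severities are stated assumptions, not published values); and shells with a
right-ventricular crescent abutting the septal wall (default intensity ratio
0.5; the stress regime uses 1.0, emulating the hardest published failure
mode where RV and LV uptake are similar). Myocardium:background is 8:1,
scanner appearance is a 5 mm FWHM Gaussian blur (the typical reconstruction
filter) and Poisson noise on counts (50 counts per intensity unit,
expectation-preserving). Batches draw tilts uniformly from ±30°, jitter the
center by up to ±8 mm in-plane, and give case i the seed `base_seed + i` so
any case is individually reproducible.

What the phantom does **not** emulate: respiratory/cardiac motion,
attenuation artifacts, full torso anatomy, non-ellipsoidal remodeled
ventricles, and the inter-observer variability of a human reference
orientation. Passing the phantom suite therefore demonstrates the
geometric correctness and noise robustness of the algorithm chain, not
clinical-grade accuracy on patient data.

## Evaluation harness and study sizes

Agreement between predicted and reference angles is summarized per axis by
Pearson, Kendall tau-b and Spearman coefficients (scipy implementations
behind the package surface, verified against brute-force oracles in the
tests) plus an OLS fit with its R². The committed study conditions are a
20/20/20 three-class batch at seed 42 (the desk-scale analogue of a
128-patient clinical cohort) and 100-shell point-cloud recovery studies
(noiseless and 5% radial noise). Reference polar maps for the similarity
score come from reorienting each divided volume by its *true* angles — the
phantom stand-in for a physician's manual reorientation. Pipeline failures
are data (success flags), not exceptions, so success rates are first-class
outputs.

## Numerical choices and degenerate inputs

- Resampling preserves physical extent exactly (spacing rescales by
  shape ratio); trilinear output is clipped to the input range.
- Constant slices yield empty edge maps; constant volumes are a
  segmentation failure signal, and MRS on low-contrast volumes warns.
- FCM handles a sample coincident with a centroid by full membership there;
  k-means requires at least k distinct values.
- A quadric whose form is not positive definite (after sign normalization)
  is rejected as non-ellipsoidal; coefficient and point-cloud scaling leave
  the angles unchanged to 1e-6 degree.
- All randomness (phantom noise, clustering seeds, PSO) flows from explicit
  integer seeds; identical seeds give bit-identical masks and volumes.

## Known limitations

- Two-angle reorientation cannot correct in-plane rotation.
- The half-angle closed forms are single-tilt exact only; the eigen route
  is the production path.
- Intensity-only clustering assumes the divided field contains no structure
  brighter than the myocardium; division's geometric priors are what make
  that assumption hold.
- The hemisphere/cylinder junction rule (80% of median radius) is
  data-driven but heuristic; strongly remodeled ventricles may shift it.
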
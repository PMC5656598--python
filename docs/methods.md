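# Methods

`paleoretro` implements the virtual-anthropology workflow for assessing and
reversing post-mortem (taphonomic) deformation of a cranial vault: quantify
whether the deformation was affine, symmetrize a bilateral landmark template
to undo it, warp the mesh accordingly, and fill missing surface with a curve
network. Because real fossil scan data is rarely redistributable, the package
ships a ground-truthed synthetic generator that emulates the study object —
a bilaterally symmetric calvarium-like shell deformed by a parametric
"sediment compression" scenario — so every stage can be validated against a
known answer.

## Thin-plate splines and bending energy

The thin-plate spline (TPS) interpolating a source landmark configuration
{s_i} onto a target {y_i} is

    f(x) = c + A x + Σ_i w_i U(|x − s_i|),

with the classical kernels U(r) = r² log r in 2D and U(r) = r in 3D, and the
side conditions Σ w_i = 0, Σ w_i s_i = 0 that make the warp affine far from
the landmarks. The bordered linear system is solved with a least-squares
solver at a relative pseudo-inverse cutoff of 1e-10; coincident source
points raise an error.

The bending energy (BE) is the integral of the squared second derivatives of
the warp. For the fitted spline this equals a quadratic form in the
non-affine weights: BE = 8π · Σ_d w_dᵀ K w_d in 2D (and the negated form in
3D, where the kernel block is negative semidefinite). The 8π constant was
verified against direct numerical integration of the definitional integral
(analytic kernel Hessians, polar trapezoid grids refined until stable); the
test suite repeats this check. BE is zero exactly for affine maps, strictly
positive otherwise, invariant under rigid motion, and scales as 1/s² when
the source alone is scaled by s — so energies reported across sections are
computed on configurations scaled to unit centroid size.

## Per-section asymmetry protocol

The deformation-assessment stage cuts the vault with seven coronal planes
spaced 10 mm over a 60 mm span. The stack is anchored, by default, at the
coronal level of maximum cranial width (the vertex farthest from the
midsagittal plane); both the anchor and the plane normal are overridable,
since the anatomical anchor of such section stacks is a judgement call. Each
section contour is split at the midsagittal plane — estimated as the
best-fit plane through bilateral-pair midpoints and midline landmarks, which
is exact for an affinely deformed symmetric object — into a left and a right
external profile, each resampled to 30 semilandmarks equally spaced by arc
length. Missing contour stretches can be bridged by a minimal-curvature
cubic (control offsets of one third of the gap chord, which reproduces a
straight line for straight gaps and tracks a circular arc to well under 1%
for gaps up to ~40°).

The right profile is mirrored in-plane, superimposed on the left by
Procrustes (with scaling, reflection disallowed beyond the explicit
mirroring), and the BE of the TPS between the two is the per-section
asymmetry measure.

One protocol detail matters and is easy to miss: equal-arc-length resampling
does **not** commute with anisotropic affine maps. Resampling each side
independently and pairing by index therefore injects spurious *tangential*
mismatch that reads as non-affine signal — on the synthetic fixture at 10%
lateral compression plus 0.12 shear, the artefact alone produces BE ≈ 6e-2,
two orders of magnitude above any sensible "close to zero". The profile
points are therefore treated as sliding semilandmarks: after superimposition
they slide along the (densely resampled) profile curve to minimise the
bending energy, parameterised by arc length and driven by damped Newton
steps with a line search that keeps the points strictly ordered. Sliding
removes tangential artefacts (affine fixtures drop to BE ≈ 1e-5) but cannot
remove displacement perpendicular to the profile, which is genuine local
bending — a 3–4 mm dent raises section BE above 0.1 only on the sections
crossing it. The affine-consistency flag uses a threshold of 1e-3 on
unit-centroid-size configurations (configurable); the configuration-level
operation `bilateral_bending_energy` does not slide unless given the profile
curve, so exact affine pairs score ≤ 1e-8 without any correction.

## Retrodeformation

Symmetrization uses the closed-form reflected-relabelling construction: the
configuration is relabelled through the bilateral pairing (an involutive
permutation P), and the optimal *improper* orthogonal alignment Q of the
relabelled copy onto the original is solved in closed form. Because P is
involutive, the cross-covariance C = Xcᵀ P Xc is symmetric; the optimal Q is
obtained from its eigendecomposition by flipping the sign of the smallest
eigenvalue, which makes Q a reflection (Q² = I, det Q = −1). The
symmetrized configuration is the pointwise midpoint of the original and the
aligned copy. Involutivity makes the output *exactly* symmetric and the
operation idempotent — both are asserted at 1e-10 — and the construction is
equivariant under rigid motion of the input. No scaling is fitted anywhere:
retrodeformation must not change the absolute size of the specimen.

Patch semilandmarks are first made geometrically homologous by sliding
within the local tangent plane of the mesh at each point to minimise the
TPS bending energy toward a reference (the provisionally symmetrized
template), then projecting back to the nearest surface point. The tangential
offsets minimising the energy quadratic form are solved in closed form each
pass; a step is accepted only if the energy decreased (with step halving
otherwise), for at most 10 passes or until the relative change drops below
1e-6. Fixed landmarks never move. Semilandmarks farther than a tolerance
(default 2% of the mesh extent) from the surface are rejected as input
errors.

The mesh warp is the full 3D TPS interpolating the (relaxed) template onto
its symmetrized counterpart, applied to every vertex; vertices far from all
landmarks follow the affine part. The result carries a signed distance map
against the input mesh (positive where the restoration moved the surface
outward along the input's outward normal), which for a laterally sheared
vault shows the expected opposite-signed left/right lobes.

### What symmetrization can and cannot recover

Only the mirror-*antisymmetric* part of a deformation is visible to a
bilateral method. A lateral shear (x += k·z — the idealised signature of a
sediment pack translating the vault from left to right) conjugates to its
exact inverse under mirroring and is removed essentially completely: on the
synthetic fixture, ≥ 97% of the RMS vertex deviation at shears 0.05–0.2.
A uniform lateral compression is mirror-symmetric and therefore
fundamentally invisible — no symmetry-based method can recover it. The
recovery benchmark consequently drives the shear magnitude (plus a fixed
rigid occipital tilt, which is shape-neutral), while the compression factor
is available as scene dressing for the asymmetry demonstration. Recovery is
scored as RMS vertex deviation to the pristine ground truth after rigid
(no-scaling) alignment with known vertex correspondence, reported before
and after retrodeformation together with the removal fraction 1 − post/pre.

## Surface completion

A missing region is spanned by polynomial (Bezier) curves whose anchors all
lie on preserved surface, with first and last anchors on opposite sides of
the hole. Curves are fitted in Bernstein form through the anchors at
chord-length parameters; the degree is the anchor count minus one, capped at
6 (more anchors are fitted in the least-squares sense) because high-degree
Bernstein bases oscillate. Each curve is sampled at equal arc-length
intervals (composite Gauss–Legendre arc-length tables with Newton
inversion; adjacent arc lengths agree to better than 1e-6 relative). The
pooled samples plus the hole-rim vertices are projected to a best-fit plane
(a cylindrical parameterization is selectable for strongly curved holes),
Delaunay-triangulated, clipped to the rim polygon, and lifted back to 3D.
Because the rim vertices themselves participate in the triangulation, the
patch boundary coincides with the rim and stitching is exact; near-rim and
near-duplicate samples (where curves cross) are decimated at 0.35 of the
median rim edge length to avoid slivers. Original vertices are never moved;
reconstructed faces are flagged. On the reference fixture — a 25°-aperture
cap excised from a 30 mm sphere, rebuilt from a 20-curve network — the
maximum radial error is about 0.4% of the radius.

## Synthetic fixtures and what they do (not) show

The generator builds the external surface of a half-ellipsoid vault
(default semi-axes 70 × 90 × 60 mm, target edge length 6 mm) whose azimuth
sampling is closed under the x → −x mirror, so the mesh is exactly
bilaterally symmetric by construction. The template carries 18 fixed
bilateral landmark pairs on a regular surface lattice, four bilateral 4×4
semilandmark patches over the parietal walls, and 8 midline points along
the sagittal arc — 172 points, the size and structure of a realistic
retrodeformation template. The `thickness` parameter is reserved; analyses
operate on the external surface, which is the surface the sectioning
protocol profiles.

The taphonomic deformation composes, in order, uniform lateral compression,
lateral shear, and occipital tilt (defaults for the demonstration preset:
0.9, 0.1–0.12, 8°, chosen to produce a visibly asymmetric posterior view;
they are illustrative, not measured values). An optional dent displaces
vertices inward with a raised-cosine profile whose peak equals the requested
depth exactly (the centre snaps to the nearest vertex). Excision removes
faces within a geodesic disc — geodesic distances come from Dijkstra
initialisation tightened by iterative triangle-unfolding sweeps, accurate
to well under one edge length (cap areas match the spherical closed form to
~0.2% on an icosphere) — and records the rim and the removed surface.
Fragmentation partitions faces by seeded region growing on the adjacency
graph and applies recorded rigid scatters; it is bookkeeping, not fracture
mechanics.

Every generator output is a pure function of its parameters and seed.

What passing tests on these fixtures show: the pipeline's operations are
internally correct (exact symmetry, known affine maps, analytic spheres,
recorded ground truth). What they do not show: performance on real fossil
surfaces with scanning noise, plaster inclusions, non-affine plastic
deformation beyond a parametric dent, anatomically realistic vault
curvature, or operator-placed (rather than lattice-placed) landmarks. The
affine-recovery numbers in particular are upper bounds tied to the affine
deformation model the method itself assumes.

## Numerical choices

- Linear systems: `lstsq` with relative cutoff 1e-10; "zero BE" asserted at
  ≤ 1e-8 on unit-centroid-size configurations.
- Procrustes: SVD (Kabsch) with determinant correction; reflections only
  when explicitly allowed; profile superimposition uses scaling,
  retrodeformation alignment does not.
- Closest-point queries: exact point-triangle minimisation over candidates
  from the k nearest face centroids plus the nearest vertex's face ring
  (k = 32), validated against an exhaustive face scan.
- Section plane count: floor(span/spacing) + 1 with a 1e-9 relative epsilon
  so exact multiples include the end plane.
- Degenerate inputs raise typed errors (`errors` module) rather than
  returning silently wrong geometry: collinear Procrustes input, coincident
  TPS sources, zero-length profiles, off-surface anchors, non-spanning
  curve anchor sets, one-sided contours.
- Plane/line tie-breaks are deterministic: best-fit plane normals have their
  largest-magnitude component forced positive; in-plane bases are built from
  the global axes.

## Known limitations

- The sliding-semilandmark Newton solver optimises each section profile
  independently; it has no notion of correspondence across sections.
- Cylindrical Delaunay parameterization assumes the hole does not wrap the
  full circumference.
- Geodesic distances are approximate (upper bounds tightened by local
  unfolding); for region excision this is far below mesh resolution, but the
  distances are not exact polyhedral geodesics.
- `relax_semilandmarks` guarantees monotone non-increasing energy, not a
  global optimum; with strongly folded surfaces the tangent-plane step may
  stop early.
- The recovery benchmark's rigid re-alignment uses the known synthetic
  vertex correspondence; real specimens would require surface registration,
  adding error not modelled here.
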
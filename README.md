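# paleoretro

Deformation assessment and virtual restoration of cranial meshes.

Fossil crania are routinely distorted by the sediments that buried them:
walls are flattened, sheared sideways, tilted, broken, and partly lost.
Before such a specimen can be compared morphometrically, two questions must
be answered — *what kind of deformation happened* (uniform/affine, which is
reversible from bilateral symmetry, or localised/non-affine, which is not),
and *what did the specimen look like before it happened*. `paleoretro` is a
Python toolkit for that workflow, aimed at virtual-anthropology and
geometric-morphometrics practitioners:

- **Asymmetry diagnosis** — cut the vault with evenly spaced coronal planes
  (default: seven sections 10 mm apart), extract left/right external
  profiles, resample each to 30 sliding semilandmarks, mirror and
  Procrustes-superimpose them, and report the thin-plate-spline bending
  energy per section. An affine deformation "tilts without bending": its
  bending energy is zero, so near-zero values on every section are the
  signature of a uniform, symmetry-reversible deformation.
- **Retrodeformation** — symmetrize a bilateral landmark/semilandmark
  template by the closed-form reflected-relabelling construction (exact,
  idempotent, size-preserving), relax semilandmarks by bending-energy
  minimisation on the surface, and warp every mesh vertex with the 3D TPS
  from the template onto its symmetrized counterpart; report signed
  surface distances between input and restoration.
- **Surface completion** — span a lost region with a network of Bezier
  curves anchored on preserved bone, sample them at equal arc length, and
  Delaunay-triangulate the cloud into a patch stitched to the hole rim.
- **Ground-truthed synthetic fixtures** — a bilaterally symmetric
  calvarium-like shell with a 172-point bilateral template, a parametric
  sediment-compression deformation (lateral shear + compression + occipital
  tilt, optional non-affine dent), region excision, and fragment scatter,
  all reproducible from a seed, so recovery can be *scored* rather than
  eyeballed.

## The central quantities

For a thin-plate spline f interpolating landmark configuration X onto Y,
the bending energy is the curvature integral

    BE = ∫∫ (f_xx² + 2 f_xy² + f_yy²) dx dy = 8π · Σ_d w_dᵀ K w_d,

where w are the non-affine kernel weights and K the kernel matrix
(U(r) = r² log r in 2D, U(r) = r in 3D). BE = 0 iff the map is affine.
Symmetrization solves, in closed form, the optimal improper orthogonal
alignment of the relabelled mirror copy onto the original and averages the
two — the result is exactly symmetric and the operation idempotent.

## Worked example

```python
import paleoretro as pr
from paleoretro.geometry import midsagittal_plane

# a symmetric vault + bilateral template, then a purely affine "sediment"
# deformation: 10% lateral compression, 0.12 shear, 8 degree occipital tilt
mesh, template = pr.generate_calvarium()
deformed, dtpl, truth = pr.apply_taphonomic_deformation(
    mesh, template,
    pr.TaphonomicDeformation(compression=0.9, shear=0.12, tilt_deg=8.0),
)

# 1. diagnose: per-section bending energy of mirrored profile pairs
midsag = midsagittal_plane(dtpl.config, dtpl.bilateral)
report = pr.run_asymmetry_analysis(deformed, midsagittal=midsag)
print(report.table[["section_index", "be"]])
print("affine-consistent:", report.affine_consistent)

# 2. restore: symmetrize the template and warp the mesh
result = pr.retrodeform_mesh(deformed, dtpl)
print("max |signed distance| moved:", abs(result.distance_map.values).max())
```

Output from this exact script:

```
   section_index            be
0              0  2.910082e-08
1              1  4.560186e-08
2              2  5.232517e-26
3              3  4.132874e-25
4              4  1.074957e-22
5              5  9.144796e-26
6              6  7.708783e-24
affine-consistent: True
max |signed distance| moved: 3.529024165099707
```

All seven section energies sit within numerical noise of zero (the
affine-consistency threshold is 1e-3 on unit-centroid-size configurations),
correctly diagnosing the deformation as uniform — exactly the situation in
which symmetry-based retrodeformation is trustworthy. The restoration then
moves the vault walls by up to ±3.5 mm, outward on the flattened side and
inward on the bent side, and recovers ≥ 97% of the RMS deviation from the
pristine ground truth at shear magnitudes 0.05–0.2 (see
`pr.run_recovery_benchmark()`). Adding a localised dent
(`TaphonomicDeformation(..., dent=pr.DentSpec(...))`) flips the diagnosis:
the sections crossing the dent jump above 0.1 while the others stay at the
floor.

A command-line interface mirrors the stages:

```bash
paleoretro synth --out fixture/ --seed 1
paleoretro asym  --mesh fixture/pristine.ply --out report/
paleoretro retro --mesh fixture/deformed.ply --template fixture/template.json --out restored/
paleoretro bench --out bench.csv
paleoretro run   --config pipeline.json
```

## Layout

```
src/paleoretro/
  geometry.py     Procrustes, mirroring, TPS + bending energy, signed distances
  asymmetry.py    coronal sectioning, profiles, sliding semilandmarks, reports
  retrodeform.py  symmetrization, semilandmark relaxation, mesh warping
  completion.py   Bezier curves, even arc-length sampling, Delaunay patching
  synthetic.py    ground-truthed calvarium fixtures and deformations
  pipeline.py     orchestration, manifests, recovery benchmark
  cli.py          `paleoretro` command-line interface
docs/methods.md   model assumptions, numerical choices, limitations
```
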
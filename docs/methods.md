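# Methods

This note records the models behind `bolusforge`, the defaults and why
they were chosen, and what the synthetic experiments can and cannot say
about real treatments.

## Coordinate and unit conventions

World coordinates are millimetres; `world = origin + index * spacing`,
axes (x: right→left, y: anterior→posterior, z: inferior→superior). The
beam travels along +y as parallel rays (infinite-SSD simplification; no
source geometry is modelled). Doses are Gray. STL files carry no units;
everything emitted is millimetres. Relative mass density is recovered
from CT numbers with the single-slope calibration ρ = max(0, 1 +
HU/1000), chosen so that HU overrides and density overrides are one
mechanism: printed PLA is stored as 190 HU ↔ 1.19 g/cm³, coupling gel as
20 HU ↔ 1.02 g/cm³.

## The synthetic phantom

The phantom emulates the geometric situation the conformal bolus
addresses, not a particular patient: a gently curved anterior skin
surface; a chest wall whose thickness along the beam axis is
`base + f(x,z)` where `f` is a band-limited random field (three
low-frequency sinusoids with seeded random orientations and phases,
rescaled so the peak-to-peak range equals the requested variation
exactly); an ipsilateral lung directly behind the wall; a spherical
heart carved out of the lung. HU values are air −1000, lung −700, soft
tissue/wall/heart +40, plus Gaussian noise (σ = 10 HU). Defaults:
96×96×64 voxels at 1 mm, wall 15 mm base with 10 mm peak-to-peak
variation at a 60 mm spatial scale. Anisotropic spacing (e.g. 1×1×3 mm)
is supported throughout.

What it does **not** model: ribs and bone, oblique/curved chest
geometry beyond the mild skin curvature, respiratory motion, realistic
CT texture. Consequently, passing tests demonstrate the *mechanisms*
(uniform-depth design, step-edge inhomogeneity, falloff placement), not
clinical dose accuracy.

## Bolus design

For each en-face ray the chest-wall depth `d` is the distance from the
first BODY crossing (skin) to the first LUNG crossing. The conformal
thickness is `t = clamp(T − d, t_min, t_max)`; wherever the clamp is
inactive, `d + t = T` exactly. `T = "auto"` means the maximum field
depth — the thinnest bolus achieving uniformity. `t_min` defaults to
2 mm, the practical floor for a printed part that must survive handling;
`t_max` to 40 mm. The conventional step bolus quantises the same deficit
to the nearest attainable stack of 5 mm sheets (default stacks 0/5/10 mm,
i.e. two sheets), ties toward the thicker sheet (conservative coverage).
The bolus solid is voxelised on the CT grid by sweeping each ray's
thickness anteriorly from the skin, then isosurfaced and cleaned; its
mesh volume agrees with Σ thickness × pixel area to a few percent at
1 mm spacing.

**Energy-matched target.** `recommended_target_depth` implements the
standard electron conformal design rule: choose `T` (by bisection) so
that the mean distal chest-wall water-equivalent depth lands where the
PDD falls to 90% of the central-axis skin reference — i.e. the coverage
isodose wraps the distal target surface. The search keeps the
central-axis entry on the dose plateau; without that guard the fixed
point runs away once the reference point slides down the falloff.

## Surfaces

Isosurfacing uses marching cubes at level 0.5 after Gaussian
pre-smoothing of the binary mask (σ = half a voxel) so printed parts do
not inherit staircase normals; if smoothing would erase a structure only
a voxel wide, the raw mask is contoured instead. Watertightness is
defined strictly — every edge incident to exactly two faces — and is the
printability contract for every emitted mesh. `clean_mesh` removes
degenerate and duplicate facets, drops open face-connected components
(isolated dangling triangles) when a closed component exists, and is
idempotent; irrecoverable meshes raise rather than pass silently.
Shrink-wrapping re-surfaces an object by relaxing (Laplacian blend 0.3)
and projecting an enclosing icosphere (4 subdivisions, 2562 vertices)
onto the target; nearest points are found with a KD-tree over per-face
sample points followed by exact point-triangle projection. Ten
iterations reproduce a 20 mm sphere with ≈0.1 mm mean radial error. The
sphere tessellation and iteration count are free parameters; the
defaults trade accuracy against runtime and are exposed as arguments.

## The toy dose engine

The engine exists to demonstrate bolus-shape effects, and is labelled in
every interface as **not a clinical dose calculator**. Per ray, the
water-equivalent depth is the cumulative density-scaled path length from
the beam-entry surface (bolus if present, else skin). Dose is
`prescription × PDD(WED) / PDD(WED at the central-axis skin voxel)` —
the prescription (default 1.8 Gy × 28 = 50.4 Gy) is delivered to the
skin on the central axis. Two lateral effects are applied:

1. **Scatter blur** — a Gaussian over the en-face plane, σ = 3 mm by
   default; enough to feather field edges and round step transitions
   without washing them out.
2. **Edge scatter** — at a lateral discontinuity of overlying material,
   side-scatter equilibrium breaks: the thin side gains dose, the thick
   side loses it. This is modelled as a multiplicative fluence factor
   `1 + k·(G_σ(w) − w)·decay(WED)` with `w` the per-column entry
   water-equivalent thickness and a linear decay to zero at the
   practical range. `k` = 0.02/mm is anchored to the magnitude of
   published bolus-edge perturbations (roughly ±10% for a 1 cm step) and
   vanishes identically for flat or smoothly conformal boluses, so it
   changes nothing in slab benchmarks. A pure broad-beam calculation is
   recovered with `k = 0`.

Default PDD tables are piecewise-linear in WED with R100/R90/Rp at the
rule-of-thumb depths E/4, E/3.2, E/2 cm, a buildup knee giving the fast
rise + plateau of clinical electron beams, a sigmoid falloff through
R50/R10, surface dose rising with energy (82–91%), and a 2%
bremsstrahlung tail. They are shipped as a JSON data file and fully
overridable; they are plausible shapes, not measured beam data.

## Evaluation

The differential DVH is a voxel-volume-weighted histogram at 0.1 Gy bins
(top edge inclusive), so Σ v·ΔD equals the structure volume exactly.
D_mean/D_std use the midpoint rule and agree with direct voxel
statistics to within half a bin; both routes are exported. CI uses an
inclusive ≥ threshold at 90% of prescription; an empty reference-isodose
region raises an explicit undefined-CI error rather than returning 0.
Volumes are voxel-count × voxel-volume with no partial-volume
interpolation. Plan comparison first rescales both plans to the same
chest-wall mean dose (the conventional plan's, by default), then
assembles per-structure means, D_std, CI and percent changes; display
rounding is half-away-from-zero at the printed precision (percent
changes: integer when |value| ≥ 10, one decimal otherwise) while raw
values are kept in the exported records. Cohort rows are column-wise
means and medians (even count → midpoint of the central pair). The
shipped six-patient reference table carries printed values whose
published aggregates were partly computed pre-rounding; the package
reports what the printed inputs actually give (e.g. conventional lung
column mean 9.12 Gy) and does not silently "correct" either side.

## The step-vs-conformal study design

The packaged comparison (tests, acceptance script, example 05) uses the
two-sheet conventional device against the conformal design at a
per-energy coverage-matched target, σ = 3 mm, t_min = 0, on the default
phantom. Two findings from exploring this design space are worth
recording:

- With sheet stacks deep enough to reach any target, the conventional
  bolus's quantisation error is symmetric and its *sign* effects on lung
  dose are decided by where the ideal-thickness distribution falls
  relative to the 5 mm lattice — a knife-edge, not a physical effect.
  The robust lung-sparing and conformity advantages of the conformal
  bolus arise from the *systematic undercompensation* of a
  range-limited device, which is exactly the clinical situation the
  two-sheet bolus represents.
- At 12 MeV the coverage-matched target (~34 mm) exceeds the two-sheet
  range everywhere, so the "step" bolus degenerates to a flat 10 mm
  slab: no edges, hence no hot/cold spots, and a grossly overshooting
  plan whose chest wall sits entirely on the PDD plateau. In a
  broad-beam model such a plan is *maximally homogeneous* in the target
  while failing badly on lung dose and conformity — the classic
  homogeneity-vs-conformity trade-off. The packaged 12 MeV comparison
  therefore shows the conformal bolus winning on lung and CI but not on
  chest-wall D_std; clinically, homogeneity differences between the two
  bolus types are small and not universally in the conformal bolus's
  favour either.

## Problem sizes and determinism

All shipped experiments run on the 96×96×64 @ 1 mm phantom (≈0.6 M
voxels); a full design + two-energy dose comparison completes in about a
second, and the entire test suite in a few seconds. Every random element
(phantom field phases, HU noise) derives from a single integer seed;
identical seeds give bit-identical phantoms, designs, dose grids and
reports, which the suite asserts end-to-end.

## Known limitations

Single parallel beam (no multi-field chest-wall techniques), no
divergence or obliquity corrections, no Monte-Carlo or pencil-beam
transport, no DICOM-RT, no bone heterogeneity, and PDD tables that are
declared shapes rather than commissioning data. The toolkit demonstrates
design mechanisms and evaluation mathematics; absolute dose numbers on
phantoms are illustrative only.
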
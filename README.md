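# bolusforge

Design and evaluate **3D-printable conformal electron boluses** for
post-mastectomy chest-wall radiotherapy — at desk scale, on synthetic CT
phantoms.

After a modified radical mastectomy the chest wall is treated with an
electron beam. Because the wall's thickness varies, a flat or stepped
tissue compensator (bolus) leaves hot and cold spots and pushes dose
into the ipsilateral lung and heart. A *conformal* bolus fixes this: its
lower surface rides the skin and its upper surface is an offset of the
lung-sided chest-wall surface, so that chest wall + bolus has a uniform
depth along the beam and the distal dose falloff hugs the target.
`bolusforge` implements the full workflow for this idea:

- **phantom** — synthetic hemithorax CT phantoms (HU grid + BODY /
  CHEST_WALL / LUNG_IPSI / HEART masks) with a smoothly undulating wall
  thickness, anisotropic-spacing support, and seeded determinism;
- **design** — per-ray chest-wall depth maps `d(x)`; conformal thickness
  `t(x) = clamp(T − d(x), t_min, t_max)` with `T = max d` ("auto") or an
  energy-matched target; the conventional step bolus as nearest-5-mm-sheet
  quantisation (ties to the thicker sheet);
- **surfaces** — marching-cubes isosurfacing, defect removal to strict
  watertightness (every edge on exactly two faces), shrink-wrap
  re-surfacing, and a byte-exact binary/ASCII STL codec (80-byte header +
  uint32 count + 50-byte facets — a 12-facet cube is exactly 684 bytes);
- **dose** — a *declared toy* broad-beam electron engine: per-ray
  water-equivalent depth (WED) via density scaling (`ρ = 1 + HU/1000`,
  printed PLA overridden to 1.19 g/cm³), tabulated percent-depth-dose
  curves for 6/9/12/15 MeV, lateral Gaussian scatter, and an
  edge-scatter term that produces the paired hot/cold spots of stepped
  compensators. Not a clinical dose calculator;
- **evaluation** — differential DVH `v(D)` with exact volume
  conservation, its moments

  D_mean = ∫ D·v(D) dD / ∫ v(D) dD,  D_std = √(∫ (D − D_mean)²·v(D) dD / ∫ v(D) dD),

  the conformity index CI = TV_RI / V_RI at the 90% reference isodose,
  equal-chest-wall-mean plan normalisation, and cohort-style comparison
  tables with percent changes and mean/median rows.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_compare_step_vs_conformal.py` designs both bolus
types on the default phantom (wall 15 ± 5 mm, 96×96×64 @ 1 mm), computes
9 MeV toy dose for each, normalises to equal chest-wall mean dose and
prints the comparison:

```
conformal vs step: lung D_mean -6.6%, CI 0.494 -> 0.547, CW D_std -19%
```

i.e. on this phantom the conformal bolus lowers the mean lung dose by
6.6%, raises the 90%-isodose conformity to the chest wall from 0.494 to
0.547, and makes the chest-wall dose 19% more homogeneous than the
conventional two-sheet step bolus. The same script re-aggregates the
shipped published six-patient cohort table (printed per-patient values),
reproducing its mean/median rows, e.g. a conformal-bolus lung-dose
cohort mean of 8.24 Gy vs 9.12 Gy conventional.

A thin CLI mirrors the library:

```bash
bolusforge phantom --out ph --seed 0
bolusforge design  --phantom-dir ph --mode conformal --out des
bolusforge dose    --phantom-dir ph --bolus-thickness des/thickness_conformal.nrrd --energy 9 --out dose.nii
bolusforge dvh     --dose-file dose.nii --phantom-dir ph
```

## Scope

The printing hardware itself (slicing, G-code), DICOM-RT I/O, CBCT-based
bolus alignment and clinical dose engines are out of scope; the
deliverable is the printable STL plus the evaluation toolchain. See
`docs/methods.md` for the model assumptions and their limits.
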
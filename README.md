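# vertefem

Finite-element simulation of vertebral compression (wedge) fractures from
quantitative-CT-style image data.

Vertebral compression fractures collapse the anterior column of a vertebral
body while the posterior column stays intact. `vertefem` implements the full
QCT-based finite-element pipeline used to predict the stiffness, strength and
failure pattern of an isolated vertebral body under axial compression:

1. **Phantom / image input** — a 3-D Hounsfield-unit (HU) volume with voxel
   spacing, either loaded from NIfTI or generated synthetically (a
   vertebral-body-like phantom with a bright cortical shell, a heterogeneous
   trabecular core and a concave waist).
2. **Density calibration** — the linear map ρ = a + HU·b (g/cm³), fit by
   ordinary least squares to cortical-core density samples and clamped from
   below at 0.01 g/cm³ (defaults a = 0.48, b = 4.6·10⁻⁴).
3. **Material mapping** — per-element isotropic elastic–perfectly-plastic
   properties from apparent density:

       E   = 3050 ρ^1.81        (MPa)
       ε_y = s · 0.0065 ρ^−1.42
       σ_y = E ε_y,   ν = 0.3

   where `s` is a dimensionless yield-strain scaling factor (default 1; the
   experimentally calibrated value for porcine vertebral bodies is 3.1).
4. **Meshing** — every masked voxel is split into six conforming linear
   tetrahedra (C3D4); cranial/caudal surfaces are labelled automatically and
   an anatomical frame (transverse plane, sagittal plane, center of mass,
   anteroposterior body width) is constructed.
5. **Follower-load solve** — displacement-controlled, quasi-static Newton
   solve with J2 (von Mises) perfect plasticity and radial return. The
   cranial surface is rigidly coupled to a control point placed 10 % of the
   body width anterior to the projected center of mass; its transverse
   translations are locked, its three rotations free, and the caudal surface
   is fully fixed — the construction that produces the anterior wedge
   failure mode.
6. **Post-processing** — stiffness (kN/mm) as the OLS slope of the linear
   part of the load–displacement curve, strength (kN) as its peak, and a
   fracture map labelling elements with nonzero equivalent plastic strain
   (PEEQ) into anterior / lateral / posterior sectors.
7. **Comparison** — percent errors and the coefficient of determination
   against experimental curves, plus 1-D calibration of the yield-strain
   scale against measured strengths.

## Worked example

Run the full pipeline on a coarse synthetic phantom (2 mm voxels, ≈5700
tetrahedra, compressed by 5 % of its height in 20 increments — about 15 s):

```python
from vertefem.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(
    output_dir="run_out", seed=42,
    phantom=dict(height=18.0, semi_axis_ap=14.0, semi_axis_ml=11.0, voxel=2.0),
    displacement_fraction=0.05, n_increments=20,
))
print(manifest["result"])
```

prints (abridged):

```
stiffness_kN_mm        28.95
strength_kN             7.62
sector_mean_peeq       anterior 0.0559  lateral-left 0.0322
                       lateral-right 0.0335  posterior 0.0160
final_sagittal_tilt_deg 3.17
```

Reading the numbers: the simulated body is elastically stiff (29 kN/mm —
the blocky, fully bonded phantom is stiffer than a real vertebra), fails at
7.6 kN, and develops the anterior-dominant plastic-strain pattern of a wedge
fracture — the mean PEEQ in the anterior sector (0.056) is three and a half
times the posterior value (0.016) — while the free rotation of the loading
point tips the anterior rim caudally by ~3°. The run directory contains the
phantom (`volume.nii`), densities, the Abaqus-dialect mesh (`mesh.inp`), the
load–displacement curve (`curve.csv`), ParaView fields (`fields.vtu`) and a
manifest with SHA-256 hashes of every artifact (re-running the same config
and seed reproduces them bit for bit).

The same stages are available from the shell:

```bash
vertefem phantom vertebra --seed 1 -o vol.nii
vertefem calibrate apply --volume vol.nii -o rho.nii
vertefem mesh build --volume vol.nii -o mesh.inp
vertefem run --config run.yaml
```

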
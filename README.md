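# fdmar — a synthetic testbed for metal artifact reduction in flat-detector CT

Metal implants — coil masses, aneurysm clips, stent struts — corrupt
rotational flat-detector CT angiography with beam-hardening bands and
photon-starvation streaks, often badly enough that the key follow-up
question after aneurysm treatment (*is there residual perfusion at the
aneurysm neck?*) cannot be answered.  Normalized-interpolation metal
artifact reduction (MAR) addresses this by segmenting metal in an initial
reconstruction, replacing the metal trace in *normalized* projections by
interpolation, and reconstructing again.  Clinical evaluations of this
approach report qualitative gains; this package makes those claims
quantitatively testable by rebuilding the whole chain inside a controlled
2-D simulation with known ground truth.

It is aimed at researchers who want a transparent, dependency-light
sandbox for MAR experiments: every input is generated by seeded code
(no data downloads), every stage is a documented function, and every claim
in the docs is backed by a test or by `scripts/acceptance.py`.

## What is inside

| module | contents |
|---|---|
| `fdmar.phantoms` | seeded axial head phantoms: vessels, aneurysm remnant, coil/clip/stent implants, named ROIs, material table |
| `fdmar.projector` | parallel-beam short-scan (220°) line integrals; polychromatic Poisson measurement model; protocol presets (5 s/133, 10 s/248, 20 s/496 views) |
| `fdmar.recon` | short-scan FBP with "sharp"/"smooth" kernels, redundancy weighting, sub-FOV cropping |
| `fdmar.mara` | the correction chain: segmentation → metal trace → tissue-prior normalization → inpainting → denormalization → boundary smoothing → FBP → metal re-insertion → monotone TV reduction |
| `fdmar.evaluation` | ROI metrics (RMSE, artifact index, neck CNR), Cohen's κ, exact McNemar, chi-square, Wilcoxon signed-rank, ROC AUC with bootstrap CI, simulated rating tables |
| `fdmar.io`, `fdmar.pipeline`, `fdmar.cli` | NIfTI/MetaImage/sinogram I/O, manifest-writing experiment runner, `fdmar` command line |

The central quantity on the correction side is the normalized sinogram:
with measured projections *p* and the forward projection *p̂* of a
tissue-classified prior, the algorithm interpolates *p/p̂* (not *p*) across
the metal trace and multiplies back, so the interpolation bridges the gap
over a nearly flat profile instead of inventing anatomy.  On the evaluation
side, residual-neck detectability is scored as
CNR = |mean(neck) − mean(adjacent parenchyma)| / SD(adjacent parenchyma),
and study-level detection performance as the ROC area over seeded
residual-present/absent cases.

## Worked example

```python
from fdmar import (ScenarioConfig, PhysicsModel, MaraParams,
                   generate_phantom, default_geometry, simulate_measurement,
                   to_line_integrals, run_mara, compute_image_metrics)

scenario = ScenarioConfig(implant_kind="coil", residual_filling_present=True,
                          grid_size=256, noise_seed=7)
phantom = generate_phantom(scenario)
geometry = default_geometry("5s", 256, phantom.voxel_size_mm)
physics = PhysicsModel(seed=8)  # 5-bin spectrum, Poisson noise, I0=1e5

measured = to_line_integrals(simulate_measurement(phantom, geometry, physics),
                             physics)
result = run_mara(measured, geometry, "sharp", MaraParams(),
                  grid_size=256, voxel_size_mm=phantom.voxel_size_mm)

for name, vol in (("uncorrected", result.uncorrected),
                  ("corrected", result.corrected)):
    m = compute_image_metrics(vol, phantom)
    print(f"{name:12s} artifact_index={m.artifact_index:.4f} "
          f"neck_cnr={m.cnr_residual:.2f}")
```

Output:

```
uncorrected  artifact_index=0.0081 neck_cnr=2.85
corrected    artifact_index=0.0024 neck_cnr=7.27
```

The artifact index (excess standard deviation, in 1/mm, of the brain
parenchyma within 2 cm of the implant; soft tissue itself is 0.020/mm)
drops more than three-fold, and the contrast-to-noise ratio of the
residual neck — ~3 and buried in streak noise before correction — rises
past 7, i.e. the remnant becomes callable.
The same pipeline is available from the shell:

```bash
fdmar simulate --implant coil --residual --grid 256 --seed 7 --out run/
fdmar mar --sinogram run/sinogram.raw --grid 256 --out run/mar/
fdmar run-all --seed 7 --out run_all/          # full chain + manifest
```

`fdmar correct-volume` accepts an already-reconstructed NIfTI/MetaImage
volume and runs the correction from re-projection onward.

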
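# Methods

`fdmar` is a fully synthetic 2-D testbed for normalized-interpolation metal
artifact reduction (MAR) in rotational flat-detector CT angiography of
treated intracranial aneurysms.  Everything a study needs — anatomy, implant,
acquisition, corruption, correction, and evaluation — is generated by code
from a single integer seed, so the qualitative clinical claims about MAR
(artifact burden falls, residual aneurysm perfusion becomes detectable)
become quantitative, repeatable experiments against known ground truth.

## Phantoms

A phantom is a square attenuation slice (1/mm at a reference energy) plus an
integer label map over four material classes: soft tissue, bone, iodinated
blood, and metal.  The anatomy is stylized — an elliptical head with a ~4 mm
skull ring, a 3 mm contrast-filled parent vessel, two incidental small
vessels, and a ~10 mm aneurysm sac packed with a device — because what
matters for MAR physics is the attenuation ordering and the spatial relations
(device abutting vessel, neck remnant between them), not anatomical fidelity.
Implant kinds: `coil` (dense irregular blob filling the sac), `clip` (one
thin bar), `multi_clip` (two or more disjoint bars), `stent_coil` (blob plus
sparse struts on a surrounding arc), `none` (metal-free twin).

The residual neck is a ~3 mm contrast pocket at the sac base facing the
parent vessel, separated from the device by a ~1.8 mm carved gap (a remnant
is by definition not packed with coil).  Scenarios differing only in the
residual flag are pixel-identical outside the neck site; scenarios differing
only in implant kind are identical outside the device region.  This
paired-twin construction is what makes the controlled comparisons below
possible.  The candidate neck location is always exposed as the `neck_site`
ROI; `residual_neck` exists only when the neck actually fills, so detection
experiments can score present and absent cases at the same location.

The field of view is fixed at 153.6 mm (512 × 0.3 mm voxels at the default
grid); smaller grids keep the field of view and coarsen the voxels, so sizes
in mm are grid-independent.  `adjacent_parenchyma` is brain tissue within
20 mm of the implant site; `contralateral_parenchyma` is its mirror image
across the midline.

### Materials

Each material carries a five-bin attenuation curve μ(E) = μ₇₀·(70/E)^k over
50–90 keV: soft tissue (μ₇₀ = 0.020/mm, k = 0.4), bone (0.048, 1.6),
contrast blood (0.034, 2.5), metal (0.80, 2.0).  The metal value is far
below real platinum — a deliberate desk-scale compromise that still drives
the two artifact mechanisms (differential hardening and photon starvation)
at the default fluence.  A phantom's reference attenuation is the
*spectrum-weighted mean* of the curve rather than the value at one energy;
by Jensen's inequality this makes the measured polychromatic attenuation a
strict lower bound of the reference line integral on any heterogeneous ray,
which is the beam-hardening direction the artifact model must exhibit, and
it makes the single-energy noiseless case exactly log-invertible.

## Forward model and reconstruction

The projector computes parallel-beam line integrals by Joseph-style ray
sampling: bilinear interpolation at half-voxel steps along each ray, zero
outside the grid.  The scan is a 220° short scan; protocol presets fix the
view count (5 s → 133, 10 s → 248, 20 s → 496 projections).  The
measurement model attenuates the five-bin spectrum per material path length
(one projection per material, any number of energy bins), scales by
I₀ = 10⁵ photons per bin, and optionally draws Poisson counts.  Zero counts
are clamped to one photon before the log, capping measured attenuation at
ln I₀ ≈ 11.5 — through the coil mass the true line integral exceeds this,
so metal-crossing rays are both biased and noisy, which is precisely the
corruption MAR exists to remove.

Reconstruction is filtered backprojection: per-view ramp × window filtering
by FFT with 4× zero padding (DC exactly zero), pixel-driven backprojection
with linear detector interpolation, and short-scan redundancy weights of 1/2
on views whose line orientation appears twice in the 220° arc (the first and
last 40°).  The "sharp" kernel is a ramp with a cosine roll-off closing at
Nyquist; "smooth" is ramp × Hann closing at 0.7 Nyquist.  The vendor kernel
is proprietary; these are documented stand-ins with the right ordering
(sharp ≥ smooth at every frequency).  A half-size sub-FOV is produced by
reconstructing the full grid and cropping around a caller-supplied center.

## The correction chain

1. **Uncorrected FBP** of the measured line integrals.
2. **Metal segmentation** by threshold (default: midpoint of the bone and
   metal reference attenuations).  All 8-connected components are kept and
   processed jointly, so multi-implant cases are corrected in one pass.
3. **Metal trace**: forward projection of the binary mask, thresholded at
   >0 and dilated by 2 detector bins so corrupted boundary samples are
   replaced too.
4. **Prior volume**: a three-class tissue prior — air (below half the soft
   reference) zeroed, the soft band (up to the soft/bone midpoint) flattened
   to its own median, denser structures (bone, vessels, a filling remnant)
   kept, and the metal mask *dilated by 2.4 mm* clamped to the soft median.
   The dilation absorbs the bright partial-volume fringe that thresholding
   misses.  Flattening the soft band is essential: a prior that merely
   clamps metal carries the beam-hardening halo around the implant into the
   normalization denominator, and the corrected image then reproduces the
   halo at the aneurysm neck — in our pilot experiments this single choice
   decided whether correction helped or hurt neck detectability.
5. **Normalization**: measured ÷ max(prior projection, ε), ε = 10⁻³.
6. **Inpainting**: per view, 1-D linear interpolation across the trace along
   the detector axis; constant extension at detector edges; a view with no
   off-trace samples falls back to the off-trace mean of the nearest valid
   view (logged, never silent).  Off-trace entries are copied through
   bit-identically.
7. **Denormalization** multiplies by the same max(prior, ε) factor, so
   normalize→denormalize is the exact identity everywhere — including rays
   where the prior is below ε.  (Multiplying by the raw prior would break
   the off-trace preservation guarantee exactly where the prior vanishes.)
8. **Boundary smoothing**: within `band` bins outside the trace edge the
   output ramps linearly from corrected (at the trace) to measured (at the
   band edge); band = 0 disables it.
9. **Corrected FBP**, optional **metal re-insertion** (segmented voxels
   copied back from the uncorrected volume so the implant stays visible to a
   reader), and **TV reduction**: gradient descent on smoothed isotropic
   total variation outside the metal mask, with backtracking step halving so
   TV is non-increasing at every iteration by construction.  The step is
   scaled by image dynamic range over gradient magnitude, making the setting
   scale-free.

With an empty metal mask the chain degrades to the uncorrected volume passed
through TV only (bit-identical at zero iterations); the degenerate path is
exercised by the test suite.

### Defaults

| parameter | default | why |
|---|---|---|
| metal_threshold | (bone_ref + metal_ref)/2 ≈ 0.49/mm | separates metal from bone across the hardening-depressed range |
| trace_margin_bins | 2 | covers partial-volume fringe rays |
| epsilon | 1e-3 | ≪ any through-head line integral (~3) |
| boundary_band_bins | 3 | one PSF width of blending |
| tv_iterations / tv_step | 10 / 0.1 | visible streak suppression without washing out vessels |
| reinsert_metal | true | implants must stay identifiable |
| prior_dilation_mm | 2.4 | fringe clamp; stays clear of the ≥1.8 mm neck gap |

All parameters are recorded in output provenance tables.

## Evaluation

Objective surrogates stand in for ordinal reader grades:

* **rmse_roi** — per-ROI RMSE against ground truth (1/mm);
* **artifact index** — SD in the adjacent parenchyma minus the same SD in
  the reconstruction of the no-metal twin under identical physics (excess
  noise attributable to the implant);
* **cnr_residual** — |mean(neck site) − mean(adjacent parenchyma)| divided
  by SD(adjacent parenchyma).  The background is deliberately the
  artifact-laden adjacent region, not the quiet contralateral hemisphere: a
  reader judges the neck against its immediate surroundings, and it is
  exactly this local noise that makes uncorrected images unreadable.  With a
  contralateral background the uncorrected condition detects the remnant
  almost perfectly and the with/without-correction ordering inverts.

`detect_residual` thresholds the CNR and exposes it as the continuous ROC
score.  The observer statistics — Cohen's κ, exact-binomial McNemar,
Pearson chi-square (no continuity correction by default, switchable),
Wilcoxon signed-rank, and ROC AUC as pairwise concordance with a seeded
bootstrap percentile CI — are implemented from their defining formulas so
the tests can pin each against exhaustive enumeration; established library
implementations (scikit-learn, statsmodels, SciPy) serve as independent
cross-checks, never as the implementation.  The Wilcoxon test enumerates
all 2ⁿ sign assignments for n ≤ 12; beyond that it uses a tie-corrected,
continuity-corrected normal approximation with an Edgeworth kurtosis term
(the null of the positive-rank sum is platykurtic), which keeps the exact
and approximate branches within ~0.01 at the crossover.

`simulate_ratings` generates tidy two-rater ordinal tables from a
latent-quality model (case burden + condition shift + rater noise, rounded
onto 1–3 / 1–4 scales) for exercising the statistics at study scale.

## Simulation studies and what they show

`studies.artifact_reduction_study` runs seeded coil cases (default 20 at
256², 133 views, polychromatic + Poisson) and compares artifact index and
mean ROI-RMSE with and without correction; each case's baseline comes from
its own no-metal twin.  `studies.detectability_study` runs residual-present
and residual-absent cases (default 20+20; the packaged studies use 192² to
keep a full study under a few minutes on one CPU) and computes detection
AUCs from the CNR scores.  Under the default conditions correction lowers
the artifact index in essentially every run, lowers mean ROI-RMSE, and
raises detection AUC — the directional reproduction of the clinical
finding, not a reproduction of any clinical number: patient data, scanner
spectra, and human readers are all outside this package.

Passing these studies shows the algorithm behaves correctly *on data whose
corruption mechanisms it was built for* (hardening + Poisson starvation in
parallel geometry).  It does not show robustness to scatter, motion, cone-
beam effects, detector nonidealities, or real device spectra — none of
which are modelled.

## Numerical choices and degenerate inputs

* Zero-count clamp: counts < 1 → 1 before the log (documented cap ln I₀).
* Interpolation at equidistant neighbors follows linear interpolation
  exactly; no tie-breaking is needed because the inpainting interpolates
  rather than selects.
* A fully-covered view in inpainting falls back to the nearest valid view's
  off-trace mean and logs a warning; an entirely covered sinogram raises.
* TV backtracking halves the step up to 30 times and otherwise stops,
  so the descent contract holds for any input, including flat images.
* FBP of an all-zero sinogram is exactly zero; filtering a constant view is
  zero up to finite-detector boundary ringing (the DC bin itself is zeroed).

## Known limitations

* 2-D parallel geometry; the real system is 3-D cone-beam on a C-arm.
* Stylized spectra, materials, and device shapes; metal attenuation is
  orders of magnitude below platinum so that desk-scale grids starve rather
  than saturate.
* The segmentation threshold is a global constant; heavily hardened small
  implants may be under-segmented (the prior dilation partly compensates).
* Correction quality at the neck depends on the prior retaining the remnant;
  when dark bands depress the neck below the soft/bone midpoint the prior
  flattens it and the corrected CNR drops — visible as occasional low
  outliers in the detectability study, mirroring the imperfect clinical
  sensitivity of MAR-corrected imaging.
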
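# Methods

`octaprof` quantifies macular microvascular change in retinitis pigmentosa
(RP) relative to the border of the preserved near-infrared
autofluorescence area (APA), implementing the multimodal SS-OCTA +
NIR-FAF quantification as a tested, scriptable pipeline. This note
documents the model assumptions, the parameters that matter, the
synthetic-data generator, and the numerical choices made where the
method left the design open.

## The measurement model

Each subject contributes four co-located en-face images of the macula: the
superficial vascular complex (SVC), deep capillary complex (DCC) and
choriocapillaris (CC) angiograms of a 6 × 6 mm swept-source OCTA scan, and
one NIR-FAF image. In RP the NIR-FAF signal collapses abruptly where the
retinal pigment epithelium / photoreceptor complex degenerates, so the
preserved-autofluorescence area is a per-eye anatomical reference: the
analysis asks how vessel density (VD) and choriocapillaris flow deficits
(FD) behave *as a function of distance from that border*, rather than in
fixed anatomical sectors that mix preserved and atrophic tissue.

The pipeline stages are:

1. **Registration** (`octaprof.register`). The angiogram set is registered
   to the NIR-FAF frame with a similarity transform (translation, rotation
   within ±10°, isotropic scale within [0.8, 1.25]), using the large
   superficial vessels as the shared landmark: they are bright flow
   structures on the SVC and dark shadows on NIR-FAF. Both images are
   ridge-enhanced with a single-scale Frangi filter (σ matched to ≥ 50 µm
   vessels; dark ridges for NIR-FAF) and the transform maximizes
   normalized cross-correlation over a coarse-to-fine grid, with FFT
   cross-correlation and sub-pixel parabolic refinement for translation at
   each (rotation, scale) node. One transform, estimated on the SVC, is
   applied to all three slabs (the scan is a single volume). Resampling is
   bilinear; pixels mapped from outside the acquired field are flagged
   invalid, never zero-filled. A best-correlation floor (default NCC 0.2)
   turns structure-free inputs into an explicit registration failure.
2. **Binarization** (`octaprof.binarize`). SVC and DCC angiograms pass a
   white top-hat (disk radius 12 px on the 1024-px grid) and are then
   binarized twice: (a) single-scale Frangi vesselness (σ = 2 px) followed
   by Huang fuzzy-entropy global thresholding of the 8-bit response
   histogram, and (b) local median thresholding (disk radius 15 px, strict
   inequality, reflection padding). The final flow map is the pixelwise
   AND of the two branches. The CC is binarized with a single global
   threshold set one SD below the pooled pixel mean of a normative
   database of young healthy CC angiograms; pixels below threshold are
   flow deficits. Large vessels are masked by smoothing the SVC with a
   15 × 15 px Gaussian window (σ = window/4) and thresholding the
   normalized intensity at 0.4 (plus a 1-px dilation); the mask excludes
   those pixels from all slabs.
3. **Sampling** (`octaprof.profiles`). Metrics are computed in a
   contiguous series of 0.1 × 0.8 mm rectangles running from the fovea
   superiorly, inferiorly and temporally (the nasal sector is not
   assessed; the optic nerve head would truncate it). Per area,
   VD = flow / analyzable pixels and FD = non-flow / analyzable pixels.
   An area is dropped when the large-vessel mask covers more than 40% of
   it or when less than half of it lies inside the registered field.
4. **Edge alignment** (`octaprof.nirfaf`). The NIR-FAF intensity-level
   (IL) profile is computed on the same sample areas; the APA border is
   the steepest decline of the 3-sample-smoothed profile, accepted when
   the drop exceeds 30% of the central plateau, with the final index
   pinned by the half-amplitude crossing of the raw profile (see
   *Numerical choices*). The sample area containing the border becomes
   offset 0; inside-APA areas are negative, outside positive. Subjects
   without a detectable border in all three directions are reported and
   excluded from the quantitative comparison. Manual edge indices can be
   supplied to override detection.
5. **Statistics** (`octaprof.stats`). At every offset, patient and
   matched-control values are compared with a two-sided Wilcoxon
   signed-rank test (exact conditional null up to 25 informative pairs;
   normal approximation with continuity and tie correction above; zeros
   dropped, ties mid-ranked; p undefined below 5 informative pairs). No
   multiple-testing correction is applied across offsets; instead a
   difference is declared significant only over runs of at least five
   consecutive offsets with p < 0.05 — the run rule is the error-control
   device for the spatially correlated profile. Summary rows report the
   control-minus-patient mean ± SD (and range) across the offsets beyond
   the border, in percent; the SD is across positions (a per-subject
   variant is a flag away). Controls have no APA, so each control profile
   is aligned with its matched patient's border distance from the fovea.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| grid | 1024 px / 6 mm (5.859 µm/px) | native working grid; 256 px = 1.5 mm |
| top-hat radius | 12 px | background flattening scale (capillary-preserving) |
| vesselness σ | 2 px | tubular-structure scale for capillaries |
| local median radius | 15 px | adaptive threshold neighborhood |
| LV window / threshold | 15 × 15 px / 0.4 | large-vessel mask smoothing and absolute cut |
| CC threshold | pooled mean − 1 SD | from the normative CC database |
| sample area | 0.1 × 0.8 mm, step 0.1 mm | directional profiling unit |
| mask exclusion | > 40% of area | sample-area drop rule |
| α, run length | 0.05, ≥ 5 | positionwise level and run rule |
| SSI gate | > 7/10 (strict) | scan-quality inclusion rule |

Pixel-unit parameters are defined on the 1024-px grid and rescaled with
the working grid (`BinarizationParams.for_grid`), so the operators act at
fixed physical scale. Intensities are normalized by the *dtype* maximum,
never per-image, so absolute thresholds (0.4, the CC threshold) are
comparable across images.

## The synthetic-data generator

No clinical images are distributed with the analysis, so
`octaprof.synth` generates paired cases with known ground truth:

* an elliptical APA (configurable semi-axes and center offset) with a
  sharp (1 px) NIR-FAF intensity step, an optional hyperautofluorescent
  ring just inside the border, and dark large-vessel shadows — the
  landmark the registration needs;
* capillary beds built by skeletonizing band-pass noise at three spatial
  scales and dilating to ~18 µm width; a smooth "keep" field then prunes
  web pixels region-by-region so the labeled vessel fraction matches the
  requested density *exactly* (to one pixel) inside and outside the APA.
  Density targets are therefore enforced against the emitted label map,
  never against the pipeline's own binarization;
* CC speckle with contiguous dark patches occupying an exact labeled
  deficit fraction per region;
* bright curvilinear large vessels (≥ 50 µm) crossing the field,
  identical in a patient and its matched control;
* an optional similarity misalignment between the angiogram frame and the
  NIR-FAF frame (the ground-truth transform is recorded);
* matched controls using the inside-APA densities everywhere, with
  uniform-high NIR-FAF (healthy-control NIR-FAF appearance is not
  modelled beyond that). The control's labels are trimmed on the
  patient's region split with equal targets, pinning its per-region label
  fraction exactly.

Default conditions: DCC VD 0.42 inside / 0.12 outside (a 30-point
deficit), SVC VD 0.40 / 0.37, CC FD 0.06 / 0.11, ellipse 1.5 × 1.0 mm,
six large vessels, additive noise SD 0.03. All randomness derives from
one integer seed through fixed child streams; identical seed and
parameters give bit-identical images.

What the generator does **not** emulate: OCTA speckle statistics and
projection or motion artifacts, signal attenuation, the irregular APA
shapes of sectorial RP (rays crossing the border once is assumed), and
capillary morphology below ~18 µm. Grids below ~512 px cannot separate
capillaries from large vessels at all (both end up several pixels wide),
so the large-vessel mask over-covers there; such grids are used only for
plumbing tests. A pass on synthetic data therefore shows the chain is
implemented correctly and recovers known truth under controlled
conditions — not that the measured clinical magnitudes would be
reproduced on device images.

Calibration at the 1024-px conditions: the binarized DCC VD tracks the
label density to within about 2 points at 0.12–0.42 (an injected 30-point
difference reads back 26–28 points — the AND of the two branches
undercounts slightly at high density), CC FD reads 2–4 points above
target, and the Dice overlap between binarized flow and the label map is
≈ 0.85–0.91. These figures are what the acceptance script re-measures.

## Numerical choices

* **"Window size, 12 pixels"** is read as a disk *radius* for the top-hat,
  matching the behaviour of the ImageJ-based protocols this chain
  descends from; it is exposed as a parameter.
* **Huang threshold**: Shannon-form fuzzy entropy over the 8-bit
  histogram, memberships 1/(1 + |g − m|/C); ties resolved to the lowest
  level; single-valued histograms are an error. The implementation is
  checked against exhaustive enumeration.
* **Vesselness normalization** saturates at the 95th percentile of the
  positive Frangi responses before 8-bit quantization: a handful of very
  bright arterioles would otherwise compress the capillary response range
  and make the global threshold unstable against the image's
  preserved/atrophic composition.
* **Local median** uses the 8-bit quantized image (sliding-histogram
  median), strict inequality, reflection padding, offset constant 0.
* **CC normative pooling** is pixel-pooled by default (per-image
  mean/SD averaging is available as `pooling="image"`); no compensation
  for local signal attenuation is applied. A database whose pooled SD is
  zero returns its mean as the threshold.
* **IL profiles exclude large-vessel-mask pixels** from each area mean
  (interpolating areas that are fully masked): vessel shadows otherwise
  dent the IL profile with declines that can out-steepen the APA border.
* **Edge index**: the steepest decline localizes the border region and
  gates detection (≥ 30% drop relative to the central plateau); the
  reported index is the first sample whose raw value falls below the
  half-amplitude level between the running pre-edge maximum (which
  includes any ring) and the profile floor. This pins "the area containing
  the border" to within one 0.1-mm step of the analytic border on
  synthetic ellipses. For irregular borders crossed multiple times the
  outermost steep decline wins; multiplicity is not modelled.
* **Registration search**: coarse grid 2° × 0.05 scale, two refinement
  passes to 0.1° × 0.0025; translation sub-pixel by parabolic
  interpolation of the correlation peak. Angiograms are resampled into
  the NIR-FAF frame (the converse is equivalent to second order because
  profiles are computed in physical millimetres).
* **Thresholds are always computed full-frame**, once per slab image;
  windowed shortcuts would let the global threshold drift with the local
  tissue composition inside the window.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: the cohort recovery study uses 29 patient–control pairs at the
native 1024-px grid (DCC quantification end-to-end); the run-rule
type-I study uses 20 replicate 29-pair cohorts at the profile level
(isolating the statistical rule from the imaging chain); registration
recovery uses 20 random transforms at 512 px and APA-edge recovery 20
randomized ellipse cases at 512 px, sizes at which those two stages are
resolution-faithful. Unit tests use smaller grids where only plumbing is
exercised.

## Known limitations

* The absolute VD/FD values produced by the binarization chain are
  method-defined, not histological densities; only within-method
  contrasts (patient vs control, inside vs outside) are meaningful.
* The run rule controls the family-wise error heuristically; no
  spatially correlated inference (e.g. cluster-based permutation) is
  attempted.
* Controls are anchored by the matched patient's border distance; any
  systematic eccentricity dependence of control VD folds into the
  position-wise differences.
* Deformable (eye-motion) misalignment is out of scope; only similarity
  transforms are corrected.
* The SVC's measured VD runs a few points below its label density in the
  presence of bright large vessels (contrast compression); DCC and CC,
  which carry the quantitative claims, are calibrated as stated above.
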
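# Methods

## Problem and approach

`oactool` quantifies the structural integrity of the photoreceptor
ellipsoid zone (EZ) from OCT raster volumes. The EZ is the hyper-reflective
outer-retinal band attributed to inner-segment mitochondria; loss of its
reflectivity is a surrogate for photoreceptor damage. En face maps of the
EZ slab make the lateral extent of damage visible, but intensity-based
maps are contaminated by projection (shadow) artifacts from overlying
retinal vessels and by speckle.

The package implements two parallel arms and the machinery to compare
them:

* **OAC(+)** — the slab is averaged over per-voxel *optical attenuation
  coefficients* rather than intensity. Under the single-scattering model
  with (near-)complete attenuation within the recorded depth range,

      mu(i) = 1 / (2 Δ) · ln(1 + I(i) / Σ_{j>i} I(j))        [mm⁻¹]

  with Δ the axial pixel pitch in mm and `I` the linear-scale intensity.
  Because a vessel shadow multiplies an A-scan segment and its entire
  tail by the same factor, the ratio `I(i)/Σ_{j>i} I(j)` — and hence `mu`
  — is *exactly* invariant below the shadow onset. This is the quantitative
  core of the artifact-suppression claim and is asserted exactly in tests.
* **OAC(−)** — the conventional intensity slab average, kept as the
  baseline the attenuation arm is evaluated against.

Both arms then share: nonlocal-means (NLM) denoising, normalization to
[0, 1], Phansalkar local adaptive thresholding, and percent white (normal)
/ black (abnormal) area over the full frame.

## Estimator details

* Natural logarithm; `mu` in mm⁻¹ (Δ converted from μm to mm).
* The tail sum is computed by reverse cumulative sum, so the vectorized
  estimator equals the literal double loop to ≤ 1e−10 relative error
  (asserted against that oracle).
* Near the volume bottom the recorded tail underestimates the remaining
  energy and `mu` is biased upward; no tail-extrapolation correction is
  applied because the EZ slab sits far above the bottom.
  `tail_valid_depth` records, per A-scan, the deepest index whose tail
  still exceeds the noise floor (`epsilon_tail`, default 1e−12 × volume
  max — a pure float-noise guard; pass 0 for noiseless synthetic data).
* Columns whose tail is exhausted while `I(i) > 0` get `mu = mu_cap`
  (default 50 mm⁻¹) to keep slab averages finite; all-zero columns get 0.
* Closed-form check: a pure exponential A-scan `I(i) = I₀ e^(−2 mu₀ Δ i)`
  returns exactly `mu₀` up to the truncation term `e^(−2 mu₀ Δ m)` with
  `m` samples left below. The recovery test fixes the per-sample optical
  depth at `2 mu₀ Δ = 0.02` with N = 8000 samples so that this term is
  ≤ 1.1e−7 above the bottom 10 % of the scan for every `mu₀` tested
  (0.5, 2, 8 mm⁻¹); coarser geometries would leak truncation bias into
  the comparison.

## EZ boundary detection and slab

The clinical reference standard is automated segmentation reviewed by a
retina specialist; the algorithm itself is not standardized. We ship a
deterministic two-peak heuristic and accept an externally supplied
(possibly hand-corrected) boundary surface file as the reproducibility
escape hatch.

Per A-scan, after Gaussian smoothing (axial σ = 2 px, lateral σ = 1.5 px;
the lateral component suppresses spatially white speckle, and the axial
kernel is kept narrower than the EZ–RPE gap so the bright RPE tail cannot
swallow a dimmed EZ peak): the global maximum anchors the RPE; the
tallest local maximum 20–80 μm above it is the EZ peak, accepted only if
its prominence (against the saddles separating it from the RPE and from
the region one band-height above) is ≥ 30 % of its height — a
scale-invariant criterion, so uniform vessel shadows cannot move the
boundary; the EZ upper boundary is the upper half-maximum crossing of
that peak. Columns without a qualifying peak are in-filled from the
nearest valid column, and the surface is median-filtered 5×5. If more
than half the columns fail, a `SegmentationFailure` is raised — mirroring
eyes whose outer retina is too disrupted for slab definition to be
meaningful.

The slab spans 15.6 μm below the boundary (a fixed sub-band of the
~24 μm foveal EZ), converted to pixels by round-half-away-from-zero with
a 1 px minimum, and averaged with the arithmetic mean. Slabs running past
the volume bottom are clamped with a warning.

## Denoising, normalization, thresholding

* **NLM**: classic (exhaustive) nonlocal means, patch 7, search window
  21, strength `H = 24` on the 8-bit scale (the image is mapped to
  [0, 255] for filtering and mapped back). The patch distance is
  noise-compensated — the expected noise contribution `2σ²` is subtracted
  before exponential weighting — with `σ` estimated robustly as the 75th
  percentile of the local-std map; a global wavelet estimate collapses
  when a large lesion makes half the image flat, which is exactly when
  denoising matters most.
* **Normalization**: attenuation maps are scaled through a *fixed physical
  display window*, 0–15 mm⁻¹ by default (≈ 1.5× the healthy EZ slab
  attenuation), so healthy tissue lands at a stable position near the top
  of the [0, 1] domain and speckle spikes saturate — the behaviour of a
  standard 8-bit conversion of a physical quantity. Intensity maps have
  no physical scale and use per-image robust percentiles (0.5/99.5) with
  clipping. Per-image plain min–max is available but pathological for
  heavy-tailed speckle: a single spike compresses the whole histogram
  into the dim region where the threshold's `p e^(−q·mean)` term fires.
* **Phansalkar threshold** over a circular window of radius R = 13 px
  (square available behind a flag), reflective border padding,
  population std:

      t = mean · (1 + p e^(−q·mean) + k (std/r − 1)),
      p = 3, q = 10, r = 0.5;  k = 0.475 (OAC+), k = 1.0 (OAC−)

  A pixel is white iff value ≥ t (documented tie-break). In the [0, 1]
  domain the window std can never exceed 0.5 = r, so the k-term is
  non-positive and the threshold is *non-increasing* in k: the white set
  under k = 1.0 contains the white set under k = 0.475. A constant image
  has nothing to normalize and is returned all white with a warning.
* **Area metrics**: percent white = 100 · #white / #pixels over the full
  frame (no foveal masking), percent black its complement; the two sum to
  100 exactly by construction.

## The phantom generator

Purpose: make every pipeline stage verifiable with known ground truth.
Forward model per voxel: `I = R · exp(−2 ∫ mu dz)` with reflectivity `R`
and attenuation `mu` piecewise constant over horizontal layers (default:
inner retina mu = 1.5 mm⁻¹, EZ 10, RPE 20, choroid 6; 512 × 128 × 128
voxels at dz = 2.6 μm over a 1.5 × 1.5 mm field — a desk-scale stand-in
for 512 × 512 clinical frames). Default reflectivities are proportional
to layer mu (backscatter tracks extinction), the single-scattering
consistency condition under which the estimator recovers each layer's mu
— asserted at ±5 % in mid-layer voxels. The choroid is optically thick
enough that the within-volume tail approximates the full remaining
energy at EZ depth.

Emulated artifacts:

* **Vessel shadows** — stripes (or discs) that multiply the signal by a
  transmission factor (default 0.35, ~80 μm calibre) below the vessel
  depth; a pure projection artifact, isolating the mechanism the
  attenuation arm cancels.
* **Speckle** — i.i.d. unit-mean exponential multiplicative noise on the
  linear intensity (fully developed speckle). This is the harshest
  speckle model (100 % contrast, no spatial correlation); real scanners
  are gentler, so tests passing under it are conservative in that one
  respect.
* **EZ defects** — lateral discs scaling the EZ layer's reflectivity and
  mu (default ×0.2); the exact pixel mask and its area fraction are
  returned as ground truth.

What the phantom does *not* model: the foveal dip and Stiles–Crawford
directionality, curved layer geometry, multiple scattering, confocal
falloff, motion artifacts. Passing tests therefore demonstrate the
pipeline's arithmetic and its artifact-suppression mechanism, not
clinical performance.

`generate_cohort` perturbs layer depth (sd = variability × 25 μm, clipped
so layers stay inside the volume), re-draws vessel/defect positions, and
re-seeds speckle per eye; everything is deterministic given the seed.

## Statistics

Per-method mean, sample SD (n − 1), min/max and CV = 100·SD/mean; paired
mean difference with t-based 95 % CI; paired t-test; Wilcoxon signed-rank,
two-sided. The Wilcoxon p is exact for n ≤ 25 via the sign-flip
permutation distribution computed by dynamic programming over doubled
midranks (ties handled exactly; zeros dropped by default, Pratt's method
behind a flag), otherwise a normal approximation with Var(W⁺) = Σ rᵢ²/4,
which absorbs the tie correction. scipy's implementation serves as the
no-ties oracle in tests and full 2ⁿ enumeration as the tied-case oracle.

## Problem sizes and reproducibility

Phantom-based end-to-end checks run at 512 × 128 × 128 (single eyes and
10-eye cohorts); oracle checks run on 16 × 8 × 8 volumes against literal
double-loop implementations. All randomness flows from explicit seeds;
seeded runs are bit-reproducible, and the pipeline writes a provenance
record containing every resolved parameter and input checksums so that a
rerun can be verified byte-for-byte.

## Known limitations

* The boundary detector is a reference heuristic tuned to layered
  phantoms; clinical volumes with drusen, detachments or severe atrophy
  need an external (expert-corrected) boundary surface.
* The attenuation display window (0–15 mm⁻¹) is a device-scale choice;
  systems with different intensity calibration may need a different
  window (it is a single config field).
* No confocal, multiple-scattering or absorption corrections are applied
  to the attenuation estimate.
* Percent-area metrics are computed over the full frame, including the
  physiologically dark fovea in real eyes.
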
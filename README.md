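# oactool

Quantify the structural integrity of the photoreceptor **ellipsoid zone
(EZ)** from OCT raster volumes using depth-resolved **optical attenuation
coefficients (OAC)**, with the conventional intensity-based pipeline as a
built-in baseline.

Intensity-based en face maps of the EZ slab are contaminated by projection
(shadow) artifacts from overlying retinal vessels: the shadow darkens the
EZ and is misread as damage. `oactool` instead averages per-voxel
attenuation coefficients over the slab,

```
mu(i) = 1 / (2 Δ) · ln( 1 + I(i) / Σ_{j>i} I(j) )        [mm⁻¹]
```

where `I` is the linear-scale A-scan intensity and Δ the axial pixel pitch
in mm. A vessel shadow multiplies `I(i)` and its entire tail by the same
factor, so `mu` is exactly unchanged below the shadow — the artifact
cancels by construction. Downstream, both arms share the same chain:
slab en face → nonlocal-means denoising (H = 24) → normalization →
Phansalkar local adaptive threshold (R = 13; k = 0.475 for the OAC arm,
k = 1.0 for the intensity arm; p = 3, q = 10, r = 0.5) → percent
white (normal) / black (abnormal) area.

The package is aimed at retinal-imaging researchers who have raster
volumes (multi-page TIFF or raw binary + JSON sidecar) and want a
reproducible, provenance-tracked EZ abnormality metric — plus a synthetic
layered-retina phantom generator (Beer–Lambert forward model, exponential
speckle, vessel shadows, EZ defects with known area) so every stage can be
validated without clinical data. A paired-statistics module (mean/SD/CV,
paired t, exact Wilcoxon signed-rank, 95 % CI) supports method-comparison
studies. See `docs/methods.md` for the full model description.

## Worked example

Build a synthetic eye with a 30 % EZ lesion plus vessel shadows and
speckle, and run both arms:

```python
from oactool import detect_ez_boundary, generate_phantom, run_arrays
from oactool.phantom import defect_spec

spec = defect_spec(0.30, seed=7)          # speckled, vesselled, 30% EZ lesion
volume, truth = generate_phantom(spec)
boundary = detect_ez_boundary(volume)
oac = run_arrays(volume, "oac_plus", boundary=boundary)
intensity = run_arrays(volume, "oac_minus", boundary=boundary)

print(f"ground-truth lesion area : {truth.defect_fraction:.2f} %")
print(f"OAC(+)  percent black    : {oac.metrics.percent_black:.2f} %")
print(f"OAC(-)  percent black    : {intensity.metrics.percent_black:.2f} %")
```

prints

```
ground-truth lesion area : 29.93 %
OAC(+)  percent black    : 30.20 %
OAC(-)  percent black    : 30.94 %
```

The attenuation arm recovers the known lesion area to ~0.3 percentage
points; the intensity arm additionally counts vessel shadows as abnormal,
which is why it reads slightly higher here and much higher (and more
variably) on heavily vesselled healthy eyes.

The same workflow is available from the shell:

```sh
oactool phantom --out-prefix ph_ --seed 7
oactool oac     --in ph_volume.tif --out mu.tif
oactool enface  --in mu.tif --boundary ph_ez_boundary.tif --out enface.tif
oactool binarize --in enface.tif --out mask.png --metrics metrics.json
oactool compare --metrics-a a.csv --metrics-b b.csv --out result.json
oactool run     --config cfg.json     # one-command pipeline with provenance
```

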
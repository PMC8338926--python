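# retorient

Quantification of retinal microvascular **orientation patterns** from en
face OCTA (optical coherence tomography angiography) images.

Vessel density — the standard OCTA metric — is insensitive to *how* the
vasculature is organized. `retorient` measures, per macular sector, the
local orientation of every vessel pixel and summarizes the resulting
orientation distribution with three metrics (preferred orientation, vessel
anisotropy, vessel area) alongside conventional vessel density. The target
audience is ophthalmic-imaging researchers studying microvascular changes
such as those of diabetic retinopathy, where localized reorganization may
precede a measurable density drop.

## Method

**Per-pixel orientation (multiscale Hessian filter).** At scale σ the image
is convolved with second-derivative-of-Gaussian kernels to form the Hessian
H(t, σ); its eigenvalues (|λ₁| ≤ |λ₂|) describe the local second-order
structure. A tubular (vessel-like) pixel has λ₁ ≈ 0 and λ₂ ≪ 0 (bright
vessel on dark background), and the eigenvector of λ₁ points along the
vessel. Two measures,

    R = |λ₁| / |λ₂|          (line similarity)
    S = √(λ₁² + λ₂²)         (structure-ness)

combine into the vesselness response

    ρ(t, σ) = exp(−R²/2β²) · (1 − exp(−S²/2γ²)),

maximized over a scale grid σ ∈ [σ_min, σ_max]. The winning scale σ₀
estimates the vessel half-width and θ₀ — the eigenvector angle of λ₁ at
σ₀ — the axial vessel orientation in [0°, 180°).

**Vessel mask.** A global Otsu threshold (minimum intra-class variance)
binarizes the image and/or the response ρ; the default mask is their
conjunction.

**Sector ROI.** A 5 mm disk centered on the macula, split into eight
equal-area 45° wedges labeled NS, SN, ST, TS, TI, IT, IN, NI
(N nasal, S superior, T temporal, I inferior; laterality-aware).

**Orientation-pattern metrics.** Masked in-sector orientations form an
angular histogram over [0°, 360°) (each pixel contributes at θ and θ+180°).
Read as a polar curve with radius = counts, the distribution is summarized
by:

* **preferred orientation** — major-axis angle of the moment-equivalent
  ellipse of the filled curve (degrees in [0°, 180°));
* **vessel anisotropy** — major/minor axis-length ratio (≥ 1; 1 = isotropic);
* **vessel area** — shoelace area of the closed curve (pixel²);

plus **vessel density** = vessel pixels / sector pixels. Group comparisons
use Mann–Whitney U (exact for small samples) and Pearson correlation, with
axial-aware circular summaries for orientations.

## Worked example

Simulate a scene of parallel tubes at 30° and analyze it (a right eye with
the macula at the image center; 512 px / 6 mm ≈ 85.33 px/mm):

```sh
retorient simulate scene.yaml --out sim/
retorient analyze scene.png --center 213,213 --px-per-mm 85.333 --eye OD --out run/
```

```
schema_version subject_id eye sector  preferred_orientation_deg  anisotropy  vessel_area_px2  vessel_density
           1.0    subject  OD     NS                  29.520348  120.410948     27249.541672        0.149408
           1.0    subject  OD     SN                  29.538421  134.496467     25585.262742        0.143946
           ...
           1.0    subject  OD     NI                  29.473405  125.064659     24109.155658        0.143161
```

Every sector recovers the true 30° orientation to within 0.6°; the
anisotropy is enormous (all vessels parallel → the rose curve collapses to
a narrow axial lobe) and vessel density is ~0.15 everywhere, as set by the
tube spacing. The same command on a clinical export writes `metrics.csv`
(the eight rows above), per-sector orientation distributions, the binary
vessel mask, an orientation color map (hue encodes θ₀ cyclically over
180°, green = 90°), and a JSON log of all parameters and thresholds.

The Python API mirrors the CLI:

```python
import retorient as rt

image = rt.load_image("scan.png", px_per_mm=512 / 6)
result = rt.analyze_image(image, center=(213, 213), eye="OD")
print(result.metrics)
```

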
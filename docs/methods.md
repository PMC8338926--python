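# Methods

## Model

A vessel cross-section is modeled as a Gaussian intensity profile of
half-width `s` (pixels): `I0(x) = A·exp(−x²/2s²)` across the vessel,
constant along it. For this ideal tube the image Hessian at the ridge is
diagonal with eigenvalues `{(x²−1)·I0, 0}` (s = 1): the smallest-magnitude
eigenvalue is exactly zero and its eigenvector points along the vessel.
This is the analytic anchor of the whole pipeline (it is also what
`scripts/acceptance.py` recomputes).

On real images, derivatives are regularized by Gaussian scale space:
second derivatives at scale σ are computed by separable convolution with
sampled derivative-of-Gaussian kernels (reflection boundary). Per pixel the
2×2 Hessian is eigen-decomposed in closed form; the vesselness response

    ρ(t, σ) = exp(−R²/2β²) · (1 − exp(−S²/2γ²)),
    R = |λ1|/|λ2|,  S = √(λ1² + λ2²),

is maximized over a scale grid, giving the response ρ, the width estimate
σ0 and the orientation θ0 (eigenvector of λ1 at σ0, axial, in [0°, 180°)).
Responses are zeroed where the sign of λ2 contradicts the polarity
(bright-on-dark vessels require λ2 < 0); without this gate thin *dark*
ridges also fire.

### Scale normalization (γ = 3/4)

Second derivatives are multiplied by σ^(2·0.75) before entering R and S.
For a Gaussian ridge of half-width s, the scale-normalized ridge strength
σ^p·s/(s²+σ²)^{3/2} peaks at σ² = p·s²/(3−p): the common p = 2 (σ²
normalization) selects σ = √2·s, whereas p = 1.5 selects σ = s exactly.
We use p = 1.5 — the classical γ-normalization exponent for ridge
detection — so that σ0 is directly interpretable as the profile half-width;
this calibration is verified in the tests (median σ0 equals s on the
default grid for s ∈ {1, 2, 3}). R is a ratio and unaffected; only the
cross-scale comparison of S depends on the choice.

### Resolved γ ("auto")

With γ = "auto", γ is set to half the maximum structure-ness S observed
over the image across the *whole* scale grid. Resolving γ per scale would
renormalize each scale's S distribution so that the strongest pixel ties at
every σ, making the scale argmax degenerate; a single global γ keeps the
max in Eq.-of-ρ meaningful. A floor (γ = 1 when max S ≤ 1e−12) guards
structureless images against floating-point dust.

### Numerical details

* Truncated second-derivative kernels do not sum exactly to zero; the
  residual (kernel sum × smoothed image) is subtracted so constant images
  have an exactly zero Hessian.
* Eigen ties (|λ1| = |λ2| within 1e−9 relative, including the zero
  Hessian) have no meaningful orientation: θ is NaN there and such pixels
  are excluded from orientation histograms.
* A border of width ceil(3·σ_max) px is reported as unreliable
  (reflection padding) in the run log.
* Angles are display-convention: counter-clockwise from image right with y
  up, folded axially into [0°, 180°). Storage is row-major (y down); the
  conversion negates the mixed derivative.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| σ grid | 1.0–4.0 px, step 0.5 | covers capillaries (~1 px at 85.33 px/mm ≈ 11.7 µm/px) through arterioles/venules (~4 px ≈ 45 µm half-width) |
| β | 0.5 | standard blob-suppression weight; R ≪ 1 on lines |
| γ | "auto" | adapts to per-scan contrast (half max Hessian norm) |
| polarity | bright-on-dark | OCTA flow signal is bright |
| Otsu bins | 256 | 8-bit provenance of exported en face images |
| mask mode | "and" | conjunction of intensity and vesselness thresholds; both pure modes are exposed because the ordering of binary and vesselness filtering is ambiguous in practice |
| ROI | 5 mm disk, 8 × 45° wedges | anatomically consistent macular region, avoids scan-edge artifacts |
| histogram bin | 1°, no smoothing | raw counts as polar radius |
| α | 0.05, two-sided | conventional |

The sector labels run counter-clockwise from the nasal axis (NS, SN, ST,
TS, TI, IT, IN, NI); nasal maps to image right for OD and image left for
OS (the anatomical rotation sense mirrors with laterality). Wedges are
half-open so boundary pixels are assigned exactly once, by pixel-center
angle. The macula center is a required user input; image exports carry no
fixation metadata.

## Rose-curve metrics

The orientation histogram (counts per 1° bin over [0°, 360°), axially
duplicated) is read as a closed polygon with vertex k at polar radius
counts[k], angle k·1°. Vessel area is its shoelace area — deterministic and
resolution-independent; tests verify agreement with high-resolution
rasterization within 2 %. Preferred orientation and anisotropy come from
the second central moments of the *filled* polygon (Green's-theorem
formulas; the axial symmetry puts the centroid at the origin): the
moment-equivalent ellipse's major-axis angle and axis ratio
√(λ_max/λ_min). Degenerate cases: an exactly isotropic distribution has no
preferred orientation (NaN, anisotropy 1); a distribution whose mass lies
on a single axis encloses zero area — the axis angle is then taken from
point-mass moments of the vertices and the anisotropy is infinite.

## Statistics

Per-sector metrics across subjects are summarized as mean, SD (ddof = 1),
min, max, n. Preferred orientation is axial (θ ≡ θ+180°), so arithmetic
summaries are misleading near the wrap ({10°, 170°} → arithmetic 90°, axial
0°); both arithmetic and axial circular summaries (angle-doubled mean and
SD) are emitted, labeled. Mann–Whitney U uses full enumeration of group
labelings (midranks for ties) when min(n) ≤ 8 and n_total ≤ 25, otherwise
the tie-corrected normal approximation; Pearson r uses the t-test p-value
with n−2 df. Group modeling beyond two-sample tests (e.g., mixed-effects
across sectors) is out of scope — the long-format CSV export feeds any
stats package.

## Synthetic scenes

The generator exists so that every stage is testable with known ground
truth. Each tube contributes `A·exp(−d²/2s²)` by perpendicular distance d
to a straight or circular-arc centerline; tubes combine by per-pixel
**maximum** (a crossing is never brighter than its brighter vessel), then
i.i.d. Gaussian noise is added and intensities clipped to [0, 1]. Ground
truth — the axial centerline tangent — is defined on the half-max footprint
(d ≤ s·√(2 ln 2)); pixels near two or more centerlines are multi-valued and
excluded from scoring. The default canvas is 427 px (a 5 mm field at
512 px / 6 mm) so sector pixel counts, and hence vessel-area magnitudes
(thousands of pixel²), are realistic. Default background 0.10 and noise
σ 0.05 give vessel-to-noise ratios of ~8–18 for the default amplitude
ranges, a moderate-quality scan.

Scene families:

* `parallel_scene` — evenly spaced straight tubes at one angle; the
  strongly oriented fixture (anisotropy ≫ 1, preferred orientation known).
* `random_scene` — arcs through random points whose tangents follow a
  fixed, uniform-axial, or axial von Mises law; gentle curvature
  (radius 60–200 px) because retinal vessels are not straight lines.
* `capillary_loop_scene` — closed loops of radius 8–12 px at capillary
  caliber (s ∈ [1, 1.3]); the isotropic fixture. A closed loop sweeps every
  tangent direction equally, so the scene is isotropic *by construction at
  the sector level*. This matters: 200 straight or gently curved tubes give
  a 45° sector only a few dozen effectively independent orientations, and
  the sector-level orientation content then fluctuates far from isotropy
  even though the tube-angle law is uniform. The loop fixture also keeps
  the amplitude range narrow (0.6–0.9) so the global Otsu threshold does
  not drop dim tubes wholesale, which would re-weight orientations
  coherently.

What the generator does **not** emulate: OCT speckle and projection
artifacts, the layered (superficial/deep) organization of the real plexus,
the foveal avascular zone, vessel taper and branching topology, and
flow-dependent signal variation. Passing tests therefore demonstrate the
correctness and calibration of the *measurement chain*, not clinical
performance on real scans.

Orientation recovery is scored as the axial distance
min(|a−b|, 180−|a−b|) on the footprint, eroded by up to 2 px to avoid
edge pixels (the erosion backs off rather than empty the footprint of
s = 1 tubes, whose half-max band is only ~3 px wide), excluding crossings
and optionally an image-border margin. On noiseless straight tubes with
s ∈ [1, 3] the pipeline's mean axial error is well under 1°; with noise at
vessel-to-noise ratio ≥ 5 it stays under 5°.

## Problem sizes used in the test suite

Single-tube recovery runs on 128 px canvases (18 scenes: 6 angles × 3
widths); sector-level fixtures use the full 427 px canvas with 200 tubes;
the vessel-area/vessel-density association uses 20 scenes with loads of
20–200 loops. These sizes keep the full suite at about a minute while
leaving every assertion at the tolerances stated above.

## Known limitations

* Orientation is undefined at isotropic points and crossings; such pixels
  are excluded rather than interpolated.
* The vesselness response penalizes strong curvature (|λ1| grows), so very
  tight loops are under-weighted relative to straight segments in the
  masked orientation mass.
* Vessel area depends on the raw pixel-count radius of the rose curve and
  therefore on image resolution and ROI size; compare only across images
  with identical geometry.
* Full-thickness (non-segmented) en face analysis only; no per-layer
  quantification, no registration between visits, no tortuosity metrics.
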
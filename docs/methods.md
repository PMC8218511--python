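# Methods

## The model

A debarked willow stem is treated as a stack of segments bounded by the
heights at which sections and sample cylinders were cut (40 cm spacing in
the shipped datasets). Within a segment, four quantities are derived from
the boundary measurements:

* **Volume** `V = L · (A_top + A_bottom)/2`, the mean-of-end-areas rule with
  `A = π d²/4` on the debarked diameters. A conic-frustum option exists but
  the mean-of-areas rule is the default because it is what the published
  segment volumes follow. The basal segment (lowest boundary down to the
  cut at ground level) has no lower diameter and is modelled as a cylinder
  at the lowest measured diameter.
* **Dry weight** `W = V · ρ / 1000` with ρ in kg/m³ (≡ mg/cm³).
* **Glucose mass** `G = W · c / 1000` with c the cellulase-released
  d-glucose in mg/g dry weight.
* **Tension volume** `V_TW = V · %TW / 100` from the stained-section area
  percentage.

**Boundary rule.** ρ, c and %TW are taken at the segment's *upper* boundary
(`boundary_rule="top"`), with a mean-of-boundaries option. The top rule is
the default because the published per-segment weights, glucose masses and
tension volumes back-compute exactly under it (e.g. 45.9 cm³ × 0.4505 →
20.7 g; 20.7 g × 155.7 mg/g → 3.22 g). Since glucose concentration rises
and density falls with height, the top rule slightly overstates glucose and
understates weight per segment relative to the mean rule; on the shipped
data the two differ by a few percent, and the mean rule remains available
for sensitivity checks.

Stem summaries over a height range are plain sums:
`%TW_vol = 100·ΣV_TW/ΣV` (over segments that have a tension volume — the
basal segment never does), `glucose/cellulose = 100·ΣG/(f_cell·ΣW)`, and
`mean glucose per m³` is the mean over grid heights of `c·ρ/1000`.

**Cellulose fraction.** `f_cell` defaults to 0.45, the midpoint of wet
chemical analyses of willow stem cellulose (41.6–55.9%); it is a parameter
everywhere, never a constant baked into an output.

## Image quantification

The %TW of a section is `100 · TW px / section px`. The chain:

1. *Masking*: pixels within an RGB distance `threshold` (default 40) of the
   background reference are background; the largest connected component of
   the rest is the section; smaller specks revert to background. Interior
   holes (pith, cracks — regions showing the scanner backing) are **filled
   as section** by default; the alternative labels them lumen so they can be
   excluded. The published method does not say which convention was used;
   the default (include) is an assumption and both are implemented.
2. *Classification*: each section pixel goes to the nearest of the TW and
   other-tissue reference colors in CIELAB. Stain uptake scales with
   section thickness, so hue/chroma rather than raw RGB intensity carry the
   class signal; CIELAB separates lightness from both.
3. *Cleanup*: TW components smaller than `min_tw_component_frac` of the
   section area (default 0.01%) are dropped — only contiguous bands are
   counted, mirroring the fact that diffusely scattered single G-fibres
   cannot be quantified this way — and sub-pixel gaps inside bands are
   filled.

Bark is assumed cropped/debarked upstream; no bark detector is provided.
The fraction is invariant to rotation and to resolution.

## Synthetic data

`gen_section_image` draws concentric growth rings around a pith centre and
places TW as non-overlapping annular-sector bands (multiple bands per ring,
typically on opposing sides — the multilateral pattern of real stems). Each
pixel gets its class reference color plus i.i.d. Gaussian channel noise
(default sd 8 on 0–255), clipped. The default palette keeps all pairwise
class distances above 4× the noise sd, so classification is well-posed; at
the defaults ≥ 99.9% of pixels stay nearest their own reference. The truth
map and the true TW fraction are returned alongside the image, with the
section denominator excluding the lumen unless `lumen_in_section` is set
(the default geometry has no pith hole, so the conventions coincide).

What the generator does **not** emulate: vessel/fibre microanatomy,
stain-uptake gradients with section thickness, scanner vignetting, torn or
folded sections, bark remnants. Passing the 1-percentage-point end-to-end
recovery check therefore demonstrates the correctness of the measurement
chain, not robustness to real histological artifacts — on real scans the
palette references and threshold must be calibrated per staining batch.

`gen_stem_profile` interpolates linearly between basal and apical anchors
and adds truncated Gaussian noise per variable. The default anchors are the
measured Tora extremes (diameter 2.83 → 1.05 cm, density 522 → 450 kg/m³,
glucose 35 → 156 mg/g, TW 18 → 45%) — i.e. the taper, the density decrease
with height and the glucose/%TW increase with height of a real 2-year stem.
Default noise levels (0.03 cm, 5 kg/m³, 4 mg/g, 1 pp) are of the order of
the replicate scatter such measurements show.

`gen_gopod_readings` inverts the GOPOD formula: it picks a dilution ≥ 1
that keeps the absorbance ratio within the single-point calibration range
and emits the absorbance that decodes to the requested concentration.
Noise is added to the sample absorbance only, so the decoded concentration
is exactly linear in the noise and the round trip is unbiased; at zero
noise it is exact to machine precision.

## Assay conventions

* GOPOD: single-point-calibration kit arithmetic; the standard
  concentration, hydrolysate volume (default 10 mL) and dilution are
  inputs, not constants, because kit dilutions vary between runs. Negative
  blank-corrected absorbances clip to zero with a warning.
* Density replicates are averaged arithmetically with the SD reported; no
  outlier rejection.
* Time courses: ordinary least squares of glucose on day;
  R² = 1 − SS_res/SS_tot; an all-equal series (SS_tot = 0) is a perfect
  flat fit and returns R² = 1 with a `degenerate` flag rather than 0/0.

## Numerical choices and known limitations

* All arithmetic is double precision; report CSVs round to one decimal.
  The published segment tables were evidently computed with π ≈ 3.14 —
  recomputing with true π shifts the largest volumes by up to ~0.16 cm³
  (e.g. 225.55 vs 225.4), which is why the table-reproduction tests allow
  ±0.2 on volumes and ±0.15 on weights while everything else reproduces to
  ±0.1.
* The shipped Björn table's per-segment weights duplicate the Tora column
  in the original source; the pipeline recomputes Björn weights from Björn
  volumes and densities, which is the convention consistent with the
  published Björn glucose masses. The published Björn "80–320 cm" summary
  percentages actually cover 40–320 cm (they reproduce only when the 40–80
  segment is included); this package reports ranges as labelled and does
  not reproduce those two footers.
* Zero-variance profile columns make Pearson correlations undefined; the
  matrix carries NaN entries plus a `degenerate` attribute naming the
  columns, never a silent 0.
* No extrapolation above the highest measured section (primary-shoot
  growth), no bark modelling, no between-variety inference; enzyme
  kinetics are reduced to the measured glucose output.

## Problem sizes

The test suite and the acceptance script run the segmentation chain on
360×360 px sections (20 sections for the recovery check), 1000 Monte-Carlo
replicates for the GOPOD bias check, and the full 9–10-height published
profiles for the stem accounting; together they complete in well under a
minute on one CPU.
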
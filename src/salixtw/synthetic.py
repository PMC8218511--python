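"""Synthetic stained sections and stem datasets with known ground truth.

No stained-section scans or measurement tables are deposited with the source
study, so every downstream stage is exercised against simulations whose
truth is known by construction:

* ``gen_section_image`` draws a stem disc as concentric growth rings with
  tension wood as annular-sector bands (TW appears in real sections as
  discrete bands along rings, often on opposing sides of the stem), colors
  each pixel with its class reference color plus i.i.d. Gaussian channel
  noise, and returns the exact label map and true TW area percentage.
* ``gen_stem_profile`` draws a height profile with the qualitative structure
  of real 2-year stems: diameter tapering with height, density decreasing,
  glucose concentration and %TW increasing.
* ``gen_gopod_readings`` inverts the GOPOD kit arithmetic to emit
  absorbances that decode to a prescribed glucose concentration.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay import GopodSample
from .imaging import (
    LABEL_BACKGROUND,
    LABEL_LUMEN,
    LABEL_SECTION,
    LABEL_TW,
    SectionImage,
    StainClassMap,
)
from .stem import HeightProfile

__all__ = [
    "DEFAULT_PALETTE",
    "TWBand",
    "SynthSectionSpec",
    "SynthStemSpec",
    "gen_section_image",
    "gen_stem_profile",
    "gen_gopod_readings",
    "spec_for_target_tw",
]

# Reference colors (8-bit RGB) emulating a chlorazol black E + safranin
# double stain: lignified tissue safranin-red, the G-layer bands near-black
# purple, scanner background near-white, lumen/pith pale.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (245, 245, 245),
    "normal_wood": (200, 90, 90),
    "tw": (70, 45, 95),
    "lumen": (235, 215, 200),
}

_CLASS_LABEL = {
    "background": LABEL_BACKGROUND,
    "normal_wood": LABEL_SECTION,
    "tw": LABEL_TW,
    "lumen": LABEL_LUMEN,
}


@dataclass(frozen=True)
class TWBand:
    """One tension-wood band: an annular sector of a growth ring.

    ``radial_fraction`` is the outer share of the ring's radial width that
    the band occupies (1.0 = the full ring width).
    """

    ring_index: int
    angular_start_deg: float
    angular_extent_deg: float
    radial_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ring_index < 0:
            raise ValueError("ring_index must be non-negative")
        if not 0 < self.angular_extent_deg <= 360:
            raise ValueError("angular extent must lie in (0, 360]")
        if not 0 < self.radial_fraction <= 1:
            raise ValueError("radial_fraction must lie in (0, 1]")


def _arc_overlap(a: TWBand, b: TWBand) -> bool:
    sa, ea = a.angular_start_deg % 360, a.angular_extent_deg
    sb, eb = b.angular_start_deg % 360, b.angular_extent_deg
    return ((sb - sa) % 360) < ea or ((sa - sb) % 360) < eb


@dataclass
class SynthSectionSpec:
    """Ground-truth geometry and rendering parameters for one section."""

    image_size_px: tuple[int, int] = (360, 360)
    pixel_size_um: float = 10.58  # 2400 dpi
    pith_center_px: tuple[float, float] | None = None  # (row, col); None=centre
    ring_radii_px: tuple[float, ...] = (80.0, 150.0)
    tw_bands: tuple[TWBand, ...] = ()
    lumen_radius_px: float = 0.0  # pith hole; 0 = solid disc
    color_palette: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    noise_sd: float = 8.0
    lumen_in_section: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        radii = tuple(float(r) for r in self.ring_radii_px)
        if not radii or any(r <= 0 for r in radii):
            raise ValueError("ring radii must be positive")
        if any(b >= a for a, b in zip(radii[1:], radii[:-1])):
            raise ValueError("ring radii must be strictly increasing")
        self.ring_radii_px = radii
        if not 0 <= self.lumen_radius_px < radii[0]:
            raise ValueError("lumen radius must lie in [0, first ring radius)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pith_center_px is None:
            self.pith_center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
        cy, cx = self.pith_center_px
        r_out = radii[-1]
        if cy - r_out < 0 or cx - r_out < 0 or cy + r_out > h - 1 or cx + r_out > w - 1:
            raise ValueError("section does not fit inside the image frame")
        self.tw_bands = tuple(self.tw_bands)
        for band in self.tw_bands:
            if band.ring_index >= len(radii):
                raise ValueError(
                    f"band ring_index {band.ring_index} exceeds ring count"
                )
        for i, a in enumerate(self.tw_bands):
            for b in self.tw_bands[i + 1 :]:
                if a.ring_index == b.ring_index and _arc_overlap(a, b):
                    raise ValueError(
                        "TW bands overlap within a ring; ground truth ambiguous"
                    )
        required = {"background", "normal_wood", "tw", "lumen"}
        if set(self.color_palette) < required:
            raise ValueError(f"palette must define {sorted(required)}")
        names = sorted(required)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ca = np.asarray(self.color_palette[a], dtype=float)
                cb = np.asarray(self.color_palette[b], dtype=float)
                if np.linalg.norm(ca - cb) <= 4.0 * self.noise_sd:
                    raise ValueError(
                        f"palette colors {a!r} and {b!r} closer than "
                        f"4 x noise_sd: classification ill-posed"
                    )


def gen_section_image(
    spec: SynthSectionSpec,
) -> tuple[SectionImage, StainClassMap, float]:
    """Render one synthetic section; return image, truth map, true %TW.

    The true fraction is 100 × TW pixels / section pixels, where the section
    comprises all non-background, non-lumen pixels (lumen is counted into
    the denominator iff ``spec.lumen_in_section``).
    """
    h, w = spec.image_size_px
    cy, cx = spec.pith_center_px
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0

    radii = np.asarray(spec.ring_radii_px)
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    disc = r <= radii[-1]
    labels[disc] = LABEL_SECTION
    if spec.lumen_radius_px > 0:
        labels[r < spec.lumen_radius_px] = LABEL_LUMEN

    inner_edges = np.concatenate(([spec.lumen_radius_px], radii[:-1]))
    for band in spec.tw_bands:
        r_in = inner_edges[band.ring_index]
        r_out = radii[band.ring_index]
        band_r_in = r_out - band.radial_fraction * (r_out - r_in)
        in_arc = ((theta - band.angular_start_deg) % 360.0) < band.angular_extent_deg
        sel = (r >= band_r_in) & (r <= r_out) & in_arc & (labels == LABEL_SECTION)
        labels[sel] = LABEL_TW

    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    for name, lab in _CLASS_LABEL.items():
        img[labels == lab] = spec.color_palette[name]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    tw_px = int(np.count_nonzero(labels == LABEL_TW))
    section_px = tw_px + int(np.count_nonzero(labels == LABEL_SECTION))
    if spec.lumen_in_section:
        section_px += int(np.count_nonzero(labels == LABEL_LUMEN))
    true_pct = 100.0 * tw_px / section_px if section_px else math.nan

    image = SectionImage(
        pixels=img,
        pixel_size_um=spec.pixel_size_um,
        source_id=f"synth-seed{spec.seed}",
    )
    return image, StainClassMap(labels), true_pct


def spec_for_target_tw(
    target_tw_percent: float,
    seed: int = 0,
    image_size_px: tuple[int, int] = (360, 360),
    noise_sd: float = 8.0,
) -> SynthSectionSpec:
    """Section spec whose true TW fraction is close to ``target_tw_percent``.

    Tension wood is laid down as two bands on opposing sides of the outer
    growth ring (the multilateral pattern seen in real stems), with the
    total arc chosen analytically so the band area over the disc area hits
    the target; the exact truth still comes from pixel counting.
    """
    if not 0 <= target_tw_percent <= 60:
        raise ValueError("target TW percent must lie in [0, 60]")
    h, w = image_size_px
    r_outer = 0.42 * min(h, w)
    r_inner = 0.55 * r_outer
    annulus_frac = (r_outer**2 - r_inner**2) / r_outer**2
    total_extent = 360.0 * (target_tw_percent / 100.0) / annulus_frac
    rng = np.random.default_rng(seed)
    start = float(rng.uniform(0.0, 360.0))
    bands: tuple[TWBand, ...]
    if total_extent <= 0:
        bands = ()
    else:
        half = total_extent / 2.0
        bands = (
            TWBand(1, start, half),
            TWBand(1, (start + 180.0) % 360.0, half),
        )
    return SynthSectionSpec(
        image_size_px=image_size_px,
        ring_radii_px=(r_inner, r_outer),
        tw_bands=bands,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class SynthStemSpec:
    """Basal/apical anchors for a linearly interpolated stem profile.

    Defaults emulate a tall 2-year commercial variety: diameter tapering
    2.8 → 1.1 cm over 40–400 cm, density falling ~520 → 450 kg/m³, glucose
    release rising ~35 → 156 mg/g, and %TW rising ~18 → 45.
    """

    height_step_cm: float = 40.0
    max_height_cm: float = 400.0
    basal_diameter_cm: float = 2.83
    apical_diameter_cm: float = 1.05
    density_basal: float = 522.4
    density_apical: float = 450.5
    glucose_basal: float = 35.0
    glucose_apical: float = 155.7
    tw_basal: float = 0.18
    tw_apical: float = 0.45
    noise_diameter_cm: float = 0.03
    noise_density: float = 5.0
    noise_glucose: float = 4.0
    noise_tw: float = 0.01
    seed: int = 0
    variety: str = "synthetic"

    def __post_init__(self) -> None:
        if self.height_step_cm <= 0:
            raise ValueError("height step must be positive")
        if self.max_height_cm < 2 * self.height_step_cm:
            raise ValueError("need at least two grid heights")
        if self.apical_diameter_cm > self.basal_diameter_cm:
            raise ValueError("apical diameter cannot exceed basal diameter")
        for name in (
            "basal_diameter_cm",
            "apical_diameter_cm",
            "density_basal",
            "density_apical",
            "glucose_basal",
            "glucose_apical",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.density_apical > self.density_basal:
            raise ValueError("density must not increase with height")
        if self.glucose_apical < self.glucose_basal:
            raise ValueError("glucose must not decrease with height")
        for name in ("tw_basal", "tw_apical"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tw_apical < self.tw_basal:
            raise ValueError("tw fraction must not decrease with height")
        for name in ("noise_diameter_cm", "noise_density", "noise_glucose", "noise_tw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gen_stem_profile(spec: SynthStemSpec) -> HeightProfile:
    """Linear basal→apical interpolation on the height grid plus noise.

    Gaussian noise is added independently per variable and truncated so the
    profile invariants hold (positive diameter/density/glucose, %TW within
    [0, 100]).
    """
    heights = np.arange(
        spec.height_step_cm,
        spec.max_height_cm + spec.height_step_cm / 2.0,
        spec.height_step_cm,
    )
    t = (heights - heights[0]) / (heights[-1] - heights[0])
    rng = np.random.default_rng(spec.seed)

    def interp(basal: float, apical: float, sd: float, lo: float, hi: float):
        base = basal + t * (apical - basal)
        if sd > 0:
            base = base + rng.normal(0.0, sd, size=base.shape)
        return np.clip(base, lo, hi)

    diameter = interp(spec.basal_diameter_cm, spec.apical_diameter_cm,
                      spec.noise_diameter_cm, 1e-6, np.inf)
    density = interp(spec.density_basal, spec.density_apical,
                     spec.noise_density, 1e-6, np.inf)
    glucose = interp(spec.glucose_basal, spec.glucose_apical,
                     spec.noise_glucose, 0.0, np.inf)
    tw = 100.0 * interp(spec.tw_basal, spec.tw_apical, spec.noise_tw, 0.0, 1.0)

    return HeightProfile(
        heights_cm=heights,
        diameter_cm=diameter,
        density_kg_m3=density,
        glucose_mg_g=glucose,
        tw_percent=tw,
        variety=spec.variety,
    )


def gen_gopod_readings(
    true_conc_mg_per_g: float,
    dry_wt_g: float,
    hydrolysate_ml: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    abs_blank: float = 0.05,
    abs_standard: float = 0.55,
    standard_conc_mg_ml: float = 1.0,
    sample_id: str = "synth",
) -> GopodSample:
    """Absorbances that decode (via the GOPOD formula) to ``true_conc``.

    The dilution factor is chosen automatically (≥ 1) so the blank-corrected
    absorbance ratio stays within the single-point calibration range.
    Gaussian noise of ``noise_sd`` absorbance units is added to the sample
    reading only, so the decoded concentration is unbiased around the truth.
    Zero noise gives an exact round trip.
    """
    if true_conc_mg_per_g <= 0 or dry_wt_g <= 0 or hydrolysate_ml <= 0:
        raise ValueError("concentration, dry weight and volume must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conc_mg_ml = true_conc_mg_per_g * dry_wt_g / hydrolysate_ml
    dilution = max(1.0, conc_mg_ml / standard_conc_mg_ml)
    ratio = conc_mg_ml / (standard_conc_mg_ml * dilution)
    abs_sample = abs_blank + ratio * (abs_standard - abs_blank)
    if noise_sd > 0:
        abs_sample += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return GopodSample(
        abs_sample=abs_sample,
        abs_blank=abs_blank,
        abs_standard=abs_standard,
        standard_conc_mg_ml=standard_conc_mg_ml,
        dry_wt_g=dry_wt_g,
        hydrolysate_volume_ml=hydrolysate_ml,
        dilution_factor=dilution,
        sample_id=sample_id,
    )
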
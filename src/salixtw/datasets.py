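"""Published stem measurement tables for the varieties Tora and Björn.

Two-year-old short-rotation *Salix* stems measured every 40 cm above ground:
debarked diameter (cm), basic (oven-dry) density (kg/m³), and d-glucose
released by a 3-day Cellic CTec2 hydrolysis of stem cross sections (mg/g dry
weight).  Tension-wood volumes per 40-cm segment (cm³, from stained-section
image analysis) are available for Tora 40–400 cm and Björn 80–320 cm.

These tables are the inputs to the whole-stem accounting; they are kept here
so the full stem report is reproducible without any external files.

Notes on the published values
-----------------------------
* The published Björn per-segment stem weights duplicate the Tora weights;
  they are retained verbatim in ``BJORN_PRINTED_WEIGHTS_G`` for reference
  but the pipeline recomputes Björn weights from Björn volumes and
  densities, which is the convention consistent with the published Björn
  glucose masses.
* No ground-level (0 cm) diameter is used: the basal 40–0 cm segment is a
  cylinder at the 40-cm diameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stem import HeightProfile

__all__ = [
    "tora_profile",
    "bjorn_profile",
    "tora_tension_volumes",
    "bjorn_tension_volumes",
    "tw_enriched_densities",
    "FIELD_SAMPLE_GLUCOSE_MG_G",
]

# 8-year-old field-grown S. viminalis control sample (single stem point).
FIELD_SAMPLE_GLUCOSE_MG_G = 116.0

# height_cm, diameter_cm, density_kg_m3, glucose_mg_g
_TORA = [
    (40, 2.83, 522.4, 35.0),
    (80, 2.52, 491.7, 49.7),
    (120, 2.35, 473.0, 60.2),
    (160, 2.20, 465.7, 64.0),
    (200, 2.04, 462.3, 67.9),
    (240, 1.91, 459.3, 81.9),
    (280, 1.69, 452.6, 95.8),
    (320, 1.53, 455.4, 82.2),
    (360, 1.35, 454.4, 124.4),
    (400, 1.05, 450.5, 155.7),
]

_BJORN = [
    (40, 2.73, 520.8, 61.8),
    (80, 2.53, 490.9, 89.2),
    (120, 2.35, 473.6, 87.8),
    (160, 2.20, 461.3, 85.9),
    (200, 2.06, 455.8, 89.0),
    (240, 1.91, 464.6, 88.9),
    (280, 1.80, 469.9, 111.2),
    (320, 1.62, 467.0, 112.8),
    (360, 1.36, 451.3, 117.9),
]

# Tension-wood volume (cm³) per segment, keyed (bottom_cm, top_cm); derived
# in the source study from %TW of the section scanned at the segment's upper
# boundary.  Not measured for the basal segments, for Björn 40-80 none is
# published either below 80 cm or above 320 cm (only the first annual ring
# is present at 360 cm).
TORA_TENSION_VOLUMES_CM3 = {
    (360, 400): 20.8,
    (320, 360): 25.5,
    (280, 320): 30.8,
    (240, 280): 34.5,
    (200, 240): 40.6,
    (160, 200): 44.2,
    (120, 160): 46.2,
    (80, 120): 44.7,
    (40, 80): 41.5,
}

BJORN_TENSION_VOLUMES_CM3 = {
    (280, 320): 35.1,
    (240, 280): 40.7,
    (200, 240): 40.8,
    (160, 200): 46.6,
    (120, 160): 52.9,
    (80, 120): 52.6,
    (40, 80): 57.6,
}

# Published Björn per-segment weights (g), basal segment last; identical to
# the Tora column in the source tables — see module docstring.
BJORN_PRINTED_WEIGHTS_G = [29.7, 37.2, 46.2, 56.3, 65.3, 75.8, 88.2, 110.8, 131.4]

# Densities (kg/m³) of tension-wood-enriched samples cut from the 1st and
# 2nd annual growth rings, and of the entire sample at the same heights.
_TW_ENRICHED = [
    # variety, height_cm, entire_sample, tension_ring1, tension_ring2
    ("Tora", 360, 417.2, 488.0, 454.4),
    ("Tora", 200, 412.1, 489.3, 462.3),
    ("Tora", 80, 443.1, 492.6, 491.7),
    ("Björn", 360, 439.6, 508.3, 451.3),
    ("Björn", 200, 457.3, 507.5, 455.8),
    ("Björn", 80, 455.8, 512.9, 490.9),
]


def _profile(rows, variety: str) -> HeightProfile:
    arr = np.array([r[1:] for r in rows], dtype=float)
    return HeightProfile(
        heights_cm=np.array([r[0] for r in rows], dtype=float),
        diameter_cm=arr[:, 0],
        density_kg_m3=arr[:, 1],
        glucose_mg_g=arr[:, 2],
        variety=variety,
    )


def tora_profile() -> HeightProfile:
    """Tora: 40–400 cm every 40 cm (10 heights)."""
    return _profile(_TORA, "Tora")


def bjorn_profile() -> HeightProfile:
    """Björn: 40–360 cm every 40 cm (9 heights)."""
    return _profile(_BJORN, "Björn")


def tora_tension_volumes() -> dict[tuple[float, float], float]:
    return dict(TORA_TENSION_VOLUMES_CM3)


def bjorn_tension_volumes() -> dict[tuple[float, float], float]:
    return dict(BJORN_TENSION_VOLUMES_CM3)


def tw_enriched_densities() -> pd.DataFrame:
    """Long-format table of TW-enriched densities by variety, height, tissue."""
    rows = []
    for variety, h, entire, ring1, ring2 in _TW_ENRICHED:
        rows.append((variety, h, "entire_sample", entire))
        rows.append((variety, h, "tension_ring1", ring1))
        rows.append((variety, h, "tension_ring2", ring2))
    return pd.DataFrame(
        rows, columns=["variety", "height_cm", "tissue", "density_kg_m3"]
    )
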
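"""Wet-lab measurement reduction: density, GOPOD glucose, time courses.

* Basic density from oven-dry mass and water-displacement volume, averaged
  over replicates.
* Free d-glucose per gram dry weight from glucose oxidase/peroxidase
  (GOPOD) absorbances against a single-point glucose standard.
* Ordinary least-squares fit of the day-by-day glucose release during
  cellulase hydrolysis, summarised by slope, intercept and R².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityMeasurement",
    "GopodSample",
    "TimeCourse",
    "density",
    "mean_by_group",
    "gopod_glucose",
    "fit_timecourse",
]


@dataclass
class DensityMeasurement:
    """One replicate: oven-dry mass (g) and displaced volume (cm³)."""

    dry_mass_g: float
    displaced_volume_cm3: float
    replicate_id: str = ""
    sample_id: str = ""
    height_cm: float = math.nan

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0:
            raise ValueError("dry mass must be positive")
        if self.displaced_volume_cm3 <= 0:
            raise ValueError("displaced volume must be positive")

    @property
    def density_kg_m3(self) -> float:
        # 1 g/cm³ = 1000 kg/m³
        return 1000.0 * self.dry_mass_g / self.displaced_volume_cm3


@dataclass
class GopodSample:
    """Raw GOPOD absorbances for one hydrolysate aliquot.

    The kit is calibrated against a single glucose standard:
    ``conc = (A_sample − A_blank)/(A_standard − A_blank) × standard_conc ×
    dilution``; multiplying by the hydrolysate volume and dividing by the
    section dry weight gives mg d-glucose per g dry wood.
    """

    abs_sample: float
    abs_blank: float
    abs_standard: float
    standard_conc_mg_ml: float
    dry_wt_g: float
    hydrolysate_volume_ml: float = 10.0
    dilution_factor: float = 1.0
    sample_id: str = ""
    height_cm: float = math.nan
    day: float = math.nan

    def __post_init__(self) -> None:
        if self.abs_standard <= self.abs_blank:
            raise ValueError("invalid calibration: abs_standard <= abs_blank")
        if self.standard_conc_mg_ml <= 0:
            raise ValueError("standard concentration must be positive")
        if self.dry_wt_g <= 0:
            raise ValueError("dry weight must be positive")
        if self.hydrolysate_volume_ml <= 0:
            raise ValueError("hydrolysate volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class TimeCourse:
    """OLS summary of glucose release (mg/g dry wt) versus day."""

    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def density(
    measurements: Sequence[DensityMeasurement],
) -> pd.DataFrame:
    """Replicate-mean basic density per sample, with replicate SD.

    Returns one row per ``sample_id`` with columns ``density_kg_m3``
    (arithmetic mean over replicates), ``sd_kg_m3`` (ddof=1; NaN for a
    single replicate) and ``n_replicates``.
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    rows = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "height_cm": [m.height_cm for m in measurements],
            "density_kg_m3": [m.density_kg_m3 for m in measurements],
        }
    )
    out = (
        rows.groupby("sample_id", sort=False)
        .agg(
            height_cm=("height_cm", "first"),
            density_kg_m3=("density_kg_m3", "mean"),
            sd_kg_m3=("density_kg_m3", lambda x: x.std(ddof=1)),
            n_replicates=("density_kg_m3", "size"),
        )
        .reset_index()
    )
    return out


def mean_by_group(values: Iterable[tuple[str, float]]) -> dict[str, float]:
    """Arithmetic mean per group; report at one decimal downstream."""
    acc: dict[str, list[float]] = {}
    for group, v in values:
        acc.setdefault(group, []).append(float(v))
    if not acc:
        raise ValueError("no values given")
    for g, vals in acc.items():
        if not vals:
            raise ValueError(f"group {g!r} is empty")
    return {g: float(np.mean(vals)) for g, vals in acc.items()}


def gopod_glucose(s: GopodSample) -> float:
    """Free d-glucose in mg per g dry weight from one GOPOD reading.

    Linear in the blank-corrected absorbance and inversely proportional to
    the section dry weight.  A sample absorbance below the blank clips to
    zero with a warning (small negative readings are instrument noise).
    """
    corrected = s.abs_sample - s.abs_blank
    if corrected < 0:
        warnings.warn(
            f"blank-corrected absorbance negative ({corrected:.4f}) for "
            f"sample {s.sample_id!r}; clipping to 0",
            stacklevel=2,
        )
        corrected = 0.0
    conc_mg_ml = (
        corrected
        / (s.abs_standard - s.abs_blank)
        * s.standard_conc_mg_ml
        * s.dilution_factor
    )
    return conc_mg_ml * s.hydrolysate_volume_ml / s.dry_wt_g


def fit_timecourse(points: Sequence[tuple[float, float]]) -> TimeCourse:
    """OLS line through (day, glucose mg/g) points with R².

    Requires at least two distinct day values.  If all glucose values are
    identical (SS_tot = 0) the fit is flat and exact; R² is defined as 1
    with ``degenerate=True``.
    """
    pts = [(float(d), float(g)) for d, g in points]
    days = np.array([p[0] for p in pts])
    glc = np.array([p[1] for p in pts])
    if np.unique(days).size < 2:
        raise ValueError("at least two distinct day values are required")
    if np.allclose(glc, glc[0]):
        return TimeCourse(
            points=pts,
            slope=0.0,
            intercept=float(glc[0]),
            r_squared=1.0,
            degenerate=True,
        )
    res = stats.linregress(days, glc)
    return TimeCourse(
        points=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
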
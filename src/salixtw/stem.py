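"""Whole-stem integration of per-height measurements.

A short-rotation willow stem is modelled as a stack of segments (40 cm by
default) whose end diameters, basic densities, enzymatically released
d-glucose concentrations and tension-wood area fractions are known at the
segment boundaries.  Each segment is reduced to a volume (mean-of-end-areas
rule), an oven-dry weight, a tension-wood volume and a d-glucose mass; stem
summaries aggregate these into the quantities a variety comparison needs:
percentage tension-wood volume, total accessible d-glucose, mean d-glucose
per cubic metre, and accessible d-glucose as a share of total stem cellulose
(literature cellulose fraction, default 0.45).

Conventions
-----------
* Segment weight and glucose use the density / concentration measured at the
  segment's *upper* boundary height (``boundary_rule="top"``); the mean of
  the two boundaries is available as an option.
* The basal segment (lowest boundary down to ground) is a cylinder at the
  lowest measured diameter when no ground-level diameter exists, and carries
  no tension-wood volume.
* All arithmetic is done at full precision; rounding to one decimal happens
  only in report output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeightProfile",
    "SegmentRecord",
    "StemSummary",
    "segment_volume",
    "segment_weight",
    "segment_glucose",
    "tension_volume",
    "build_segments",
    "attach_tension_volumes",
    "segments_to_frame",
    "stem_summary",
    "point_glucose_per_cellulose",
    "correlation_matrix",
]

BoundaryRule = Literal["top", "mean"]
VolumeMethod = Literal["mean_area", "frustum"]

PROFILE_COLUMNS = (
    "height_cm",
    "diameter_cm",
    "density_kg_m3",
    "glucose_mg_g",
    "tw_percent",
)


@dataclass
class HeightProfile:
    """Per-height stem measurements on a strictly increasing height grid.

    ``tw_percent`` is optional (NaN where the tension-wood area fraction was
    not measured, e.g. where only the first annual ring is present).
    """

    heights_cm: np.ndarray
    diameter_cm: np.ndarray
    density_kg_m3: np.ndarray
    glucose_mg_g: np.ndarray
    tw_percent: np.ndarray | None = None
    variety: str = ""

    def __post_init__(self) -> None:
        self.heights_cm = np.asarray(self.heights_cm, dtype=float)
        self.diameter_cm = np.asarray(self.diameter_cm, dtype=float)
        self.density_kg_m3 = np.asarray(self.density_kg_m3, dtype=float)
        self.glucose_mg_g = np.asarray(self.glucose_mg_g, dtype=float)
        if self.tw_percent is not None:
            self.tw_percent = np.asarray(self.tw_percent, dtype=float)
        n = self.heights_cm.size
        for name in ("diameter_cm", "density_kg_m3", "glucose_mg_g"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} length != height grid length")
        if self.tw_percent is not None and self.tw_percent.size != n:
            raise ValueError("tw_percent length != height grid length")
        if n and not np.all(np.diff(self.heights_cm) > 0):
            raise ValueError("heights must be strictly increasing")
        if np.any(self.diameter_cm <= 0):
            raise ValueError("diameters must be positive")
        if np.any(self.density_kg_m3 <= 0):
            raise ValueError("densities must be positive")
        if np.any(self.glucose_mg_g < 0):
            raise ValueError("glucose concentrations must be non-negative")
        if self.tw_percent is not None:
            tw = self.tw_percent[~np.isnan(self.tw_percent)]
            if np.any((tw < 0) | (tw > 100)):
                raise ValueError("tw_percent must lie in [0, 100]")

    def __len__(self) -> int:
        return int(self.heights_cm.size)

    def to_frame(self) -> pd.DataFrame:
        tw = (
            self.tw_percent
            if self.tw_percent is not None
            else np.full(len(self), np.nan)
        )
        return pd.DataFrame(
            {
                "height_cm": self.heights_cm,
                "diameter_cm": self.diameter_cm,
                "density_kg_m3": self.density_kg_m3,
                "glucose_mg_g": self.glucose_mg_g,
                "tw_percent": tw,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variety: str = "") -> "HeightProfile":
        missing = [c for c in PROFILE_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"profile table missing columns: {missing}")
        df = df.sort_values("height_cm")
        tw = df["tw_percent"].to_numpy(float) if "tw_percent" in df.columns else None
        if tw is not None and np.all(np.isnan(tw)):
            tw = None
        return cls(
            heights_cm=df["height_cm"].to_numpy(float),
            diameter_cm=df["diameter_cm"].to_numpy(float),
            density_kg_m3=df["density_kg_m3"].to_numpy(float),
            glucose_mg_g=df["glucose_mg_g"].to_numpy(float),
            tw_percent=tw,
            variety=variety,
        )

    @classmethod
    def from_csv(cls, path, variety: str = "") -> "HeightProfile":
        return cls.from_frame(pd.read_csv(path), variety=variety)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SegmentRecord:
    """One stem segment's derived quantities (heights in cm above ground)."""

    top_cm: float
    bottom_cm: float
    volume_cm3: float
    dry_weight_g: float
    tension_volume_cm3: float = math.nan  # NaN where %TW was not measured
    glucose_g: float = 0.0

    def __post_init__(self) -> None:
        if not self.top_cm > self.bottom_cm:
            raise ValueError("segment top must lie above its bottom")
        if not self.volume_cm3 > 0:
            raise ValueError("segment volume must be positive")
        if not self.dry_weight_g > 0:
            raise ValueError("segment dry weight must be positive")
        if self.glucose_g < 0:
            raise ValueError("glucose mass must be non-negative")
        if not math.isnan(self.tension_volume_cm3):
            if not 0 <= self.tension_volume_cm3 <= self.volume_cm3 + 1e-9:
                raise ValueError("tension volume must lie in [0, volume]")

    @property
    def length_cm(self) -> float:
        return self.top_cm - self.bottom_cm


@dataclass
class StemSummary:
    """Aggregates over a height range of a segment stack."""

    h_low_cm: float
    h_high_cm: float
    total_volume_cm3: float
    total_weight_g: float
    total_tension_volume_cm3: float
    total_glucose_g: float
    tension_volume_percent: float
    glucose_per_cellulose_percent: float
    cellulose_fraction: float = 0.45
    mean_glucose_kg_m3: float = math.nan
    n_segments: int = 0
    n_segments_with_tension: int = 0


def _circle_area(diameter_cm: float) -> float:
    return math.pi * diameter_cm * diameter_cm / 4.0


def segment_volume(
    d_top_cm: float | None,
    d_bottom_cm: float | None,
    length_cm: float,
    method: VolumeMethod = "mean_area",
) -> float:
    """Volume (cm³) of a stem segment from its end diameters (cm).

    Default is the mean-of-end-areas rule, ``length × (A_top + A_bottom)/2``;
    ``method="frustum"`` uses the conic frustum instead.  If only one end
    diameter is known the segment is treated as a cylinder at that diameter
    (the basal-segment rule).
    """
    if length_cm <= 0:
        raise ValueError("segment length must be positive")
    if d_top_cm is None and d_bottom_cm is None:
        raise ValueError("at least one end diameter is required")
    if d_top_cm is None or d_bottom_cm is None:
        d = d_top_cm if d_top_cm is not None else d_bottom_cm
        if d <= 0:
            raise ValueError("diameter must be positive")
        return _circle_area(d) * length_cm
    if d_top_cm <= 0 or d_bottom_cm <= 0:
        raise ValueError("diameters must be positive")
    if method == "mean_area":
        return length_cm * (_circle_area(d_top_cm) + _circle_area(d_bottom_cm)) / 2.0
    if method == "frustum":
        r1, r2 = d_top_cm / 2.0, d_bottom_cm / 2.0
        return math.pi * length_cm / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)
    raise ValueError(f"unknown volume method {method!r}")


def segment_weight(volume_cm3: float, density_kg_m3: float) -> float:
    """Oven-dry weight (g) of a segment: volume (cm³) × density (kg/m³)/1000.

    1 kg/m³ equals 1 mg/cm³, hence the factor 1000 from mg to g.
    """
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    if density_kg_m3 <= 0:
        raise ValueError("density must be positive")
    return volume_cm3 * density_kg_m3 / 1000.0


def segment_glucose(weight_g: float, glucose_mg_g: float) -> float:
    """Accessible d-glucose mass (g) in a segment of given dry weight."""
    if weight_g < 0:
        raise ValueError("weight must be non-negative")
    if glucose_mg_g < 0:
        raise ValueError("glucose concentration must be non-negative")
    return weight_g * glucose_mg_g / 1000.0


def tension_volume(volume_cm3: float, tw_percent: float) -> float:
    """Tension-wood volume (cm³) from the cross-section area percentage."""
    if not 0 <= tw_percent <= 100:
        raise ValueError("tw_percent must lie in [0, 100]")
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    return volume_cm3 * tw_percent / 100.0


def _boundary_value(top: float, bottom: float, rule: BoundaryRule) -> float:
    if rule == "top":
        return top
    if rule == "mean":
        return (top + bottom) / 2.0
    raise ValueError(f"unknown boundary rule {rule!r}")


def build_segments(
    profile: HeightProfile,
    boundary_rule: BoundaryRule = "top",
    volume_method: VolumeMethod = "mean_area",
    basal_segment: bool = True,
) -> list[SegmentRecord]:
    """Reduce a height profile to a stack of segments, basal first.

    One segment per adjacent height pair, plus (by default) a basal segment
    from the lowest measured height to ground modelled as a cylinder at the
    lowest diameter.  The basal segment carries no tension-wood volume
    because no section is cut below the lowest boundary.
    """
    if len(profile) < 2:
        raise ValueError("at least two heights are required to form segments")
    h = profile.heights_cm
    d = profile.diameter_cm
    rho = profile.density_kg_m3
    glu = profile.glucose_mg_g
    tw = profile.tw_percent

    segments: list[SegmentRecord] = []
    if basal_segment and h[0] > 0:
        vol = segment_volume(d[0], None, h[0], method=volume_method)
        wt = segment_weight(vol, rho[0])
        segments.append(
            SegmentRecord(
                top_cm=float(h[0]),
                bottom_cm=0.0,
                volume_cm3=vol,
                dry_weight_g=wt,
                tension_volume_cm3=math.nan,
                glucose_g=segment_glucose(wt, glu[0]),
            )
        )
    for i in range(len(h) - 1):
        bot, top = h[i], h[i + 1]
        vol = segment_volume(d[i + 1], d[i], top - bot, method=volume_method)
        dens = _boundary_value(rho[i + 1], rho[i], boundary_rule)
        conc = _boundary_value(glu[i + 1], glu[i], boundary_rule)
        wt = segment_weight(vol, dens)
        if tw is None or math.isnan(tw[i + 1]) or (
            boundary_rule == "mean" and math.isnan(tw[i])
        ):
            tvol = math.nan
        else:
            tvol = tension_volume(vol, _boundary_value(tw[i + 1], tw[i], boundary_rule))
        segments.append(
            SegmentRecord(
                top_cm=float(top),
                bottom_cm=float(bot),
                volume_cm3=vol,
                dry_weight_g=wt,
                tension_volume_cm3=tvol,
                glucose_g=segment_glucose(wt, conc),
            )
        )
    return segments


def attach_tension_volumes(
    segments: Sequence[SegmentRecord],
    volumes_cm3: dict[tuple[float, float], float],
) -> list[SegmentRecord]:
    """Return segments with tension volumes set from ``{(bottom, top): cm³}``.

    Used when tension-wood volumes were measured per segment (stained-section
    image analysis) rather than derived from a %TW column in the profile.
    Segments without an entry keep a NaN tension volume.
    """
    out = []
    for s in segments:
        key = (s.bottom_cm, s.top_cm)
        tvol = volumes_cm3.get(key, s.tension_volume_cm3)
        out.append(
            SegmentRecord(
                top_cm=s.top_cm,
                bottom_cm=s.bottom_cm,
                volume_cm3=s.volume_cm3,
                dry_weight_g=s.dry_weight_g,
                tension_volume_cm3=tvol,
                glucose_g=s.glucose_g,
            )
        )
    return out


def segments_to_frame(segments: Sequence[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "top_cm": [s.top_cm for s in segments],
            "bottom_cm": [s.bottom_cm for s in segments],
            "volume_cm3": [s.volume_cm3 for s in segments],
            "weight_g": [s.dry_weight_g for s in segments],
            "tension_volume_cm3": [s.tension_volume_cm3 for s in segments],
            "glucose_g": [s.glucose_g for s in segments],
        }
    )


def stem_summary(
    segments: Sequence[SegmentRecord],
    h_low_cm: float,
    h_high_cm: float,
    cellulose_fraction: float = 0.45,
    profile: HeightProfile | None = None,
) -> StemSummary:
    """Aggregate a segment stack over ``[h_low_cm, h_high_cm]``.

    The tension-volume percentage is taken over the segments that carry a
    tension-wood volume (the basal segment and unmeasured heights are
    excluded from both numerator and denominator).  The glucose-to-cellulose
    percentage is ``100 × Σ glucose / (cellulose_fraction × Σ dry weight)``
    over every selected segment.  If ``profile`` is given,
    ``mean_glucose_kg_m3`` is the mean over its grid heights inside the range
    of glucose_mg_g × density_kg_m3 / 1000.
    """
    if not 0 < cellulose_fraction < 1:
        raise ValueError("cellulose_fraction must lie in (0, 1)")
    sel = [
        s
        for s in segments
        if s.bottom_cm >= h_low_cm - 1e-9 and s.top_cm <= h_high_cm + 1e-9
    ]
    if not sel:
        raise ValueError(f"no segments inside range [{h_low_cm}, {h_high_cm}] cm")
    tot_v = sum(s.volume_cm3 for s in sel)
    tot_w = sum(s.dry_weight_g for s in sel)
    tot_g = sum(s.glucose_g for s in sel)
    with_t = [s for s in sel if not math.isnan(s.tension_volume_cm3)]
    tot_t = sum(s.tension_volume_cm3 for s in with_t)
    tv_pct = (
        100.0 * tot_t / sum(s.volume_cm3 for s in with_t) if with_t else math.nan
    )
    gc_pct = 100.0 * tot_g / (cellulose_fraction * tot_w)
    mean_gkm3 = math.nan
    if profile is not None:
        in_range = (profile.heights_cm >= h_low_cm - 1e-9) & (
            profile.heights_cm <= h_high_cm + 1e-9
        )
        if in_range.any():
            mean_gkm3 = float(
                np.mean(
                    profile.glucose_mg_g[in_range]
                    * profile.density_kg_m3[in_range]
                    / 1000.0
                )
            )
    return StemSummary(
        h_low_cm=h_low_cm,
        h_high_cm=h_high_cm,
        total_volume_cm3=tot_v,
        total_weight_g=tot_w,
        total_tension_volume_cm3=tot_t if with_t else math.nan,
        total_glucose_g=tot_g,
        tension_volume_percent=tv_pct,
        glucose_per_cellulose_percent=gc_pct,
        cellulose_fraction=cellulose_fraction,
        mean_glucose_kg_m3=mean_gkm3,
        n_segments=len(sel),
        n_segments_with_tension=len(with_t),
    )


def point_glucose_per_cellulose(
    glucose_mg_g: float, cellulose_fraction: float = 0.45
) -> float:
    """Share (%) of total cellulose released as d-glucose at a single point.

    ``100 × glucose_mg_g / (1000 × cellulose_fraction)`` — e.g. 116 mg/g at
    45% cellulose means 25.78% of the wood's cellulose was accessible.
    """
    if glucose_mg_g < 0:
        raise ValueError("glucose concentration must be non-negative")
    if not 0 < cellulose_fraction < 1:
        raise ValueError("cellulose_fraction must lie in (0, 1)")
    return 100.0 * glucose_mg_g / (1000.0 * cellulose_fraction)


def correlation_matrix(profile: HeightProfile) -> pd.DataFrame:
    """Pairwise Pearson correlations among height, glucose, %TW and density.

    Zero-variance columns yield NaN entries (flagged by the NaN itself and a
    ``degenerate`` attribute on the returned frame) rather than a silent 0.
    Columns entirely missing (e.g. no %TW) are dropped.
    """
    if len(profile) < 3:
        raise ValueError("at least three complete rows are required")
    cols = {
        "height_cm": profile.heights_cm,
        "glucose_mg_g": profile.glucose_mg_g,
        "density_kg_m3": profile.density_kg_m3,
    }
    if profile.tw_percent is not None and not np.all(np.isnan(profile.tw_percent)):
        cols["tw_percent"] = profile.tw_percent
    df = pd.DataFrame(cols).dropna()
    if len(df) < 3:
        raise ValueError("fewer than three complete rows after dropping NaNs")
    degenerate = [c for c in df.columns if np.isclose(df[c].std(ddof=0), 0.0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = df.corr(method="pearson")
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["degenerate"] = degenerate
    return corr
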
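"""Directional sample-area series and VD/FD/IL profiles.

The quantitative unit of analysis is a 0.1 x 0.8 mm rectangular sample
area: 0.1 mm along the sampling direction, 0.8 mm across it. A contiguous
series of such areas radiates from the fovea in three directions —
superior, inferior and temporal (the nasal sector is not assessed, the
optic nerve head truncates it). Per area, vessel density (VD, retinal
slabs) is the fraction of flow pixels among analyzable pixels, and the CC
flow-deficit fraction (FD) is the analogous fraction of non-flow pixels;
areas covered > 40% by the large-vessel mask are excluded, as are areas
with less than half their pixels inside the registered field.

Profiles are aligned across subjects by re-indexing offsets so the sample
area containing the APA border sits at 0 mm: inside-APA areas get negative
offsets, outside positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binarize import BinarizedMap
from .io import EnFaceImage

__all__ = [
    "SampleArea",
    "SampleAreaSeries",
    "ProfileSeries",
    "build_series",
    "area_metric",
    "compute_profile",
    "il_profile",
    "align_to_edge",
    "profiles_to_frame",
]

STEP_MM = 0.1          # along-direction extent and stride (contiguous)
ACROSS_MM = 0.8        # across-direction extent
MASK_EXCLUSION_FRACTION = 0.4   # excluded when mask covers > 40% of the area
MIN_VALID_FRACTION = 0.5        # excluded when < 50% of the area is valid


@dataclass(frozen=True)
class SampleArea:
    """One pixel rectangle, half-open: [x0, x1) x [y0, y1)."""

    index: int
    x0: int
    x1: int
    y0: int
    y1: int
    center_distance_mm: float

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y1), slice(self.x0, self.x1))

    @property
    def n_px(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class SampleAreaSeries:
    direction: str
    areas: list[SampleArea]
    step_mm: float = STEP_MM
    temporal_side: str = "left"

    def __len__(self) -> int:
        return len(self.areas)


@dataclass
class ProfileSeries:
    """Ordered per-area values of one metric along one direction.

    ``offsets_mm`` are distances from the fovea until :func:`align_to_edge`
    re-references them to the APA border. Excluded areas carry NaN and a
    reason string.
    """

    direction: str
    metric: str                      # VD | FD | IL
    values: np.ndarray               # float, NaN where excluded
    offsets_mm: np.ndarray
    excluded_reasons: list = field(default_factory=list)
    aligned: bool = False
    subject_id: str = ""
    role: str = "patient"
    modality: str = ""          # source slab (SVC/DCC/CC) or NIRFAF

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.offsets_mm = np.asarray(self.offsets_mm, dtype=np.float64)
        if self.values.shape != self.offsets_mm.shape:
            raise ValueError("values and offsets_mm must have the same length")
        if not self.excluded_reasons:
            self.excluded_reasons = [""] * self.values.size


def _px_per_mm(img_scale_um_per_px: float) -> float:
    return 1000.0 / img_scale_um_per_px


def build_series(
    n_px: int,
    scale_um_per_px: float,
    direction: str,
    fovea_xy_px: tuple[float, float],
    temporal_side: str = "left",
) -> SampleAreaSeries:
    """Pixel rectangles of the 0.1 x 0.8 mm series along one direction.

    A pixel belongs to an area iff its center lies in the half-open
    rectangle; the first area is centered on the fovea; the series stops
    at the last area lying fully inside the image.
    """
    ppm = _px_per_mm(scale_um_per_px)
    fx, fy = fovea_xy_px
    if direction == "superior":
        ux, uy = 0.0, -1.0
    elif direction == "inferior":
        ux, uy = 0.0, 1.0
    elif direction == "temporal":
        ux, uy = (-1.0, 0.0) if temporal_side == "left" else (1.0, 0.0)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    half_along = STEP_MM / 2 * ppm
    half_across = ACROSS_MM / 2 * ppm
    areas = []
    k = 0
    while True:
        d_px = k * STEP_MM * ppm
        cx = fx + ux * d_px
        cy = fy + uy * d_px
        if ux == 0.0:
            x_lo, x_hi = cx - half_across, cx + half_across
            y_lo, y_hi = cy - half_along, cy + half_along
        else:
            x_lo, x_hi = cx - half_along, cx + half_along
            y_lo, y_hi = cy - half_across, cy + half_across
        # pixel-center-in-half-open-rect membership: pixel j has center
        # j + 0.5, so j is included iff lo <= j + 0.5 < hi
        x0, x1 = int(np.ceil(x_lo - 0.5)), int(np.ceil(x_hi - 0.5))
        y0, y1 = int(np.ceil(y_lo - 0.5)), int(np.ceil(y_hi - 0.5))
        if x0 < 0 or y0 < 0 or x1 > n_px or y1 > n_px:
            break
        areas.append(SampleArea(k, x0, x1, y0, y1, k * STEP_MM))
        k += 1
    return SampleAreaSeries(direction=direction, areas=areas,
                            temporal_side=temporal_side)


def area_metric(bmap: BinarizedMap, area: SampleArea, metric: str = "VD"
                ) -> tuple[float, str]:
    """Value of VD or FD in one sample area, or (NaN, reason) if excluded.

    VD counts flow pixels among analyzable (valid, non-masked) pixels; FD
    counts non-flow pixels the same way. Exclusions: the large-vessel mask
    covers more than 40% of the area's valid pixels; less than half the
    area lies in the registered field; no analyzable pixel remains.
    """
    sl = area.slice()
    valid = bmap.valid[sl]
    n_valid = int(valid.sum())
    if n_valid < MIN_VALID_FRACTION * area.n_px:
        return np.nan, "outside registered field"
    masked = bmap.vessel_mask[sl]
    if masked.sum() > MASK_EXCLUSION_FRACTION * n_valid:
        return np.nan, "large-vessel mask > 40%"
    analyzable = valid & ~masked
    denom = int(analyzable.sum())
    if denom == 0:
        return np.nan, "no analyzable pixels"
    flow = bmap.flow[sl]
    n_flow = int((flow & analyzable).sum())
    if metric == "VD":
        return n_flow / denom, ""
    if metric == "FD":
        return (denom - n_flow) / denom, ""
    raise ValueError(f"unknown metric {metric!r}")


def compute_profile(bmap: BinarizedMap, series: SampleAreaSeries,
                    metric: str = "VD", subject_id: str = "",
                    role: str = "patient") -> ProfileSeries:
    """VD or FD profile over a sample-area series."""
    values, reasons = [], []
    for area in series.areas:
        v, reason = area_metric(bmap, area, metric)
        values.append(v)
        reasons.append(reason)
    offsets = np.array([a.center_distance_mm for a in series.areas])
    return ProfileSeries(series.direction, metric, np.array(values), offsets,
                         excluded_reasons=reasons, subject_id=subject_id,
                         role=role, modality=bmap.modality)


def il_profile(nirfaf: EnFaceImage, series: SampleAreaSeries,
               exclude_mask: np.ndarray | None = None) -> ProfileSeries:
    """Mean normalized NIR-FAF intensity (IL) per sample area, on the same
    geometry as the VD/FD profiles.

    ``exclude_mask`` (typically the large-vessel mask) drops pixels from
    the area means: retinal vessels shadow the autofluorescence signal and
    would dent the IL profile with dips unrelated to the APA border. An
    area fully covered by the mask is interpolated from its neighbours.
    """
    values = []
    for a in series.areas:
        px = nirfaf.pixels[a.slice()]
        if exclude_mask is not None:
            keep = ~exclude_mask[a.slice()]
            values.append(float(px[keep].mean()) if keep.any() else np.nan)
        else:
            values.append(float(px.mean()))
    values = np.asarray(values)
    bad = np.isnan(values)
    if bad.any() and not bad.all():
        idx = np.arange(values.size)
        values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    elif bad.all():
        values = np.array([float(nirfaf.pixels[a.slice()].mean())
                           for a in series.areas])
    offsets = np.array([a.center_distance_mm for a in series.areas])
    return ProfileSeries(series.direction, "IL", np.array(values), offsets,
                         subject_id=nirfaf.subject_id, role=nirfaf.role,
                         modality="NIRFAF")


def align_to_edge(profile: ProfileSeries, edge_index: int) -> ProfileSeries:
    """Re-reference offsets to the APA border: the sample area containing
    the border becomes offset 0; inside-APA areas are negative, outside
    positive. Values and exclusions are untouched. Control profiles are
    aligned with the matched patient's edge index."""
    new_offsets = (np.arange(profile.values.size) - edge_index) * STEP_MM
    return replace(profile, offsets_mm=new_offsets, aligned=True)


def profiles_to_frame(profiles: list[ProfileSeries]) -> pd.DataFrame:
    """Tidy long-format table of profiles (one row per sample area)."""
    rows = []
    for p in profiles:
        for v, off, reason in zip(p.values, p.offsets_mm, p.excluded_reasons):
            rows.append({
                "subject_id": p.subject_id,
                "role": p.role,
                "direction": p.direction,
                "metric": p.metric,
                "modality": p.modality,
                "offset_mm": round(float(off), 4),
                "value": v,
                "excluded": bool(reason),
                "reason": reason,
            })
    return pd.DataFrame(rows)
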
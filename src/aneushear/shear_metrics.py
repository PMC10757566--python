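"""Wall-shear-stress postprocessing: TAWSS, OSI and low-shear-area metrics.

Per-point quantities over one cardiac cycle of period T:

    TAWSS = (1/T) * integral_0^T |WSS(t)| dt
    OSI   = 1/2 * (1 - |integral WSS dt| / integral |WSS| dt)

OSI is 0 for unidirectional shear and 0.5 for fully reversing shear; where
the denominator vanishes (zero shear throughout the cycle) OSI is defined
as 0.  Region summaries are area-weighted over per-triangle values, where a
triangle's value is the mean of its three vertex values and its region is
the majority vote of its vertex labels.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import (
    REGION_DOME,
    REGION_PARENT,
    InvalidParameterError,
    TriSurfaceField,
    triangle_areas,
    triangle_regions,
)

#: MTLSA thresholds reported by default, percent of parent mean TAWSS.
DEFAULT_MTLSA_PERCENTS = (50, 70, 90)


@dataclass
class RegionShearSummary:
    """Area-weighted shear statistics for the dome and parent regions.

    TAWSS entries are in dyne/cm^2, OSI dimensionless in [0, 0.5], areas in
    cm^2, and the low-shear metrics (LSA, MTLSA_X) are percentages of the
    total dome area.
    """

    dome_mean_tawss: float
    dome_min_tawss: float
    dome_max_tawss: float
    dome_mean_osi: float
    dome_min_osi: float
    dome_max_osi: float
    dome_area: float
    parent_mean_tawss: float
    parent_min_tawss: float
    parent_max_tawss: float
    parent_mean_osi: float
    parent_min_osi: float
    parent_max_osi: float
    parent_area: float
    lsa: float | None = None
    mtlsa: dict[int, float] | None = None

    def as_metric_row(self) -> dict[str, float]:
        """Flat metric row with the cohort-table column names."""
        row = {
            "Mean_TAWSS": self.dome_mean_tawss,
            "Max_TAWSS": self.dome_max_tawss,
            "Min_TAWSS": self.dome_min_tawss,
            "Mean_OSI": self.dome_mean_osi,
            "Max_OSI": self.dome_max_osi,
            "Min_OSI": self.dome_min_osi,
        }
        if self.lsa is not None:
            row["LSA"] = self.lsa
        for x, v in (self.mtlsa or {}).items():
            row[f"MTLSA_{x}"] = v
        return row

    def to_dict(self) -> dict:
        return asdict(self)


def pointwise_tawss_osi(field: TriSurfaceField) -> tuple[np.ndarray, np.ndarray]:
    """Per-point TAWSS and OSI by trapezoid integration on the stored grid.

    Returns
    -------
    tawss : (N,) array, dyne/cm^2
    osi : (N,) array in [0, 0.5]
    """
    if not np.all(np.isfinite(field.wss)):
        k, i = np.argwhere(~np.isfinite(field.wss).all(axis=2))[0]
        raise InvalidParameterError(f"non-finite WSS vector at point {i}, time index {k}")
    t = field.times
    period = field.period
    if period <= 0:
        raise InvalidParameterError("period must be positive")
    mag = np.linalg.norm(field.wss, axis=2)          # (K, N)
    int_mag = np.trapezoid(mag, t, axis=0)           # (N,)
    int_vec = np.trapezoid(field.wss, t, axis=0)     # (N, 3)
    tawss = int_mag / period
    mag_int_vec = np.linalg.norm(int_vec, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(int_mag > 0, mag_int_vec / np.where(int_mag > 0, int_mag, 1.0), 1.0)
    osi = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return tawss, osi


def _region_stats(
    values: np.ndarray,
    tri_vals: np.ndarray,
    areas: np.ndarray,
    tri_reg: np.ndarray,
    point_mask: np.ndarray,
    label: int,
) -> tuple[float, float, float]:
    """(area-weighted mean over triangles, min over points, max over points)."""
    sel = tri_reg == label
    w = areas[sel]
    mean = float(np.sum(tri_vals[sel] * w) / np.sum(w))
    pts = values[point_mask]
    return mean, float(pts.min()), float(pts.max())


def region_summary(
    field: TriSurfaceField,
    tawss: np.ndarray,
    osi: np.ndarray,
    mtlsa_percents: tuple[int, ...] = DEFAULT_MTLSA_PERCENTS,
) -> RegionShearSummary:
    """Area-weighted dome/parent summaries plus dome low-shear metrics."""
    areas = triangle_areas(field.points, field.triangles)
    tri_reg = triangle_regions(field.region, field.triangles)
    tri = field.triangles
    tri_tawss = tawss[tri].mean(axis=1)
    tri_osi = osi[tri].mean(axis=1)

    for label, name in ((REGION_DOME, "dome"), (REGION_PARENT, "parent")):
        if not np.any(tri_reg == label):
            raise InvalidParameterError(f"empty {name} region")

    dome_pts = field.region == REGION_DOME
    parent_pts = field.region == REGION_PARENT
    d_t = _region_stats(tawss, tri_tawss, areas, tri_reg, dome_pts, REGION_DOME)
    d_o = _region_stats(osi, tri_osi, areas, tri_reg, dome_pts, REGION_DOME)
    p_t = _region_stats(tawss, tri_tawss, areas, tri_reg, parent_pts, REGION_PARENT)
    p_o = _region_stats(osi, tri_osi, areas, tri_reg, parent_pts, REGION_PARENT)

    summary = RegionShearSummary(
        dome_mean_tawss=d_t[0], dome_min_tawss=d_t[1], dome_max_tawss=d_t[2],
        dome_mean_osi=d_o[0], dome_min_osi=d_o[1], dome_max_osi=d_o[2],
        dome_area=float(areas[tri_reg == REGION_DOME].sum()),
        parent_mean_tawss=p_t[0], parent_min_tawss=p_t[1], parent_max_tawss=p_t[2],
        parent_mean_osi=p_o[0], parent_min_osi=p_o[1], parent_max_osi=p_o[2],
        parent_area=float(areas[tri_reg == REGION_PARENT].sum()),
    )
    lsa, mtlsa = low_shear_areas(field, tawss, summary, mtlsa_percents)
    summary.lsa = lsa
    summary.mtlsa = mtlsa
    return summary


def low_shear_areas(
    field: TriSurfaceField,
    tawss: np.ndarray,
    parent_summary: RegionShearSummary,
    mtlsa_percents: tuple[int, ...] = DEFAULT_MTLSA_PERCENTS,
) -> tuple[float, dict[int, float]]:
    """Dome low-shear area metrics, as percent of total dome area.

    LSA uses the threshold (parent mean - 1 parent SD), with the spatial SD
    area-weighted over per-triangle parent TAWSS; a non-positive threshold
    gives LSA = 0.  MTLSA_X uses the threshold X% of the parent mean.
    Triangles count as low under strict ``<`` (ties are not low).
    """
    parent_mean = parent_summary.parent_mean_tawss
    if not parent_mean > 0:
        raise InvalidParameterError("parent mean TAWSS must be positive for thresholding")
    areas = triangle_areas(field.points, field.triangles)
    tri_reg = triangle_regions(field.region, field.triangles)
    tri_tawss = tawss[field.triangles].mean(axis=1)

    dome_sel = tri_reg == REGION_DOME
    dome_area = float(areas[dome_sel].sum())
    if dome_area <= 0:
        raise InvalidParameterError("zero dome area")
    parent_sel = tri_reg == REGION_PARENT
    w = areas[parent_sel]
    v = tri_tawss[parent_sel]
    parent_sd = float(np.sqrt(np.sum(w * (v - np.sum(w * v) / np.sum(w)) ** 2) / np.sum(w)))

    def low_frac(threshold: float) -> float:
        if threshold <= 0:
            return 0.0
        low = dome_sel & (tri_tawss < threshold)
        return 100.0 * float(areas[low].sum()) / dome_area

    lsa = low_frac(parent_mean - parent_sd)
    mtlsa = {int(x): low_frac(x / 100.0 * parent_mean) for x in mtlsa_percents}
    return lsa, mtlsa
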
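"""Synthetic vascular surfaces, WSS fields, inflow waveforms and cohorts.

This module generates every input the downstream pipeline consumes, with
analytically known ground truth: a parent-artery tube carrying a smooth
heterogeneous TAWSS field, a hemispherical aneurysm dome carrying an exact
two-level (low / normal) TAWSS field, prescribed flow-direction reversal
for an OSI target, truncated-Fourier pulsatile inflow waveforms, and paired
growing/stable cohort tables with a controlled additive effect.

The constructions trade physical realism for exact bookkeeping: area
fractions are exact by whole-sector assignment on a rotationally symmetric
dome grid, and WSS magnitudes are constant in time so that the per-point
TAWSS equals the assigned level under trapezoid integration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import (
    REGION_DOME,
    REGION_PARENT,
    FluidProperties,
    InvalidParameterError,
    TriSurfaceField,
    Waveform,
    triangle_areas,
    triangle_regions,
)
from .cohortstats import PairedCohort
from .shear_metrics import DEFAULT_MTLSA_PERCENTS

#: Representative ICA mean flow used as the default inflow, cm^3/s.
DEFAULT_ICA_MEAN_FLOW = 4.0

#: Stable-group metric means used as the default cohort baseline template.
DEFAULT_COHORT_BASELINE: dict[str, float] = {
    "Mean_TAWSS": 55.60,
    "Max_TAWSS": 140.08,
    "Min_TAWSS": 11.14,
    "Mean_OSI": 0.03,
    "Max_OSI": 0.27,
    "Min_OSI": 0.002,
    "LSA": 46.72,
    "MTLSA_50": 37.60,
    "MTLSA_70": 55.74,
    "MTLSA_90": 69.81,
}

#: Default per-metric noise SDs (between- and within-pair), on each metric's
#: own scale.  TAWSS/LSA dispersions follow the reported cohort spreads; the
#: MTLSA values take the growing-group spreads (~17-28 points), the
#: stable-group ones being implausibly small for percentage metrics.
DEFAULT_COHORT_NOISE_SD: dict[str, float] = {
    "Mean_TAWSS": 29.8,
    "Max_TAWSS": 61.2,
    "Min_TAWSS": 7.74,
    "Mean_OSI": 0.05,
    "Max_OSI": 0.12,
    "Min_OSI": 0.003,
    "LSA": 33.23,
    "MTLSA_50": 28.11,
    "MTLSA_70": 23.21,
    "MTLSA_90": 17.14,
}

#: Valid ranges metrics are clipped to after noise.
METRIC_BOUNDS: dict[str, tuple[float, float]] = {
    "Mean_TAWSS": (0.0, np.inf),
    "Max_TAWSS": (0.0, np.inf),
    "Min_TAWSS": (0.0, np.inf),
    "Mean_OSI": (0.0, 0.5),
    "Max_OSI": (0.0, 0.5),
    "Min_OSI": (0.0, 0.5),
    "LSA": (0.0, 100.0),
    "MTLSA_50": (0.0, 100.0),
    "MTLSA_70": (0.0, 100.0),
    "MTLSA_90": (0.0, 100.0),
}


def poiseuille_wss(props: FluidProperties, flow: float, radius: float) -> float:
    """Fully developed Poiseuille wall shear stress tau = 4*mu*Q/(pi*R^3).

    Used as the physical anchor for synthetic parent-artery TAWSS levels.
    Flow in cm^3/s, radius in cm; returns dyne/cm^2.
    """
    if not radius > 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    return 4.0 * props.viscosity * flow / (math.pi * radius**3)


def make_waveform(
    mean_flow: float,
    pulsatility_index: float = 1.0,
    heart_rate: float = 60.0,
    n_harmonics: int = 8,
    n_samples: int = 201,
    systolic_peak_fraction: float = 0.15,
    pulse_width_fraction: float = 0.08,
) -> Waveform:
    """Synthesize a pulsatile ICA-like inflow waveform.

    The shape is a truncated Fourier series of a wrapped Gaussian pulse
    (fast systolic upstroke at ``systolic_peak_fraction`` of the cycle),
    shifted and scaled so that the trapezoid cycle mean equals ``mean_flow``
    exactly and (max - min)/mean equals ``pulsatility_index`` exactly on
    the sample grid.

    Parameters
    ----------
    mean_flow : float
        Cycle-averaged flow, cm^3/s; must be positive.
    pulsatility_index : float
        (max - min)/mean; 0 gives a constant waveform.
    heart_rate : float
        Beats per minute; the period is 60/heart_rate seconds.
    n_harmonics : int
        Harmonics retained in the pulse shape.
    """
    if not (mean_flow > 0 and np.isfinite(mean_flow)):
        raise InvalidParameterError(f"mean_flow must be positive, got {mean_flow}")
    if pulsatility_index < 0:
        raise InvalidParameterError("pulsatility_index must be >= 0")
    if not heart_rate > 0:
        raise InvalidParameterError("heart_rate must be positive")
    period = 60.0 / heart_rate
    t = np.linspace(0.0, period, n_samples)
    omega = 2.0 * math.pi / period
    t0 = systolic_peak_fraction * period
    sigma = pulse_width_fraction * period
    shape = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        shape += math.exp(-0.5 * (k * sigma * omega) ** 2) * np.cos(k * omega * (t - t0))
    shape[-1] = shape[0]  # exact periodic closure
    shape -= np.trapezoid(shape, t) / period
    ptp = shape.max() - shape.min()
    if pulsatility_index == 0 or ptp == 0:
        flow = np.full_like(t, mean_flow)
    else:
        flow = mean_flow + (pulsatility_index * mean_flow / ptp) * shape
    return Waveform(time=t, flow=flow, period=period)


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Parameters of one synthetic aneurysm model.

    Lengths in cm, shear in dyne/cm^2.  ``parent_tawss_mean=None`` anchors
    the parent level to the Poiseuille value for the default ICA mean flow
    in a tube of ``tube_radius``.  ``dome_low_fraction`` is the area
    fraction of the dome assigned the low-shear level
    ``dome_low_level * parent_mean``; it is realized exactly when it is a
    rational with small denominator (whole longitude sectors of the dome
    grid), otherwise to the nearest realizable sector count.
    """

    tube_radius: float = 0.2
    tube_length: float = 2.0
    dome_radius: float = 0.3
    mesh_edge_size: float = 0.03
    parent_tawss_mean: float | None = None
    parent_tawss_cv: float = 0.2
    dome_low_fraction: float = 0.3
    dome_low_level: float = 0.1
    osi_target: float = 0.1
    n_time_samples: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tube_radius", "tube_length", "dome_radius", "mesh_edge_size"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 <= self.dome_low_fraction <= 1.0:
            raise InvalidParameterError("dome_low_fraction must be in [0, 1]")
        if not 0.0 <= self.dome_low_level < 1.0:
            raise InvalidParameterError("dome_low_level must be in [0, 1)")
        if not 0.0 <= self.osi_target <= 0.5:
            raise InvalidParameterError("osi_target must be in [0, 0.5]")
        if not 0.0 <= self.parent_tawss_cv < 0.5:
            raise InvalidParameterError("parent_tawss_cv must be in [0, 0.5)")
        if self.n_time_samples < 4:
            raise InvalidParameterError("need at least 4 time samples")


@dataclass
class GroundTruth:
    """Exact as-constructed values for a synthetic patient."""

    parent_mean_tawss: float
    dome_mean_tawss: float
    dome_low_fraction: float
    dome_area: float
    parent_area: float
    dome_osi: float
    lsa: float
    mtlsa: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _tube_mesh(radius: float, length: float, edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Open cylinder along z, structured triangulation."""
    n_theta = max(12, round(2.0 * math.pi * radius / edge))
    n_z = max(3, round(length / edge))
    theta = np.arange(n_theta) * (2.0 * math.pi / n_theta)
    z = np.linspace(0.0, length, n_z + 1)
    tt, zz = np.meshgrid(theta, z)
    pts = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    )
    tris = []
    for j in range(n_z):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = (j + 1) * n_theta + i
            d = (j + 1) * n_theta + (i + 1) % n_theta
            tris.append((a, b, d))
            tris.append((a, d, c))
    return pts, np.asarray(tris, dtype=np.int64)


def _dome_sector_count(edge: float, radius: float, low_fraction: float) -> int:
    """Longitude sector count, rounded up to a multiple of the fraction's
    denominator so whole-sector assignment realizes it exactly."""
    base = max(12, round(2.0 * math.pi * radius / edge))
    den = Fraction(low_fraction).limit_denominator(60).denominator
    return int(math.ceil(base / den) * den)


def _dome_mesh(
    radius: float, edge: float, center: np.ndarray, n_theta: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hemisphere of longitude sector strips with duplicated seam points.

    Each of the ``n_theta`` sector strips owns private copies of its
    bounding meridians (and of the apex), so any per-sector value
    assignment yields triangles whose three vertices share that value —
    area fractions then follow from exact whole-sector bookkeeping.
    Returns (points, triangles, sector index per point).
    """
    n_phi = max(3, round(0.5 * math.pi * radius / edge))
    phi = np.linspace(0.0, 0.5 * math.pi, n_phi + 1)  # 0 = apex
    d_theta = 2.0 * math.pi / n_theta
    pts: list[np.ndarray] = []
    tris: list[tuple[int, int, int]] = []
    sector: list[int] = []
    for s in range(n_theta):
        th = np.array([s * d_theta, (s + 1) * d_theta])
        base = len(pts)
        # apex copy, then rings phi[1:] x 2 meridians
        pts.append(center + radius * np.array([0.0, 0.0, 1.0]))
        sector.append(s)
        for p in phi[1:]:
            for t in th:
                pts.append(
                    center
                    + radius
                    * np.array([math.sin(p) * math.cos(t), math.sin(p) * math.sin(t), math.cos(p)])
                )
                sector.append(s)
        # apex triangle
        tris.append((base, base + 1, base + 2))
        for j in range(n_phi - 1):
            a = base + 1 + 2 * j
            b, c, d = a + 1, a + 2, a + 3
            tris.append((a, b, d))
            tris.append((a, d, c))
    return np.asarray(pts), np.asarray(tris, dtype=np.int64), np.asarray(sector, dtype=np.int64)


def _area_weighted_mean_sd(
    values: np.ndarray, points: np.ndarray, triangles: np.ndarray, sel: np.ndarray
) -> tuple[float, float]:
    """Area-weighted per-triangle mean and population SD (vertex-averaged values)."""
    w = triangle_areas(points, triangles)[sel]
    v = values[triangles[sel]].mean(axis=1)
    mean = float(np.sum(w * v) / np.sum(w))
    sd = float(np.sqrt(np.sum(w * (v - mean) ** 2) / np.sum(w)))
    return mean, sd


def make_patient(
    spec: SyntheticPatientSpec,
    props: FluidProperties | None = None,
    mtlsa_percents: tuple[int, ...] = DEFAULT_MTLSA_PERCENTS,
) -> tuple[TriSurfaceField, GroundTruth]:
    """Build a synthetic aneurysm surface with known shear ground truth.

    The parent tube carries a smooth heterogeneous TAWSS field around the
    requested mean; the dome carries an exact two-level field (a fraction
    of its area at ``dome_low_level`` times the measured parent mean, the
    rest at the parent mean).  WSS magnitude is constant in time; the dome
    direction reverses once per cycle at the grid index that realizes the
    OSI target under trapezoid integration.
    """
    props = props or FluidProperties()
    if spec.mesh_edge_size > spec.dome_radius:
        raise InvalidParameterError(
            f"mesh_edge_size {spec.mesh_edge_size} cm exceeds dome_radius "
            f"{spec.dome_radius} cm: mesh would be degenerate"
        )
    parent_level = (
        spec.parent_tawss_mean
        if spec.parent_tawss_mean is not None
        else poiseuille_wss(props, DEFAULT_ICA_MEAN_FLOW, spec.tube_radius)
    )

    tube_pts, tube_tris = _tube_mesh(spec.tube_radius, spec.tube_length, spec.mesh_edge_size)
    n_theta = _dome_sector_count(spec.mesh_edge_size, spec.dome_radius, spec.dome_low_fraction)
    center = np.array([spec.tube_radius, 0.0, spec.tube_length / 2.0])
    dome_pts, dome_tris, dome_sector = _dome_mesh(
        spec.dome_radius, spec.mesh_edge_size, center, n_theta
    )

    points = np.vstack([tube_pts, dome_pts])
    triangles = np.vstack([tube_tris, dome_tris + tube_pts.shape[0]])
    region = np.concatenate(
        [np.full(tube_pts.shape[0], REGION_PARENT), np.full(dome_pts.shape[0], REGION_DOME)]
    ).astype(np.int64)

    # parent TAWSS: smooth modulation with approximate CV parent_tawss_cv
    theta_p = np.arctan2(tube_pts[:, 1], tube_pts[:, 0])
    z_p = tube_pts[:, 2]
    modulation = 2.0 * spec.parent_tawss_cv * np.sin(
        2.0 * math.pi * z_p / spec.tube_length
    ) * np.cos(theta_p)
    parent_vals = parent_level * (1.0 + modulation)

    tri_reg = triangle_regions(region, triangles)
    parent_sel = tri_reg == REGION_PARENT
    dome_sel = tri_reg == REGION_DOME

    values = np.empty(points.shape[0])
    values[: tube_pts.shape[0]] = parent_vals
    values[tube_pts.shape[0]:] = 0.0  # placeholder until parent mean is known
    parent_mean, parent_sd = _area_weighted_mean_sd(values, points, triangles, parent_sel)

    # exact two-level dome field on whole longitude sectors
    n_low = round(spec.dome_low_fraction * n_theta)
    low_level = spec.dome_low_level * parent_mean
    dome_vals = np.where(dome_sector < n_low, low_level, parent_mean)
    values[tube_pts.shape[0]:] = dome_vals

    areas = triangle_areas(points, triangles)
    dome_area = float(areas[dome_sel].sum())
    parent_area = float(areas[parent_sel].sum())
    tri_dome_vals = values[triangles[dome_sel]].mean(axis=1)
    low_area = float(areas[dome_sel][tri_dome_vals < 0.5 * (low_level + parent_mean)].sum())
    low_fraction = low_area / dome_area
    dome_mean = float(np.sum(areas[dome_sel] * tri_dome_vals) / dome_area)

    # time axis and direction reversal realizing the OSI target
    n_t = spec.n_time_samples
    times = np.linspace(0.0, 1.0, n_t)  # one cycle, period normalized to 1 s
    if spec.osi_target == 0.0:
        k_flip = n_t  # no reversal
        achieved_osi = 0.0
    else:
        alpha = 1.0 - spec.osi_target
        k_flip = round((n_t + (2.0 * alpha - 1.0) * (n_t - 1)) / 2.0)
        k_flip = min(max(k_flip, 1), n_t - 1)
        achieved_osi = 0.5 * (1.0 - abs(2.0 * k_flip - n_t) / (n_t - 1))
    sign = np.where(np.arange(n_t) < k_flip, 1.0, -1.0)

    direction = np.array([0.0, 0.0, 1.0])
    wss = np.empty((n_t, points.shape[0], 3))
    dome_mask_pts = region == REGION_DOME
    for k in range(n_t):
        mags = values.copy()
        s = np.where(dome_mask_pts, sign[k], 1.0)
        wss[k] = (mags * s)[:, None] * direction[None, :]

    field_obj = TriSurfaceField(
        points=points,
        triangles=triangles,
        region=region,
        times=times,
        wss=wss,
        metadata={"length_unit": "cm", "spec": asdict(spec)},
    )

    # ground-truth low-shear metrics by construction bookkeeping
    def low_frac_at(threshold: float) -> float:
        if threshold <= 0:
            return 0.0
        frac = 0.0
        if low_level < threshold:
            frac += low_fraction
        if parent_mean < threshold:
            frac += 1.0 - low_fraction
        return 100.0 * frac

    gt = GroundTruth(
        parent_mean_tawss=parent_mean,
        dome_mean_tawss=dome_mean,
        dome_low_fraction=low_fraction,
        dome_area=dome_area,
        parent_area=parent_area,
        dome_osi=achieved_osi,
        lsa=low_frac_at(parent_mean - parent_sd),
        mtlsa={int(x): low_frac_at(x / 100.0 * parent_mean) for x in mtlsa_percents},
    )
    return field_obj, gt


def make_cohort(
    n_pairs: int,
    baseline: dict[str, float] | None = None,
    effect: tuple[str, float] | None = None,
    noise_sd: float | dict[str, float] | None = None,
    seed: int = 0,
    between_sd: float | dict[str, float] | None = None,
    location: str = "ICA",
) -> PairedCohort:
    """Generate a matched growing/stable cohort table.

    Stable members are the baseline template plus between-pair noise;
    growing members are their matched stable member plus independent noise
    on every metric, plus the additive ``effect = (metric_name, shift)`` on
    that one metric.  All metrics are clipped to their valid ranges.

    ``noise_sd`` (and ``between_sd``, defaulting to ``noise_sd``) may be a
    scalar applied to every metric or a per-metric mapping (unnamed metrics
    get 0); ``None`` selects :data:`DEFAULT_COHORT_NOISE_SD`.  Reproducible
    under ``seed``.
    """
    if n_pairs < 1:
        raise InvalidParameterError("n_pairs must be >= 1")
    if noise_sd is None:
        noise_sd = dict(DEFAULT_COHORT_NOISE_SD)
    baseline = dict(baseline) if baseline is not None else dict(DEFAULT_COHORT_BASELINE)
    metrics = list(baseline)
    if effect is not None and effect[0] not in metrics:
        raise InvalidParameterError(
            f"unknown metric {effect[0]!r}; valid metrics: {', '.join(metrics)}"
        )

    def sd_for(m: str, spec_sd) -> float:
        if isinstance(spec_sd, dict):
            return float(spec_sd.get(m, 0.0))
        return float(spec_sd)

    between = between_sd if between_sd is not None else noise_sd
    rng = np.random.default_rng(seed)
    rows = []
    for pair in range(1, n_pairs + 1):
        stable = {}
        for m in metrics:
            lo, hi = METRIC_BOUNDS.get(m, (-np.inf, np.inf))
            stable[m] = float(np.clip(baseline[m] + rng.normal(0.0, sd_for(m, between)), lo, hi))
        growing = {}
        for m in metrics:
            lo, hi = METRIC_BOUNDS.get(m, (-np.inf, np.inf))
            shift = effect[1] if (effect is not None and m == effect[0]) else 0.0
            growing[m] = float(
                np.clip(stable[m] + shift + rng.normal(0.0, sd_for(m, noise_sd)), lo, hi)
            )
        rows.append({"pair_id": pair, "group": "stable", "location": location, **stable})
        rows.append({"pair_id": pair, "group": "growing", "location": location, **growing})
    return PairedCohort(pd.DataFrame(rows))
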
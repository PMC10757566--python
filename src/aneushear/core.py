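"""Core domain types shared across the pipeline.

All internal quantities are CGS: lengths in cm, time in s, flow in cm^3/s,
pressure in barye (dyne/cm^2), wall shear stress in dyne/cm^2.  mmHg and mm
appear only at interfaces, with explicit conversion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 1 mmHg in barye (dyne/cm^2).
MMHG_TO_BARYE = 1333.22

#: Region label codes carried per mesh point.
REGION_EXCLUDED = 0
REGION_DOME = 1
REGION_PARENT = 2

REGION_NAMES = {REGION_EXCLUDED: "excluded", REGION_DOME: "dome", REGION_PARENT: "parent"}


class InvalidParameterError(ValueError):
    """A physically or numerically invalid input parameter."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood approximation.

    Parameters
    ----------
    density : float
        Fluid density in g/cm^3 (default 1.06, whole blood).
    viscosity : float
        Dynamic viscosity in Poise (default 0.04, whole blood).
    """

    density: float = 1.06
    viscosity: float = 0.04

    def __post_init__(self) -> None:
        if not (self.density > 0 and np.isfinite(self.density)):
            raise InvalidParameterError(f"density must be positive, got {self.density}")
        if not (self.viscosity > 0 and np.isfinite(self.viscosity)):
            raise InvalidParameterError(f"viscosity must be positive, got {self.viscosity}")


@dataclass(frozen=True)
class Waveform:
    """Periodic volumetric inflow waveform over one cardiac cycle.

    ``time`` is strictly increasing, starts at 0 and ends at ``period``;
    ``flow`` is in cm^3/s and periodically closed (first and last samples
    agree).
    """

    time: np.ndarray
    flow: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", q)
        if t.ndim != 1 or q.shape != t.shape or t.size < 2:
            raise InvalidParameterError("time and flow must be matching 1-D arrays, >=2 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("time must be strictly increasing")
        if t[0] != 0.0:
            raise InvalidParameterError("time must start at 0")
        if not np.isclose(t[-1], self.period, rtol=0, atol=1e-12 * max(self.period, 1.0)):
            raise InvalidParameterError("last time sample must equal the period")
        if not np.all(np.isfinite(q)):
            raise InvalidParameterError("flow contains non-finite values")
        scale = np.max(np.abs(q)) or 1.0
        if abs(q[0] - q[-1]) > 1e-9 * scale:
            raise InvalidParameterError("waveform is not periodically closed")

    @property
    def mean_flow(self) -> float:
        """Cycle-averaged flow, trapezoid rule on the stored grid."""
        return float(np.trapezoid(self.flow, self.time) / self.period)

    @property
    def pulsatility_index(self) -> float:
        """(max - min) / mean of the flow over one cycle."""
        return float((self.flow.max() - self.flow.min()) / self.mean_flow)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Flow at arbitrary times by periodic linear interpolation."""
        return np.interp(np.mod(t, self.period), self.time, self.flow)


@dataclass
class TriSurfaceField:
    """Labeled triangulated surface carrying a WSS vector time series.

    Attributes
    ----------
    points : (N, 3) float array, cm
    triangles : (M, 3) int array of point indices
    region : (N,) int array; 0 excluded, 1 dome, 2 parent
    times : (K,) float array, s; strictly increasing over [0, T]
    wss : (K, N, 3) float array, dyne/cm^2
    """

    points: np.ndarray
    triangles: np.ndarray
    region: np.ndarray
    times: np.ndarray
    wss: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        n = self.points.shape[0]
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidParameterError("points must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise InvalidParameterError("triangles must be (M, 3)")
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise InvalidParameterError("triangle indices out of range")
        if self.region.shape != (n,):
            raise InvalidParameterError("region must be per-point, shape (N,)")
        if self.times.ndim != 1 or self.times.size < 2 or not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing, >=2 samples")
        if self.wss.shape != (self.times.size, n, 3):
            raise InvalidParameterError(
                f"wss must have shape (K={self.times.size}, N={n}, 3), got {self.wss.shape}"
            )
        if not (np.any(self.region == REGION_DOME) and np.any(self.region == REGION_PARENT)):
            raise InvalidParameterError("field needs at least one dome and one parent point")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-triangle areas via the cross-product formula, cm^2."""
    p = np.asarray(points, dtype=float)
    t = np.asarray(triangles, dtype=np.int64)
    a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_regions(region: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-triangle region label by majority vote of the three vertex labels.

    A three-way (or two-way) tie resolves to parent, so ambiguous seam
    triangles inflate the reference region rather than the dome.
    """
    labels = np.asarray(region)[np.asarray(triangles)]
    l0, l1, l2 = labels[:, 0], labels[:, 1], labels[:, 2]
    return np.select(
        [l0 == l1, l1 == l2, l0 == l2],
        [l0, l1, l0],
        default=REGION_PARENT,
    ).astype(np.int64)
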
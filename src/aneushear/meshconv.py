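"""Mesh-convergence bookkeeping for dome mean TAWSS.

A refinement study is a sequence of (max edge size, dome mean TAWSS)
records at strictly decreasing edge size.  The study is converged at the
first refinement whose dome mean TAWSS is within a relative tolerance
(default 5%) of the *previous* refinement.  For reporting, residuals are
also computed against the *final* refinement, together with the mesh size
normalized by the final size — both conventions are emitted because
published convergence plots typically use the final-value normalization
while the stopping rule uses the previous-step one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InvalidParameterError


@dataclass
class ConvergenceTrace:
    """Ordered refinement records; edge sizes in mm, TAWSS in dyne/cm^2."""

    edge_sizes: np.ndarray
    dome_mean_tawss: np.ndarray
    converged: bool = False
    converged_index: int | None = None
    tol: float = 0.05
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.edge_sizes, dtype=float))
        t = np.atleast_1d(np.asarray(self.dome_mean_tawss, dtype=float))
        object.__setattr__(self, "edge_sizes", e)
        object.__setattr__(self, "dome_mean_tawss", t)
        if e.size < 1 or e.shape != t.shape:
            raise InvalidParameterError("edge_sizes and dome_mean_tawss must match, >=1 record")
        if not np.all(np.diff(e) < 0):
            raise InvalidParameterError("edge sizes must be strictly decreasing")


def residual_table(trace: ConvergenceTrace) -> pd.DataFrame:
    """Residuals in both conventions plus normalized mesh size.

    ``residual_vs_final`` = (TAWSS - final TAWSS)/final TAWSS (plot
    convention; exactly 0 at the last record, with ``normalized_size`` =
    size/final size exactly 1 there).  ``residual_vs_previous`` =
    |TAWSS_k - TAWSS_{k-1}|/TAWSS_{k-1} (stopping rule; NaN at the first
    record).
    """
    e, t = trace.edge_sizes, trace.dome_mean_tawss
    prev = np.full_like(t, np.nan)
    prev[1:] = np.abs(np.diff(t)) / np.abs(t[:-1])
    return pd.DataFrame(
        {
            "edge_size_mm": e,
            "dome_mean_tawss": t,
            "normalized_size": e / e[-1],
            "residual_vs_final": (t - t[-1]) / t[-1],
            "residual_vs_previous": prev,
        }
    )


def check_converged(trace: ConvergenceTrace, tol: float = 0.05) -> ConvergenceTrace:
    """Apply the previous-refinement stopping rule; annotate the trace.

    Converged at the first index k >= 1 with
    |TAWSS_k - TAWSS_{k-1}| / TAWSS_{k-1} <= tol.
    """
    if not 0 <= tol < 1:
        raise InvalidParameterError("tol must be in [0, 1)")
    tab = residual_table(trace)
    trace.tol = tol
    trace.table = tab
    trace.converged = False
    trace.converged_index = None
    res = tab["residual_vs_previous"].to_numpy()
    hits = np.where(res[1:] <= tol)[0]
    if hits.size:
        trace.converged = True
        trace.converged_index = int(hits[0] + 1)
    return trace


def next_edge_size(current: float, factor: float = 0.9) -> float:
    """Edge size for the next refinement: current * factor (default -10%)."""
    if not current > 0:
        raise InvalidParameterError("current edge size must be positive")
    if not 0.0 < factor < 1.0:
        raise InvalidParameterError(f"refinement factor must be in (0, 1), got {factor}")
    return current * factor
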
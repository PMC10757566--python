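"""Growth classification and paired cohort statistics.

The growth rule follows the clinical definition used for the cohort: an
aneurysm is *growing* when at least two of its three orthogonal diameters
increased by >= 1 mm between scans, *stable* otherwise.

Group comparisons use the Wilcoxon signed-rank test on paired differences.
For the cohort sizes involved (n around 11) the null distribution is
computed exactly over all 2^n sign assignments of the (mid-)ranked
absolute differences — via a generating-function convolution, not
sampling — so p-values are exact even with ties.  Zero differences are
dropped before ranking by default (Wilcoxon's treatment); the Pratt
variant, which ranks zeros and then discards them, is available.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidParameterError

#: Cohort-table metric columns, in reporting order.
METRIC_COLUMNS = [
    "Mean_TAWSS",
    "Max_TAWSS",
    "Min_TAWSS",
    "Mean_OSI",
    "Max_OSI",
    "Min_OSI",
    "LSA",
    "MTLSA_50",
    "MTLSA_70",
    "MTLSA_90",
]

#: Significance level the cohort report flags at.
DEFAULT_ALPHA = 0.1

#: Largest n for which the exact enumeration is used.
EXACT_N_MAX = 20


@dataclass(frozen=True)
class AneurysmMeasurement:
    """Aneurysm size at one scan: three orthogonal diameters in mm."""

    d1: float
    d2: float
    d3: float
    scan_date: _dt.date | None = None

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise InvalidParameterError(f"missing or non-finite dimension {name}")
            if not v > 0:
                raise InvalidParameterError(f"dimension {name} must be positive, got {v}")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3])

    @property
    def volume(self) -> float:
        """Ellipsoid volume estimate pi/6 * d1*d2*d3, mm^3."""
        return float(np.pi / 6.0 * self.d1 * self.d2 * self.d3)


def classify_growth(
    baseline: AneurysmMeasurement,
    followup: AneurysmMeasurement,
    threshold_mm: float = 1.0,
    min_dimensions: int = 2,
) -> str:
    """Classify an aneurysm as ``"growing"`` or ``"stable"`` between scans."""
    if baseline.scan_date is not None and followup.scan_date is not None:
        if followup.scan_date <= baseline.scan_date:
            raise InvalidParameterError("follow-up scan must be later than baseline")
    deltas = followup.diameters - baseline.diameters
    return "growing" if int(np.sum(deltas >= threshold_mm)) >= min_dimensions else "stable"


class PairedCohort:
    """Matched growing/stable cohort: one row per member, paired by pair_id.

    Wraps a DataFrame with columns ``pair_id``, ``group`` (growing/stable),
    ``location``, and one column per metric.  Every pair must contain
    exactly one growing and one stable member with the same location.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"pair_id", "group"}
        missing = required - set(table.columns)
        if missing:
            raise InvalidParameterError(f"cohort table missing columns: {sorted(missing)}")
        bad_groups = set(table["group"]) - {"growing", "stable"}
        if bad_groups:
            raise InvalidParameterError(f"unknown group labels: {sorted(bad_groups)}")
        for pid, sub in table.groupby("pair_id"):
            if sorted(sub["group"]) != ["growing", "stable"]:
                raise InvalidParameterError(
                    f"pair {pid} must have exactly one growing and one stable member"
                )
            if "location" in sub.columns and sub["location"].nunique() != 1:
                raise InvalidParameterError(f"pair {pid} members have different locations")
        self.table = table.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    @property
    def metrics(self) -> list[str]:
        known = [c for c in METRIC_COLUMNS if c in self.table.columns]
        extra = [
            c
            for c in self.table.columns
            if c not in known and c not in ("pair_id", "group", "location")
        ]
        return known + extra

    def paired_values(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        """(growing, stable) value vectors aligned by pair_id."""
        if metric not in self.table.columns:
            raise InvalidParameterError(f"metric {metric!r} not in cohort table")
        wide = self.table.pivot(index="pair_id", columns="group", values=metric)
        if wide.isna().any().any():
            pid = wide[wide.isna().any(axis=1)].index[0]
            raise InvalidParameterError(f"metric {metric!r} missing for pair {pid}")
        return wide["growing"].to_numpy(float), wide["stable"].to_numpy(float)

    def differences(self, metric: str) -> np.ndarray:
        g, s = self.paired_values(metric)
        return g - s


@dataclass
class PairedTestResult:
    """Exact Wilcoxon signed-rank result for one metric."""

    metric: str
    n_pairs: int
    n_effective: int
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    growing_mean: float = np.nan
    growing_sd: float = np.nan
    stable_mean: float = np.nan
    stable_sd: float = np.nan
    method: str = "exact"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _signed_rank_statistic(diffs: np.ndarray, zero_method: str) -> tuple[float, np.ndarray, int]:
    """W+ and the mid-rank vector used in the null enumeration."""
    d = np.asarray(diffs, dtype=float)
    n_zero = int(np.sum(d == 0))
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise InvalidParameterError(f"unknown zero_method {zero_method!r}")
    if d.size == 0:
        return 0.0, np.array([]), 0
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(np.sum(ranks[d > 0]))
    if zero_method == "pratt":
        # zeros consume the smallest ranks, then drop from the enumeration
        keep = d != 0
        ranks = ranks[keep]
        d = d[keep]
        w_plus = float(np.sum(ranks[d > 0]))
    return w_plus, ranks, d.size


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments of the given ranks.

    Works on doubled ranks (mid-ranks become integers) with a
    generating-function convolution: coefficient c[w] of
    prod_i (1 + x^{2 r_i}) counts sign vectors with doubled W+ = w.
    Two-sided p = 2 * min(P(W <= w_obs), P(W >= w_obs)), capped at 1.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()  # copy: slices overlap
    n_assign = 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired_exact(
    growing: np.ndarray,
    stable: np.ndarray,
    metric: str = "",
    zero_method: str = "wilcox",
) -> PairedTestResult:
    """Exact Wilcoxon signed-rank test on paired growing - stable differences.

    For up to 20 effective pairs the full 2^n null enumeration is used
    (mid-rank ties included exactly); beyond that, a normal approximation
    with tie and continuity corrections.  All differences zero gives
    p = 1 with ``n_effective = 0`` flagged degenerate.
    """
    g = np.asarray(growing, dtype=float)
    s = np.asarray(stable, dtype=float)
    if g.shape != s.shape or g.ndim != 1 or g.size < 1:
        raise InvalidParameterError("growing and stable must be equal-length 1-D, n >= 1")
    diffs = g - s
    w_plus, ranks, n_eff = _signed_rank_statistic(diffs, zero_method)
    res = PairedTestResult(
        metric=metric,
        n_pairs=g.size,
        n_effective=n_eff,
        statistic=w_plus,
        p_value=1.0,
        growing_mean=float(g.mean()),
        growing_sd=float(g.std(ddof=1)) if g.size > 1 else 0.0,
        stable_mean=float(s.mean()),
        stable_sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
    )
    if n_eff == 0:
        res.degenerate = True
        res.method = "degenerate"
        return res
    if n_eff <= EXACT_N_MAX:
        res.p_value = _exact_signed_rank_p(w_plus, ranks)
        res.method = "exact"
    else:
        res.p_value = _approx_signed_rank_p(w_plus, ranks)
        res.method = "normal-approx"
    return res


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


@dataclass
class NormalityRow:
    metric: str
    statistic: float
    p_value: float
    normal: bool
    degenerate: bool = False


@dataclass
class NormalityGate:
    rows: list[NormalityRow] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def recommendation(self) -> str:
        return "nonparametric" if any(not r.normal for r in self.rows) else "parametric"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def shapiro_wilk_gate(cohort: PairedCohort, alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk normality screen on paired differences, per metric.

    Recommends the nonparametric route if any metric rejects normality at
    ``alpha``.  Constant difference vectors have no defined normality and
    are flagged degenerate and treated as non-normal.
    """
    if cohort.n_pairs < 3:
        raise InvalidParameterError("need at least 3 pairs for a normality test")
    gate = NormalityGate(alpha=alpha)
    for metric in cohort.metrics:
        d = cohort.differences(metric)
        if np.ptp(d) == 0:
            gate.rows.append(
                NormalityRow(metric=metric, statistic=np.nan, p_value=np.nan,
                             normal=False, degenerate=True)
            )
            continue
        w, p = stats.shapiro(d)
        gate.rows.append(
            NormalityRow(metric=metric, statistic=float(w), p_value=float(p), normal=p > alpha)
        )
    return gate


def cohort_report(
    cohort: PairedCohort,
    alpha: float = DEFAULT_ALPHA,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Per-metric summary table: group means/SDs, exact p, significance flag.

    One row per metric in reporting order; ``significant`` marks
    p <= alpha (default 0.1).
    """
    rows = []
    for metric in cohort.metrics:
        g, s = cohort.paired_values(metric)
        r = wilcoxon_paired_exact(g, s, metric=metric, zero_method=zero_method)
        rows.append(
            {
                "metric": metric,
                "stable_mean": r.stable_mean,
                "stable_sd": r.stable_sd,
                "growing_mean": r.growing_mean,
                "growing_sd": r.growing_sd,
                "n_pairs": r.n_pairs,
                "n_effective": r.n_effective,
                "W": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "significant": bool(r.p_value <= alpha),
            }
        )
    return pd.DataFrame(rows)
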
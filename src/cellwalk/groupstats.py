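"""Condition-comparison statistics for migration and microtubule data.

Three procedures:

* **Vehicle-anchored tertile analysis** of microtubule plus-end growth
  speeds: the reference (vehicle) condition's events are split into
  equal thirds by speed, and those same bin edges are applied to every
  other condition, so shifts inside the slow/medium/fast sub-populations
  can be compared directly.
* **Step-length frequency distributions** on shared bins across
  conditions (treatment shows up as a left-shift of the curve).
* **Rank-sum time-course scan**: at every acquisition time point the
  cumulative distances of treated and vehicle cells still being tracked
  are compared with a two-sided Mann–Whitney/Wilcoxon rank-sum test;
  the earliest significant time is the first point with p below α
  (default 0.0001) *and* a reduced treated median.  No multiplicity
  correction is applied across the scan — the threshold is a
  per-time-point criterion, which is why the default α is so strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .trajectories import CumulativeDistanceMatrix

TERTILE_LABELS = ("slow", "medium", "fast")

EXACT_TEST_MAX_N = 50  # per arm; larger groups use the tie-corrected normal approx


@dataclass(frozen=True)
class TertileSummary:
    """Reference-anchored tertile bins with per-condition counts and medians."""

    reference: str
    edges: tuple[float, float]  # (e1, e2): bins (-inf, e1], (e1, e2], (e2, inf)
    counts: pd.DataFrame  # condition x bin
    medians: pd.DataFrame  # condition x bin

    def __post_init__(self):
        if not self.edges[0] < self.edges[1]:
            raise DataError("tertile edges must be strictly increasing")


def tertile_analysis(events: pd.DataFrame, reference_condition: str,
                     speed_column: str = "growth_speed_um_min",
                     condition_column: str = "condition") -> TertileSummary:
    """Split growth-speed events into reference-anchored tertiles.

    Edges are the 1/3 and 2/3 empirical quantiles (inclusive linear
    interpolation) of the reference condition; bins are left-open /
    right-closed with ties in the lower bin.
    """
    if reference_condition not in set(events[condition_column]):
        raise DataError(f"reference condition {reference_condition!r} absent")
    ref = events.loc[events[condition_column] == reference_condition, speed_column]
    if ref.size < 3:
        raise DataError("reference condition needs >= 3 events")
    if (events[speed_column] <= 0).any():
        raise DataError("growth speeds must be > 0")
    e1, e2 = np.quantile(ref.to_numpy(float), [1.0 / 3.0, 2.0 / 3.0])
    if not e1 < e2:
        raise DataError("degenerate reference speeds: tertile edges coincide")
    counts = {}
    medians = {}
    for condition, grp in events.groupby(condition_column, sort=True):
        v = grp[speed_column].to_numpy(float)
        masks = (v <= e1, (v > e1) & (v <= e2), v > e2)
        counts[condition] = [int(m.sum()) for m in masks]
        medians[condition] = [float(np.median(v[m])) if m.any() else float("nan")
                              for m in masks]
    return TertileSummary(
        reference=reference_condition,
        edges=(float(e1), float(e2)),
        counts=pd.DataFrame(counts, index=TERTILE_LABELS).T,
        medians=pd.DataFrame(medians, index=TERTILE_LABELS).T,
    )


def step_length_histogram(steps_by_condition: dict[str, np.ndarray],
                          bin_width: float,
                          normalised: bool = True) -> pd.DataFrame:
    """Step-length frequency curves on bins shared across conditions."""
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    if not steps_by_condition:
        raise DataError("no conditions supplied")
    all_steps = np.concatenate([np.asarray(v, float) for v in steps_by_condition.values()])
    if all_steps.size == 0:
        raise DataError("no step data supplied")
    lo = np.floor(all_steps.min() / bin_width) * bin_width
    hi = np.ceil(all_steps.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    out = {"bin_left": edges[:-1], "bin_centre": 0.5 * (edges[:-1] + edges[1:])}
    for condition, v in steps_by_condition.items():
        counts, _ = np.histogram(np.asarray(v, float), bins=edges)
        out[condition] = counts / counts.sum() if normalised and counts.sum() else counts
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SignificanceScanResult:
    """Per-time-point rank-sum scan outcome."""

    table: pd.DataFrame  # t_min, n_vehicle, n_treated, p_value, treated_median_lower, significant
    alpha: float
    earliest_significant_time: float | None

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum())
        first = ("none" if self.earliest_significant_time is None
                 else f"{self.earliest_significant_time:g} min")
        return (
            f"Rank-sum scan over {len(self.table)} time points (alpha={self.alpha:g})\n"
            f"significant points: {n_sig}; earliest significant time: {first}"
        )


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact for small arms, normal approx otherwise."""
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= EXACT_TEST_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def rank_sum_scan(treated: CumulativeDistanceMatrix,
                  vehicle: CumulativeDistanceMatrix,
                  alpha: float = 0.0001,
                  require_median_reduction: bool = True,
                  min_group: int = 2) -> SignificanceScanResult:
    """Scan the time course for the earliest significant migration reduction.

    At each shared time point, cells whose tracks end earlier are
    dropped from that point only.  A point is significant when the
    two-sided rank-sum p-value is below ``alpha`` and (by default) the
    treated median is below the vehicle median.
    """
    if not np.isclose(treated.frame_interval, vehicle.frame_interval):
        raise DataError("cohorts must share a frame interval")
    n_times = min(treated.times.size, vehicle.times.size)
    if n_times == 0 or treated.n_tracked_at(0) < min_group or vehicle.n_tracked_at(0) < min_group:
        raise DataError("empty group at the first time point")
    rows = []
    earliest = None
    for k in range(1, n_times):  # k=0 is identically zero for every track
        tv = treated.values_at(k)
        vv = vehicle.values_at(k)
        if tv.size < min_group or vv.size < min_group:
            break
        p = _rank_sum_p(tv, vv)
        reduced = bool(np.median(tv) < np.median(vv))
        significant = (p < alpha) and (reduced or not require_median_reduction)
        t_min = float(treated.times[k])
        if significant and earliest is None:
            earliest = t_min
        rows.append({
            "t_min": t_min, "n_vehicle": int(vv.size), "n_treated": int(tv.size),
            "p_value": p, "treated_median_lower": reduced, "significant": significant,
        })
    if not rows:
        raise DataError("no comparable time points beyond t=0")
    return SignificanceScanResult(
        table=pd.DataFrame(rows), alpha=alpha, earliest_significant_time=earliest
    )
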
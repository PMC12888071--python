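"""Survey-time equalization by constrained subsampling.

Continuous sensor records (camera traps, acoustic recorders) accumulate
far more survey time than a human point-transect protocol.  To compare
detectability at equal survey time, a sensor record is repeatedly
subsampled into three equal occasions whose total length matches a
survey-time window, with consecutive occasions separated by at least
five days (mirroring the transect protocol of three visits at least
five days apart).  Repeating the random placement many times yields a
detectability estimate with a replicate confidence band per window
length; the window at which the sensor curve first reaches the
point-transect benchmark is found by linear interpolation, and the
effect of window length is tested with a one-way ANOVA.

Detectability per window is the pooled occasion-level detection
proportion across sites — identical to the psi = 1 intercept-only
occupancy MLE on the 3-occasion histories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection_data import ValidationError

HOURS_PER_DAY = 24.0

__all__ = [
    "WindowScheme",
    "EffortCurve",
    "feasible",
    "draw_occasions",
    "subsample_history",
    "effort_curve",
    "crossing_time",
    "anova_windows",
]


@dataclass(frozen=True)
class WindowScheme:
    """A survey-time window split into 3 gap-constrained occasions.

    ``window_hours`` is the total survey time (grid runs in 5-h steps
    from 5 h to 576 h = 24 days); each of the ``n_occasions`` = 3
    occasions lasts ``window_hours / 3``.  ``min_gap_days`` separates
    the end of one occasion from the start of the next (the stricter
    reading of "at least 5 days apart"; set ``gap_from_start=True`` for
    start-to-start spacing).
    """

    window_hours: float
    n_occasions: int = 3
    min_gap_days: float = 5.0
    n_reps: int = 1000
    seed: int = 0
    gap_from_start: bool = False

    def __post_init__(self):
        if self.window_hours <= 0:
            raise ValidationError("window_hours must be positive")
        if self.n_occasions < 1:
            raise ValidationError("need at least one occasion")

    @property
    def occasion_hours(self) -> float:
        return self.window_hours / self.n_occasions

    @property
    def gap_hours(self) -> float:
        return self.min_gap_days * HOURS_PER_DAY

    def span_required(self) -> float:
        """Minimum record length (hours) admitting a feasible draw."""
        L, G, n = self.occasion_hours, self.gap_hours, self.n_occasions
        if self.gap_from_start:
            return max(L, (n - 1) * max(G, L) + L)
        return n * L + (n - 1) * G


def feasible(scheme: WindowScheme, record_hours: float) -> bool:
    return record_hours >= scheme.span_required()


def draw_occasions(
    record_hours: float, scheme: WindowScheme, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw occasion start times uniformly over the feasible set.

    Returns an array of shape ``(size, n_occasions)`` of start times in
    hours from the record start; occasion k covers
    ``[start_k, start_k + occasion_hours)``.  Uniformity over the
    ordered, gap-constrained polytope is exact: subtracting
    ``k * (occasion + gap)`` from the k-th ordered start maps the
    polytope onto the simplex of 3 ordered points on the slack
    interval, so sorted uniform draws on the slack, shifted back, are
    uniform on the polytope.
    """
    if not feasible(scheme, record_hours):
        raise ValidationError(
            f"record of {record_hours:.1f} h cannot host {scheme.n_occasions} "
            f"occasions of {scheme.occasion_hours:.2f} h with "
            f"{scheme.min_gap_days}-day gaps (needs {scheme.span_required():.1f} h)"
        )
    n = scheme.n_occasions
    L = scheme.occasion_hours
    step = max(scheme.gap_hours, L) if scheme.gap_from_start else L + scheme.gap_hours
    slack = record_hours - L - (n - 1) * step
    u = np.sort(rng.random((size, n)), axis=1) * slack
    offsets = np.arange(n) * step
    return u + offsets


def subsample_history(
    event_hours: np.ndarray, starts: np.ndarray, occasion_hours: float
) -> np.ndarray:
    """Score occasions 1/0: 1 iff >= 1 detected event falls inside.

    ``event_hours`` are detected-event times in hours from the record
    start (sorted or not); ``starts`` has shape (..., n_occasions).
    """
    ev = np.sort(np.asarray(event_hours, dtype=float))
    lo = np.searchsorted(ev, starts, side="left")
    hi = np.searchsorted(ev, starts + occasion_hours, side="left")
    return (hi > lo).astype(float)


@dataclass
class EffortCurve:
    """Replicate detectability estimates per survey-time window."""

    table: pd.DataFrame                 # window_hours, mean, lo, hi, n_sites, n_reps
    replicates: dict[float, np.ndarray] # window_hours -> per-replicate estimates
    excluded: dict[float, list[str]]    # window_hours -> infeasible site ids
    reference: dict | None = None       # {"mean": p, "lo": ..., "hi": ...}


def effort_curve(
    events_by_site: Mapping[str, np.ndarray],
    record_hours_by_site: Mapping[str, float],
    grid_hours: Sequence[float],
    n_reps: int = 1000,
    seed: int = 0,
    min_gap_days: float = 5.0,
    reference: dict | None = None,
    interval: tuple[float, float] = (2.5, 97.5),
) -> EffortCurve:
    """Detectability versus survey-time window for one method.

    For every window length on the grid, each feasible site contributes
    3 randomly placed occasions per replicate; the replicate estimate is
    the pooled proportion of detected occasions across sites.  The
    summary per window is the replicate mean and a percentile interval.
    Sites whose records are too short for a window are excluded from
    that grid point and reported (mirroring recorders that failed before
    accumulating enough days).  Deterministic under a fixed seed.
    """
    grid = sorted(float(w) for w in grid_hours)
    rows, reps_store, excluded = [], {}, {}
    for wi, w in enumerate(grid):
        scheme = WindowScheme(
            window_hours=w, min_gap_days=min_gap_days, n_reps=n_reps, seed=seed
        )
        ok_sites = [
            s for s in events_by_site if feasible(scheme, record_hours_by_site[s])
        ]
        excluded[w] = [s for s in events_by_site if s not in ok_sites]
        if not ok_sites:
            rows.append(
                {"window_hours": w, "mean": np.nan, "lo": np.nan, "hi": np.nan,
                 "n_sites": 0, "n_reps": n_reps}
            )
            reps_store[w] = np.full(n_reps, np.nan)
            continue
        det = np.zeros(n_reps)
        total = len(ok_sites) * scheme.n_occasions
        for si, s in enumerate(ok_sites):
            rng = np.random.default_rng([seed, wi, si])
            starts = draw_occasions(record_hours_by_site[s], scheme, rng, size=n_reps)
            cells = subsample_history(events_by_site[s], starts, scheme.occasion_hours)
            det += cells.sum(axis=1)
        est = det / total
        lo, hi = np.percentile(est, interval)
        rows.append(
            {"window_hours": w, "mean": float(est.mean()), "lo": float(lo),
             "hi": float(hi), "n_sites": len(ok_sites), "n_reps": n_reps}
        )
        reps_store[w] = est
    return EffortCurve(
        table=pd.DataFrame(rows), replicates=reps_store, excluded=excluded,
        reference=reference,
    )


def crossing_time(curve: EffortCurve, reference: dict | None = None) -> dict:
    """Hours of survey time at which the mean curve first reaches the benchmark.

    Linear interpolation between adjacent grid points; ``nan`` when the
    curve never reaches the level within the grid.  Returns hours to
    the reference mean and to the reference upper bound.
    """
    ref = reference or curve.reference
    if ref is None:
        raise ValidationError("crossing_time needs a reference level")
    tab = curve.table.dropna(subset=["mean"])
    x = tab["window_hours"].to_numpy(dtype=float)
    y = tab["mean"].to_numpy(dtype=float)

    def first_cross(level: float) -> float:
        if x.size == 0:
            return np.nan
        if y[0] >= level:
            return float(x[0])
        above = np.flatnonzero(y >= level)
        if above.size == 0:
            return np.nan
        i = above[0]
        x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
        if y1 == y0:
            return float(x1)
        return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))

    out = {"hours_to_reference_mean": first_cross(float(ref["mean"]))}
    if "hi" in ref:
        out["hours_to_reference_upper"] = first_cross(float(ref["hi"]))
    return out


def anova_windows(groups: Mapping[float, np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA of replicate estimates on window length.

    Returns F, degrees of freedom, p-value and the sums of squares.
    All-identical data (zero between-group variation) give F = 0; zero
    within-group variance with non-zero between-group variation leaves
    F undefined and sets ``degenerate``.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("ANOVA needs at least two replicates per group")
    k = len(arrays)
    N = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, N - k
    if ssb == 0.0:
        return {"F": 0.0, "df": (df_b, df_w), "p_value": 1.0,
                "ssb": 0.0, "ssw": float(ssw), "degenerate": False}
    if ssw == 0.0:
        return {"F": np.inf, "df": (df_b, df_w), "p_value": 0.0,
                "ssb": float(ssb), "ssw": 0.0, "degenerate": True}
    from scipy.stats import f as f_dist

    F = (ssb / df_b) / (ssw / df_w)
    return {
        "F": float(F),
        "df": (df_b, df_w),
        "p_value": float(f_dist.sf(F, df_b, df_w)),
        "ssb": float(ssb),
        "ssw": float(ssw),
        "degenerate": False,
    }
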
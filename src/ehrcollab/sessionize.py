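"""Sessionize audit-log events into intervals; knee-point cutoff estimation.

An *interval* is a maximal run of one HCW's consecutive events on one
patient's record in which successive events are separated by at most a gap
cutoff (strictly more than the cutoff starts a new interval, so a gap exactly
equal to the cutoff stays within the interval). A single-event interval has
duration zero. Two intervals of the same HCW on the same patient can never
overlap, by construction.

The gap cutoff is estimated from the data as the knee of the trade-off curve
"number of intervals produced" versus "cutoff": the curve falls steeply while
the cutoff is below the within-task gap scale and flattens once it passes it.
The knee is located with the Kneedle construction, which operationalizes the
point of maximum curvature

    K(x) = f''(x) / (1 + f'(x)^2)^1.5

of the normalized curve; :func:`discrete_curvature` exposes the discrete
version of this quantity for inspection and cross-checking.

An *active EHR workday* is a calendar day on which an HCW's summed interval
duration reaches a threshold (15 minutes by default, the value appropriate
for intensive-care settings); lower-activity days are flagged inactive and
excluded from downstream intensity metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WORKDAY_CUTOFF_MIN = 15.0
DEFAULT_CANDIDATE_CUTOFFS = np.arange(10.0, 1801.0, 10.0)

INTERVAL_COLUMNS = (
    "hcw_id",
    "patient_id",
    "start",
    "stop",
    "duration_s",
    "n_events",
    "actions",
)


class KneeNotFoundError(ValueError):
    """The curve has no knee (flat, linear, or wrong orientation)."""


@dataclass(frozen=True)
class KneeCurve:
    """A candidate-versus-response curve with its selected knee.

    ``x`` is strictly increasing and ``knee`` is an element of ``x``.
    ``difference`` is the normalized Kneedle difference curve whose maximum
    defines the knee.
    """

    x: np.ndarray
    y: np.ndarray
    knee: float
    difference: np.ndarray


def build_intervals(
    events: pd.DataFrame, cutoff_s: float, collect_actions: bool = True
) -> pd.DataFrame:
    """Group sorted events into intervals at the given gap cutoff.

    Parameters
    ----------
    events:
        Sorted by ``(hcw_id, patient_id, timestamp)`` — enforced, unsorted
        input raises.
    cutoff_s:
        Gap cutoff in seconds (> 0). A new interval starts when the gap to
        the previous event of the same HCW/patient stream exceeds it.
    collect_actions:
        When True the per-interval ``actions`` column holds the multiset of
        action IDs (as a tuple in event order); disable for large scans that
        only need counts and times.

    Returns
    -------
    DataFrame with one row per interval (columns
    ``hcw_id, patient_id, start, stop, duration_s, n_events[, actions]``).
    Every event belongs to exactly one interval.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    if events.empty:
        cols = [c for c in INTERVAL_COLUMNS if collect_actions or c != "actions"]
        return pd.DataFrame(columns=cols)

    hcw = events["hcw_id"].to_numpy()
    pat = events["patient_id"].to_numpy()
    ts = events["timestamp"].to_numpy(dtype="datetime64[ns]")

    new_group = np.ones(len(events), dtype=bool)
    new_group[1:] = (hcw[1:] != hcw[:-1]) | (pat[1:] != pat[:-1])
    gaps = np.empty(len(events))
    gaps[0] = 0.0
    gaps[1:] = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
    if np.any(gaps[~new_group] < 0):
        raise ValueError("events must be sorted by (hcw_id, patient_id, timestamp)")

    new_interval = new_group | (gaps > cutoff_s)
    iid = np.cumsum(new_interval) - 1

    df = pd.DataFrame(
        {
            "iid": iid,
            "hcw_id": hcw,
            "patient_id": pat,
            "timestamp": ts,
        }
    )
    agg = {
        "hcw_id": ("hcw_id", "first"),
        "patient_id": ("patient_id", "first"),
        "start": ("timestamp", "first"),
        "stop": ("timestamp", "last"),
        "n_events": ("timestamp", "size"),
    }
    out = df.groupby("iid", sort=True).agg(**agg).reset_index(drop=True)
    out["duration_s"] = (out["stop"] - out["start"]).dt.total_seconds()
    if collect_actions:
        actions = (
            pd.Series(events["action_id"].to_numpy(), name="action_id")
            .groupby(iid)
            .agg(tuple)
        )
        out["actions"] = actions.to_numpy()
    return out[[c for c in INTERVAL_COLUMNS if c in out.columns]]


def discrete_curvature(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Discrete curvature ``y'' / (1 + y'^2)^1.5`` via central differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)
    return d2 / (1.0 + d1**2) ** 1.5


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def knee_point(
    curve_x: np.ndarray, curve_y: np.ndarray, smoothing: int = 5
) -> float:
    """Locate the knee of a trade-off curve by the Kneedle construction.

    The curve is smoothed with a centered moving average (``smoothing``
    points; 1 disables), min–max normalized, orientation-corrected so that a
    decreasing curve becomes increasing, and the knee is the ``x`` at the
    maximum of the difference curve ``y_norm − x_norm``. Ties return the
    smallest ``x`` (conservative sessionization). The result is invariant to
    affine rescaling of either axis.

    Raises
    ------
    KneeNotFoundError
        For flat or purely linear curves ("no knee").
    ValueError
        For fewer than five points or non-increasing ``x``.
    """
    x = np.asarray(curve_x, dtype=float)
    y = np.asarray(curve_y, dtype=float)
    if len(x) < 5:
        raise ValueError("knee detection needs at least 5 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("curve_x must be strictly increasing")
    if smoothing % 2 == 0:
        smoothing += 1
    ys = _moving_average(y, smoothing)
    if np.ptp(ys) == 0:
        raise KneeNotFoundError("no knee: flat curve")
    dy = np.diff(ys)
    if np.any(dy > 1e-12) and np.any(dy < -1e-12):
        warnings.warn("curve is not monotone after smoothing", stacklevel=2)

    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (ys - ys.min()) / np.ptp(ys)
    if yn[-1] < yn[0]:  # decreasing curve -> flip to increasing
        yn = 1.0 - yn
    diff = yn - xn
    if diff.max() <= 1e-9:
        raise KneeNotFoundError("no knee: curve is linear or convex-increasing")
    best = np.flatnonzero(diff >= diff.max() - 1e-12)[0]
    return float(x[best])


def interval_count_curve(
    events: pd.DataFrame, candidate_cutoffs: np.ndarray
) -> np.ndarray:
    """Number of intervals produced at each candidate cutoff.

    Equivalent to ``len(build_intervals(events, c))`` for every candidate,
    computed in one pass: the interval count at cutoff ``c`` is the number
    of (hcw, patient) streams plus the number of within-stream gaps
    strictly greater than ``c``.
    """
    candidates = np.asarray(candidate_cutoffs, dtype=float)
    if events.empty:
        return np.zeros(len(candidates))
    hcw = events["hcw_id"].to_numpy()
    pat = events["patient_id"].to_numpy()
    ts = events["timestamp"].to_numpy(dtype="datetime64[ns]")
    new_group = np.ones(len(events), dtype=bool)
    new_group[1:] = (hcw[1:] != hcw[:-1]) | (pat[1:] != pat[:-1])
    n_groups = int(new_group.sum())
    gaps = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
    gaps = np.sort(gaps[~new_group[1:]])
    # gaps strictly greater than c: total - count(gap <= c)
    exceed = len(gaps) - np.searchsorted(gaps, candidates, side="right")
    return n_groups + exceed


def cutoff_curve(
    events: pd.DataFrame,
    candidate_cutoffs: np.ndarray = DEFAULT_CANDIDATE_CUTOFFS,
    smoothing: int = 5,
) -> KneeCurve:
    """Interval-count-versus-cutoff curve with its knee, for inspection."""
    x = np.asarray(candidate_cutoffs, dtype=float)
    y = interval_count_curve(events, x)
    knee = knee_point(x, y, smoothing=smoothing)
    ys = _moving_average(y, smoothing if smoothing % 2 else smoothing + 1)
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (ys - ys.min()) / np.ptp(ys) if np.ptp(ys) else ys * 0.0
    if len(yn) and yn[-1] < yn[0]:
        yn = 1.0 - yn
    return KneeCurve(x=x, y=y, knee=knee, difference=yn - xn)


def estimate_cutoff(
    events: pd.DataFrame,
    candidate_cutoffs: np.ndarray = DEFAULT_CANDIDATE_CUTOFFS,
    smoothing: int = 5,
) -> float:
    """Gap cutoff (seconds) at the knee of the interval-count curve."""
    return cutoff_curve(events, candidate_cutoffs, smoothing=smoothing).knee


def split_durations_by_day(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-(interval, calendar day) seconds of activity.

    Intervals crossing midnight contribute their duration split
    proportionally to each day they touch. Returns columns
    ``interval``, ``hcw_id``, ``date``, ``seconds``, ``concurrent`` (the
    last only if present on the input).
    """
    has_label = "concurrent" in intervals.columns
    start = pd.to_datetime(intervals["start"])
    stop = pd.to_datetime(intervals["stop"])
    same_day = stop <= start.dt.normalize() + pd.Timedelta(days=1)

    base = pd.DataFrame(
        {
            "interval": intervals.index[same_day],
            "hcw_id": intervals.loc[same_day, "hcw_id"].to_numpy(),
            "date": start[same_day].dt.date.to_numpy(),
            "seconds": (stop[same_day] - start[same_day]).dt.total_seconds().to_numpy(),
        }
    )
    if has_label:
        base["concurrent"] = intervals.loc[same_day, "concurrent"].to_numpy()

    rows: list[tuple] = []
    for idx in intervals.index[~same_day]:
        r = intervals.loc[idx]
        s, e = pd.Timestamp(r["start"]), pd.Timestamp(r["stop"])
        label = bool(r["concurrent"]) if has_label else None
        day = s.normalize()
        while True:
            day_end = day + pd.Timedelta(days=1)
            seg = (min(e, day_end) - max(s, day)).total_seconds()
            rows.append((idx, r["hcw_id"], day.date(), seg, label))
            if e <= day_end:
                break
            day = day_end
    if not rows:
        return base
    cols = ["interval", "hcw_id", "date", "seconds", "concurrent"]
    extra = pd.DataFrame(rows, columns=cols)
    if not has_label:
        extra = extra.drop(columns="concurrent")
    if base.empty:
        return extra
    return pd.concat([base, extra], ignore_index=True)


def flag_workdays(
    intervals: pd.DataFrame, workday_cutoff_min: float = DEFAULT_WORKDAY_CUTOFF_MIN
) -> pd.DataFrame:
    """One record per (HCW, calendar day) with any interval activity.

    ``ehr_time_min`` sums that HCW's interval durations on the day (midnight
    crossers split proportionally); ``active`` is True when it reaches the
    workday cutoff (minutes).
    """
    if workday_cutoff_min <= 0:
        raise ValueError("workday_cutoff_min must be positive")
    if intervals.empty:
        return pd.DataFrame(columns=["hcw_id", "date", "ehr_time_min", "active"])
    per_day = split_durations_by_day(intervals)
    out = (
        per_day.groupby(["hcw_id", "date"], sort=True)["seconds"]
        .sum()
        .reset_index()
    )
    out["ehr_time_min"] = out.pop("seconds") / 60.0
    out["active"] = out["ehr_time_min"] >= workday_cutoff_min
    return out
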
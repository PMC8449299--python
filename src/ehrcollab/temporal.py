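"""Hourly profiles of concurrent EHR activity around admission and discharge.

For each patient three stay phases are anchored on the visit metadata: the
24 hours after admission, the 24 hours before discharge, and the calendar
day(s) around the stay midpoint. Patients are grouped by whether the anchor
falls on a weekday or a weekend (Saturday/Sunday, log-local calendar), and a
*temporal pattern* is the 24-slot vector of mean concurrent-interval counts
per patient per hour. Hour slots are offsets from the anchor
(hours-since-window-start), not clock hours; an interval lands in the slot
containing its start time (``attribute="overlap"`` instead prorates by
overlap seconds with each slot).

Pattern comparison uses the Wilcoxon rank-sum test on the two 24-value
sequences (purely order-based) and a Welch t-test on their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PHASES = ("admission", "discharge", "intermediate")


def _day_type(ts: pd.Timestamp) -> str:
    return "weekend" if ts.dayofweek >= 5 else "weekday"


def phase_windows(
    visits: pd.DataFrame, phase: str, mid_days: int = 0
) -> tuple[pd.DataFrame, int]:
    """Per-patient anchored time window for a stay phase.

    admission → ``[admission, admission + 24 h)``; discharge →
    ``[discharge − 24 h, discharge)``; intermediate → the full calendar day
    containing the stay midpoint, widened by ``mid_days`` on each side.
    Stays shorter than 24 h are excluded from the admission/discharge
    phases; the excluded count is returned alongside.

    Returns columns ``patient_id, window_start, window_end, day_type``
    (day type of the anchoring event or midpoint day).
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    rows = []
    excluded = 0
    day = pd.Timedelta(days=1)
    for _, r in visits.iterrows():
        adm, dis = r["admission"], r["discharge"]
        if phase in ("admission", "discharge") and dis - adm < day:
            excluded += 1
            continue
        if phase == "admission":
            start, end, anchor = adm, adm + day, adm
        elif phase == "discharge":
            start, end, anchor = dis - day, dis, dis
        else:
            mid = adm + (dis - adm) / 2
            start = mid.normalize() - mid_days * day
            end = mid.normalize() + (mid_days + 1) * day
            anchor = mid
        rows.append(
            {
                "patient_id": r["patient_id"],
                "window_start": start,
                "window_end": end,
                "day_type": _day_type(anchor),
            }
        )
    return (
        pd.DataFrame(rows, columns=["patient_id", "window_start", "window_end", "day_type"]),
        excluded,
    )


@dataclass
class TemporalPattern:
    """24-slot hourly profile of mean concurrent-interval counts for a
    patient group (``mean_counts[h]`` averages over the group's patients,
    zero-activity patients included)."""

    label: str
    mean_counts: np.ndarray = field(default_factory=lambda: np.zeros(24))
    n_patients: int = 0
    total_intervals: int = 0

    @property
    def hourly_mean(self) -> float:
        return float(np.mean(self.mean_counts))


def hourly_pattern(
    labeled: pd.DataFrame,
    windows: pd.DataFrame,
    day_type: str,
    label: str | None = None,
    attribute: str = "start",
) -> TemporalPattern:
    """Temporal pattern for the patients whose window anchor falls on
    ``day_type`` (``"weekday"`` or ``"weekend"``).

    ``labeled`` must carry the ``concurrent`` flag; only concurrent
    intervals are counted. Slot ``h`` covers hours ``[h, h+1)`` after the
    window start (wrapping mod 24 for multi-day intermediate windows). With
    ``attribute="overlap"`` an interval contributes to each slot its
    fractional overlap in hours instead of one count at its start slot.
    """
    grp = windows[windows["day_type"] == day_type]
    label = label or day_type
    if grp.empty:
        return TemporalPattern(label=label)
    conc = labeled[labeled["concurrent"]] if "concurrent" in labeled.columns else labeled
    counts = np.zeros((len(grp), 24))
    total = 0
    for i, (_, w) in enumerate(grp.iterrows()):
        sub = conc[conc["patient_id"] == w["patient_id"]]
        if sub.empty:
            continue
        if attribute == "start":
            sel = sub[
                (sub["start"] >= w["window_start"]) & (sub["start"] < w["window_end"])
            ]
            offs = (
                (sel["start"] - w["window_start"]).dt.total_seconds().to_numpy() // 3600
            ).astype(int) % 24
            np.add.at(counts[i], offs, 1.0)
            total += len(sel)
        elif attribute == "overlap":
            w0 = w["window_start"].value / 1e9
            w1 = w["window_end"].value / 1e9
            s = sub["start"].astype("int64").to_numpy() / 1e9
            e = sub["stop"].astype("int64").to_numpy() / 1e9
            keep = (e > w0) & (s < w1)
            for a, b in zip(np.maximum(s[keep], w0), np.minimum(e[keep], w1)):
                total += 1
                h0 = int((a - w0) // 3600)
                h1 = int(np.ceil((b - w0) / 3600))
                for h in range(h0, max(h1, h0 + 1)):
                    lo = w0 + h * 3600
                    counts[i, h % 24] += max(
                        0.0, (min(b, lo + 3600) - max(a, lo)) / 3600.0
                    )
        else:
            raise ValueError("attribute must be 'start' or 'overlap'")
    return TemporalPattern(
        label=label,
        mean_counts=counts.mean(axis=0),
        n_patients=len(grp),
        total_intervals=total,
    )


@dataclass
class PatternComparison:
    wilcoxon_stat: float
    wilcoxon_p: float
    t_stat: float
    t_p: float
    mean_a: float
    mean_b: float


def compare_patterns(a: TemporalPattern, b: TemporalPattern) -> PatternComparison:
    """Wilcoxon rank-sum and Welch t-test between two 24-slot patterns.

    Identical patterns (including identical constants) report p = 1 for
    both tests rather than NaN.
    """
    xa, xb = np.asarray(a.mean_counts), np.asarray(b.mean_counts)
    if len(xa) != 24 or len(xb) != 24:
        raise ValueError("patterns must have exactly 24 hourly slots")
    if np.array_equal(xa, xb):
        return PatternComparison(0.0, 1.0, 0.0, 1.0, xa.mean(), xb.mean())
    ws, wp = stats.ranksums(xa, xb)
    ts, tp = stats.ttest_ind(xa, xb, equal_var=False)
    if np.isnan(tp):  # zero variance in both but unequal means
        ts, tp = np.inf, 0.0
    return PatternComparison(
        float(ws), float(wp), float(ts), float(tp), float(xa.mean()), float(xb.mean())
    )
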
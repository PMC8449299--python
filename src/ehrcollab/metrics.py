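"""Concurrent-intensity metrics and specialty-level comparisons.

The *concurrent intensity* of an HCW on a day has two parts: the proportion
of that day's intervals that are concurrent, and the proportion of that
day's EHR time spent in concurrent intervals (a concurrent interval
contributes its full duration — partial overlap is not prorated). Intensity
is measured per active EHR workday only; inactive days are excluded.

Specialty summaries are two-stage: per-HCW means over days first, then the
specialty mean and 95% t-interval over its HCWs, so HCWs with many workdays
do not dominate. Comparisons delegate to standard routines: one-way ANOVA
across specialties and, within each specialty, a Spearman rank correlation
between daily EHR time and daily concurrent time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ehrcollab.sessionize import split_durations_by_day

INTENSITY_COLUMNS = (
    "hcw_id",
    "date",
    "n_intervals",
    "n_concurrent",
    "n_actions",
    "ehr_time_min",
    "concurrent_time_min",
    "prop_intervals",
    "prop_time",
)

_METRICS = ("ehr_time_min", "n_actions", "prop_intervals", "prop_time")


class IntensityConsistencyError(RuntimeError):
    """An active workday with zero EHR time contradicts the workday cutoff."""


def compute_intensity(labeled: pd.DataFrame, workdays: pd.DataFrame) -> pd.DataFrame:
    """Per-(HCW, active day) concurrent-intensity records.

    Midnight-crossing intervals contribute time to each day proportionally
    (matching the workday accounting, so summed ``ehr_time_min`` agrees with
    the workday table) and are counted once per day they touch; their
    actions are attributed to the start day.
    """
    active = workdays[workdays["active"]]
    if active.empty or labeled.empty:
        return pd.DataFrame(columns=list(INTENSITY_COLUMNS))
    per_day = split_durations_by_day(labeled)
    grp = per_day.groupby(["hcw_id", "date"], sort=True)
    agg = grp.agg(
        n_intervals=("interval", "size"),
        n_concurrent=("concurrent", "sum"),
        ehr_time_min=("seconds", "sum"),
    ).reset_index()
    agg["ehr_time_min"] /= 60.0
    conc_time = (
        per_day[per_day["concurrent"]]
        .groupby(["hcw_id", "date"])["seconds"]
        .sum()
        / 60.0
    ).rename("concurrent_time_min")
    agg = agg.merge(conc_time, on=["hcw_id", "date"], how="left")
    agg["concurrent_time_min"] = agg["concurrent_time_min"].fillna(0.0)

    actions = (
        labeled.assign(date=pd.to_datetime(labeled["start"]).dt.date)
        .groupby(["hcw_id", "date"])["n_events"]
        .sum()
        .rename("n_actions")
    )
    agg = agg.merge(actions, on=["hcw_id", "date"], how="left")
    agg["n_actions"] = agg["n_actions"].fillna(0).astype(int)

    out = agg.merge(active[["hcw_id", "date"]], on=["hcw_id", "date"], how="inner")
    if (out["ehr_time_min"] <= 0).any():
        raise IntensityConsistencyError(
            "active workday with zero EHR time; workday flags inconsistent"
        )
    out["n_concurrent"] = out["n_concurrent"].astype(int)
    out["prop_intervals"] = out["n_concurrent"] / out["n_intervals"]
    out["prop_time"] = out["concurrent_time_min"] / out["ehr_time_min"]
    return out[list(INTENSITY_COLUMNS)]


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return (np.nan, np.nan)
    m = values.mean()
    se = values.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * se
    return (m - half, m + half)


def per_hcw_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean of each intensity metric over an HCW's active days."""
    return (
        records.groupby("hcw_id")[list(_METRICS)].mean().reset_index()
    )


def summarize_by_specialty(
    records: pd.DataFrame, hcw_meta: pd.DataFrame, top_k: int = 13
) -> pd.DataFrame:
    """Specialty-level mean and 95% CI for EHR time, actions/day, and both
    intensity proportions, ranked by mean EHR time (top ``top_k`` kept).

    CIs use t-quantiles over per-HCW means; a specialty with a single HCW
    reports NaN bounds.
    """
    hcw = per_hcw_means(records).merge(
        hcw_meta[["hcw_id", "specialty"]], on="hcw_id", how="inner"
    )
    if hcw.empty:
        raise ValueError("no intensity records join the HCW metadata")
    rows = []
    for spec, grp in hcw.groupby("specialty"):
        row: dict = {"specialty": spec, "n_hcws": len(grp)}
        for m in _METRICS:
            vals = grp[m].to_numpy()
            lo, hi = _t_ci(vals)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_ci_low"] = lo
            row[f"{m}_ci_high"] = hi
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        "ehr_time_min_mean", ascending=False, kind="stable"
    )
    return out.head(top_k).reset_index(drop=True)


@dataclass
class AnovaResult:
    metric: str
    f_stat: float
    p_value: float
    significant: bool
    note: str = ""


@dataclass
class SpearmanResult:
    specialty: str
    rho: float
    p_value: float
    n_days: int
    significant: bool


@dataclass
class SpecialtyComparison:
    """One-way ANOVA per metric across specialties (per-HCW means as
    observations) and per-specialty Spearman association between daily EHR
    time and daily concurrent time."""

    anova: list[AnovaResult]
    spearman: list[SpearmanResult]


def compare_specialties(
    records: pd.DataFrame, hcw_meta: pd.DataFrame, alpha: float = 0.05
) -> SpecialtyComparison:
    hcw = per_hcw_means(records).merge(
        hcw_meta[["hcw_id", "specialty"]], on="hcw_id", how="inner"
    )
    sizes = hcw.groupby("specialty").size()
    eligible = sizes[sizes >= 2].index
    if len(eligible) < 2:
        raise ValueError("need >=2 specialties with >=2 HCWs each")
    hcw = hcw[hcw["specialty"].isin(eligible)]

    anova = []
    for m in ("ehr_time_min", "prop_intervals", "prop_time"):
        groups = [g[m].to_numpy() for _, g in hcw.groupby("specialty")]
        if all(np.allclose(g, g.mean()) for g in groups):
            anova.append(
                AnovaResult(m, np.nan, np.nan, False, "degenerate within-group variance")
            )
            continue
        f, p = stats.f_oneway(*groups)
        anova.append(AnovaResult(m, float(f), float(p), bool(p < alpha)))

    daily = records.merge(
        hcw_meta[["hcw_id", "specialty"]], on="hcw_id", how="inner"
    )
    spearman = []
    for spec, grp in daily.groupby("specialty"):
        if spec not in set(eligible) or len(grp) < 3:
            continue
        x = grp["ehr_time_min"].to_numpy()
        y = grp["concurrent_time_min"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            spearman.append(SpearmanResult(spec, np.nan, np.nan, len(grp), False))
            continue
        rho, p = stats.spearmanr(x, y)
        spearman.append(
            SpearmanResult(spec, float(rho), float(p), len(grp), bool(p < alpha))
        )
    return SpecialtyComparison(anova=anova, spearman=spearman)
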
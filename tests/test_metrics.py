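import numpy as np
import pandas as pd
import pytest

from ehrcollab import metrics, sessionize
from ehrcollab.metrics import (
    compare_specialties,
    compute_intensity,
    summarize_by_specialty,
)


def labeled_intervals(rows):
    """rows: (hcw, start, stop, concurrent)."""
    df = pd.DataFrame(rows, columns=["hcw_id", "start", "stop", "concurrent"])
    df["patient_id"] = "P"
    df["start"] = pd.to_datetime(df["start"])
    df["stop"] = pd.to_datetime(df["stop"])
    df["duration_s"] = (df["stop"] - df["start"]).dt.total_seconds()
    df["n_events"] = 3
    df["session_id"] = np.where(df["concurrent"], "S", None)
    return df


def records_frame(spec_props, n_hcws=30, n_days=5, sd=0.05, seed=0):
    """Synthetic intensity records with planted per-specialty prop_time."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for si, (spec, prop) in enumerate(spec_props.items()):
        for h in range(n_hcws):
            hid = f"{spec}-{h}"
            meta.append({"hcw_id": hid, "specialty": spec, "role": "nurse"})
            for d in range(n_days):
                p = float(np.clip(prop + rng.normal(0, sd), 0, 1))
                ehr = 40 + rng.normal(0, 5)
                rows.append(
                    {
                        "hcw_id": hid,
                        "date": pd.Timestamp("2020-01-06") + pd.Timedelta(days=d),
                        "n_intervals": 10,
                        "n_concurrent": int(round(10 * p)),
                        "n_actions": 50,
                        "ehr_time_min": ehr,
                        "concurrent_time_min": ehr * p,
                        "prop_intervals": p,
                        "prop_time": p,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(meta)


class TestComputeIntensity:
    def test_quarter_concurrent_day(self):
        iv = labeled_intervals(
            [
                ("H", "2020-01-06 08:00", "2020-01-06 08:10", True),
                ("H", "2020-01-06 09:00", "2020-01-06 09:10", False),
                ("H", "2020-01-06 10:00", "2020-01-06 10:10", False),
                ("H", "2020-01-06 11:00", "2020-01-06 11:10", False),
            ]
        )
        wd = sessionize.flag_workdays(iv, 15)
        rec = compute_intensity(iv, wd)
        assert len(rec) == 1
        assert rec.loc[0, "prop_intervals"] == 0.25
        assert rec.loc[0, "prop_time"] == 0.25

    @pytest.mark.parametrize("flag,expect", [(True, 1.0), (False, 0.0)])
    def test_all_or_none_concurrent(self, flag, expect):
        iv = labeled_intervals(
            [
                ("H", "2020-01-06 08:00", "2020-01-06 08:10", flag),
                ("H", "2020-01-06 09:00", "2020-01-06 09:10", flag),
            ]
        )
        rec = compute_intensity(iv, sessionize.flag_workdays(iv, 15))
        assert rec.loc[0, "prop_intervals"] == expect
        assert rec.loc[0, "prop_time"] == expect

    def test_inactive_days_excluded(self):
        iv = labeled_intervals(
            [("H", "2020-01-06 08:00", "2020-01-06 08:05", True)]
        )
        rec = compute_intensity(iv, sessionize.flag_workdays(iv, 15))
        assert len(rec) == 0

    def test_ehr_time_matches_workday_accounting(self, pipe_default):
        rec = pipe_default.intensity
        wd = pipe_default.workdays.set_index(["hcw_id", "date"])
        for _, r in rec.head(50).iterrows():
            assert r["ehr_time_min"] == pytest.approx(
                wd.loc[(r["hcw_id"], r["date"]), "ehr_time_min"]
            )

    def test_invariant_to_id_relabeling(self):
        iv = labeled_intervals(
            [
                ("H", "2020-01-06 08:00", "2020-01-06 08:20", True),
                ("H", "2020-01-06 09:00", "2020-01-06 09:20", False),
            ]
        )
        renamed = iv.assign(hcw_id="ZZZ", patient_id="Q")
        a = compute_intensity(iv, sessionize.flag_workdays(iv, 15))
        b = compute_intensity(renamed, sessionize.flag_workdays(renamed, 15))
        for col in ("prop_intervals", "prop_time", "ehr_time_min"):
            assert list(a[col]) == list(b[col])


class TestSummaries:
    def test_two_hcw_specialty_mean(self):
        rec, meta = records_frame({"nicu-rn": 0.5}, n_hcws=2, sd=0.0)
        rec.loc[rec["hcw_id"] == "nicu-rn-0", "prop_time"] = 0.4
        rec.loc[rec["hcw_id"] == "nicu-rn-1", "prop_time"] = 0.6
        out = summarize_by_specialty(rec, meta)
        assert out.loc[0, "prop_time_mean"] == pytest.approx(0.5)

    def test_top_k_keeps_highest_ehr_time(self):
        rec, meta = records_frame({"a": 0.2, "b": 0.2}, n_hcws=3, sd=0.0)
        rec.loc[rec["hcw_id"].str.startswith("b"), "ehr_time_min"] += 100
        out = summarize_by_specialty(rec, meta, top_k=1)
        assert list(out["specialty"]) == ["b"]

    def test_single_hcw_specialty_has_no_ci(self):
        rec, meta = records_frame({"solo": 0.3}, n_hcws=1)
        out = summarize_by_specialty(rec, meta)
        assert np.isnan(out.loc[0, "prop_time_ci_low"])

    def test_planted_prop_time_recovered_within_ci(self):
        rec, meta = records_frame({"ecmo": 0.7}, n_hcws=25, seed=3)
        out = summarize_by_specialty(rec, meta)
        assert out.loc[0, "prop_time_ci_low"] <= 0.7 <= out.loc[0, "prop_time_ci_high"]


class TestComparisons:
    def test_identical_specialties_give_null_anova(self):
        rec, meta = records_frame({"a": 0.4, "b": 0.4}, n_hcws=10, sd=0.05, seed=1)
        # force identical per-HCW mean patterns across the two specialties
        a_vals = rec[rec["hcw_id"].str.startswith("a")]["prop_time"].to_numpy()
        rec.loc[rec["hcw_id"].str.startswith("b"), "prop_time"] = a_vals
        cmp = compare_specialties(rec, meta)
        res = {a.metric: a for a in cmp.anova}
        assert res["prop_time"].f_stat == pytest.approx(0.0, abs=1e-12)
        assert res["prop_time"].p_value == pytest.approx(1.0)

    def test_planted_gap_detected(self):
        rec, meta = records_frame({"lo": 0.1, "hi": 0.7}, n_hcws=30, sd=0.05, seed=2)
        cmp = compare_specialties(rec, meta)
        res = {a.metric: a for a in cmp.anova}
        assert res["prop_time"].p_value < 1e-3
        assert res["prop_time"].significant

    def test_monotone_association_gives_unit_rho(self):
        rec, meta = records_frame({"a": 0.5, "b": 0.5}, n_hcws=3, n_days=8, seed=4)
        rec["concurrent_time_min"] = rec["ehr_time_min"] * 0.5
        cmp = compare_specialties(rec, meta)
        assert all(s.rho == pytest.approx(1.0) for s in cmp.spearman)

    def test_too_few_groups_rejected(self):
        rec, meta = records_frame({"a": 0.5}, n_hcws=3)
        with pytest.raises(ValueError, match="specialties"):
            compare_specialties(rec, meta)
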
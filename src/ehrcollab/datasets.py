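"""Small bundled worked-example datasets.

Two tiny tables used throughout the documentation and tests: a dozen
example audit-log rows (two HCWs, two patients, Epic-style action labels)
for the sessionization walk-through, and the 12 role-pair mean Likert
ratings from a NICU expert survey that validates EHR-derived collaboration
likelihoods (six relationships each of high and low EHR-derived likelihood,
rated 1–5 by a 13-expert panel and averaged per relationship).
"""

from __future__ import annotations

import pandas as pd

from ehrcollab.audit_log import events_from_records


def example_audit_events() -> pd.DataFrame:
    """Twelve example audit-log events: two HCWs, two patients.

    HCW A's six events on patient 1 contain one between-task gap of a few
    minutes, so a 120 s cutoff splits them into two intervals; HCW B's six
    events on patient 2 are evenly spaced under the cutoff and form one
    eight-minute interval.
    """
    rows = [
        ("A", "1", "FLOWSHEETS DATA SAVED", "2020-04-05 02:14:25"),
        ("A", "1", "CHART REVIEW ENCOUNTERS TAB SELECTED", "2020-04-05 02:15:00"),
        ("A", "1", "CHART REVIEW OTHER ORDERS TAB SELECTED", "2020-04-05 02:18:23"),
        ("A", "1", "HISTORY ACTIVITY ACCESSED", "2020-04-05 02:19:53"),
        ("A", "1", "FLOWSHEETS DATA COPIED FORWARD", "2020-04-05 02:21:32"),
        ("A", "1", "CHART REVIEW MEDICATIONS TAB SELECTED", "2020-04-05 02:22:23"),
        ("B", "2", "VISIT NAVIGATOR TEMPLATE LOADED", "2020-12-03 06:31:27"),
        ("B", "2", "SNAPSHOT REPORT VIEWED", "2020-12-03 06:33:11"),
        ("B", "2", "CHART REVIEW NOTES", "2020-12-03 06:34:41"),
        ("B", "2", "CHART REVIEW ENCOUNTER", "2020-12-03 06:36:27"),
        ("B", "2", "CHART REVIEW RESULTS", "2020-12-03 06:37:33"),
        ("B", "2", "CHART REVIEW OTHER ORDERS", "2020-12-03 06:39:27"),
    ]
    return events_from_records(rows)


def example_survey_scores() -> pd.DataFrame:
    """Mean Likert ratings of 12 role-pair collaborative relationships.

    Each row is one surveyed relationship: the panel-mean 1–5 rating of how
    likely the two roles are to interact through the EHR, with the
    EHR-derived likelihood label raters were blind to. Suitable as
    single-observation input to
    :func:`ehrcollab.survey.fit_likelihood_model`.
    """
    rows = [
        ("R01", "frontline provider <-> consultant", "high", 3.85),
        ("R02", "ancillary staff <-> consultant", "high", 2.23),
        ("R03", "nurse <-> consultant", "high", 4.46),
        ("R04", "frontline provider <-> ancillary staff", "high", 4.08),
        ("R05", "ancillary staff <-> nurse", "high", 3.46),
        ("R06", "support staff <-> nurse", "high", 3.15),
        ("R07", "frontline provider <-> neonatologist", "low", 3.15),
        ("R08", "ancillary staff <-> support staff", "low", 2.07),
        ("R09", "nurse <-> fellow", "low", 3.07),
        ("R10", "frontline provider <-> fellow", "low", 2.84),
        ("R11", "ancillary staff <-> fellow", "low", 3.07),
        ("R12", "support staff <-> fellow", "low", 1.69),
    ]
    df = pd.DataFrame(
        rows, columns=["relationship_id", "relationship", "label", "likert"]
    )
    df["respondent_id"] = "panel-mean"
    return df[["respondent_id", "relationship_id", "relationship", "label", "likert"]]
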
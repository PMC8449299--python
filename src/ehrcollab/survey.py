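"""Likert-survey validation of inferred collaborative relationships.

Experts rate, on a 1–5 Likert scale, how likely two roles are to interact
through the EHR; they are blind to the EHR-derived label (high or low
collaboration likelihood). The discrimination model is a linear regression
of the Likert score on the 0/1 label indicator:

    likert = alpha + theta * beta,   theta in {0 (low), 1 (high)}

so alpha is exactly the low-group mean, alpha + beta exactly the high-group
mean, and an ANOVA F-test of beta != 0 (equivalently the squared t-test)
decides whether raters distinguish the two groups. Observations are
individual responses; respondent clustering is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RESPONSE_COLUMNS = ("respondent_id", "relationship_id", "label", "likert")


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read survey responses (``respondent_id, relationship_id, label,
    likert``); validates labels and the 1–5 Likert range."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "relationship_id": str})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file missing columns: {missing}")
    validate_responses(df)
    return df


def validate_responses(responses: pd.DataFrame) -> None:
    if not responses["label"].isin(["high", "low"]).all():
        raise ValueError("labels must be 'high' or 'low'")
    likert = responses["likert"]
    if not ((likert >= 1) & (likert <= 5)).all():
        raise ValueError("likert scores must be in 1..5")


@dataclass
class LikelihoodModelFit:
    """Fit of the label-discrimination regression.

    ``alpha`` equals the low-group mean and ``alpha + beta`` the high-group
    mean by construction; ``p_value`` is the ANOVA F-test of beta != 0
    (equal to the squared-t test for this single-predictor model).
    """

    alpha: float
    beta: float
    f_stat: float
    t_stat: float
    p_value: float
    significant: bool
    group_means: dict[str, float]
    group_cis: dict[str, tuple[float, float]]
    n: dict[str, int]


def _group_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    if n < 2:
        return (np.nan, np.nan)
    m, se = values.mean(), values.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * se
    return (float(m - half), float(m + half))


def fit_likelihood_model(
    responses: pd.DataFrame, alpha_level: float = 0.05
) -> LikelihoodModelFit:
    """Least-squares fit of Likert score on the high/low label.

    Requires at least two responses per label. Degenerate data (all scores
    equal) reports beta = 0 with p = 1.
    """
    validate_responses(responses)
    counts = responses["label"].value_counts()
    for lab in ("high", "low"):
        if counts.get(lab, 0) < 2:
            raise ValueError(f"need >=2 responses with label {lab!r}")
    y = responses["likert"].to_numpy(dtype=float)
    theta = (responses["label"] == "high").to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(theta)).fit()
    a, b = model.params
    f_stat, t_stat = float(model.fvalue), float(model.tvalues[1])
    p = float(model.f_pvalue)
    if np.ptp(y) == 0:
        f_stat, t_stat, p = 0.0, 0.0, 1.0
        b = 0.0
    lo = y[theta == 0]
    hi = y[theta == 1]
    return LikelihoodModelFit(
        alpha=float(a),
        beta=float(b),
        f_stat=f_stat,
        t_stat=t_stat,
        p_value=p,
        significant=bool(p < alpha_level),
        group_means={"low": float(lo.mean()), "high": float(hi.mean())},
        group_cis={"low": _group_ci(lo), "high": _group_ci(hi)},
        n={"low": int(len(lo)), "high": int(len(hi))},
    )


def summarize_survey(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean Likert score per relationship, with its label and response
    count (high-likelihood relationships first, then by relationship ID)."""
    validate_responses(responses)
    out = (
        responses.groupby(["relationship_id", "label"])["likert"]
        .agg(mean_likert="mean", n="size")
        .reset_index()
    )
    out["_ord"] = (out["label"] == "low").astype(int)
    out = out.sort_values(["_ord", "relationship_id"], kind="stable").drop(columns="_ord")
    return out.reset_index(drop=True)
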
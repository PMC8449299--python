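"""Synthetic audit-log generator with planted ground truth.

The generator emulates the statistical structure of intensive-care EHR
audit logs — not their clinical content — so that every pipeline stage can
be validated without protected health information:

* multiple HCWs act on each patient's record;
* per-HCW event streams are bursty, with within-burst inter-event gaps on a
  seconds-to-minutes scale and between-burst gaps an order of magnitude
  larger (a work bout may continue with follow-up bursts after a long gap),
  giving the bimodal gap distribution sessionization exploits;
* *planted teams* of HCWs act on their shared patients in overlapping time
  windows with a configurable propensity — the ground truth for
  collaboration-network recovery;
* weekday activity outpaces weekend activity by a configurable rate ratio;
* each patient has an admission/discharge span;
* each burst draws its actions from one of a fixed set of action templates,
  and all member bursts of one team bout share a template, so concurrent
  sessions are action-homogeneous by construction.

All randomness flows from a single seeded generator; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ehrcollab.audit_log import ROLES, sort_events

#: Plausible staffing mix for an intensive-care unit.
DEFAULT_ROLE_PROPORTIONS = {
    "nurse": 0.40,
    "frontline provider": 0.15,
    "respiratory therapist": 0.10,
    "neonatologist": 0.08,
    "fellow": 0.07,
    "consultant": 0.08,
    "ancillary staff": 0.07,
    "support staff": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic audit log.

    Defaults describe a two-week window of a small intensive-care unit:
    bursty activity with 30 s within-burst and 20 min between-burst gap
    scales, planted two-person teams that work concurrently on shared
    patients 90% of the time, and a 20:1 weekday:weekend activity ratio.
    """

    n_hcws: int = 40
    n_patients: int = 12
    n_days: int = 14
    start_date: str = "2020-03-02"  # a Monday
    role_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_PROPORTIONS)
    )
    specialties_per_role: int = 2
    n_teams: int = 4
    team_size: int = 2
    team_propensity: float = 0.9
    within_gap_s: float = 30.0
    between_gap_s: float = 1200.0
    events_per_burst_mean: float = 6.0
    follow_up_prob: float = 0.35
    team_bursts_per_patient_day: float = 3.0
    solo_bursts_per_hcw_patient_day: float = 1.0
    weekday_rate: float = 1.0
    weekend_rate: float = 0.05
    mean_stay_days: float = 6.0
    hcws_per_patient: int = 6
    n_actions: int = 60
    n_templates: int = 8
    actions_per_template: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_teams * self.team_size > self.n_hcws:
            raise ValueError("planted teams need more HCWs than n_hcws provides")
        if not 0 <= self.team_propensity <= 1:
            raise ValueError("team_propensity must be in [0, 1]")
        for name in (
            "within_gap_s",
            "between_gap_s",
            "weekday_rate",
            "weekend_rate",
            "team_bursts_per_patient_day",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    teams: list[tuple[str, ...]]
    team_pairs: list[tuple[str, str]]
    bursts: pd.DataFrame  # burst_id, hcw_id, patient_id, t0_s, template, concurrent_planned
    visits: pd.DataFrame
    config: SimConfig


@dataclass
class SimResult:
    events: pd.DataFrame
    hcw_meta: pd.DataFrame
    visits: pd.DataFrame
    truth: GroundTruth


def _make_templates(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Each template concentrates probability on its own small action set."""
    templates = np.full((cfg.n_templates, cfg.n_actions), 0.02 / cfg.n_actions)
    for t in range(cfg.n_templates):
        chosen = rng.choice(cfg.n_actions, size=cfg.actions_per_template, replace=False)
        templates[t, chosen] += rng.dirichlet(np.ones(cfg.actions_per_template)) * 0.98
    return templates / templates.sum(axis=1, keepdims=True)


def generate(config: SimConfig) -> SimResult:
    """Generate (events, hcw_meta, visits, ground truth) for one run."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_date)

    # --- HCWs, roles, specialties -------------------------------------
    roles = list(cfg.role_proportions) or list(ROLES)
    props = np.array([cfg.role_proportions[r] for r in roles], dtype=float)
    props = props / props.sum()
    hcw_ids = [f"H{i:03d}" for i in range(cfg.n_hcws)]
    hcw_roles = rng.choice(roles, size=cfg.n_hcws, p=props)
    hcw_spec = [
        f"{role}-{rng.integers(cfg.specialties_per_role)}" for role in hcw_roles
    ]
    hcw_meta = pd.DataFrame(
        {"hcw_id": hcw_ids, "specialty": hcw_spec, "role": hcw_roles}
    )

    # --- planted teams -------------------------------------------------
    pool = rng.permutation(cfg.n_hcws)
    teams = [
        tuple(hcw_ids[j] for j in pool[i * cfg.team_size : (i + 1) * cfg.team_size])
        for i in range(cfg.n_teams)
    ]
    team_pairs = sorted(
        {
            tuple(sorted((a, b)))
            for team in teams
            for i, a in enumerate(team)
            for b in team[i + 1 :]
        }
    )

    # --- visits ---------------------------------------------------------
    pat_ids = [f"P{i:03d}" for i in range(cfg.n_patients)]
    adm_day = rng.uniform(0, max(cfg.n_days * 0.5, 1.0), size=cfg.n_patients)
    stay = 2.0 + rng.exponential(max(cfg.mean_stay_days - 2.0, 0.5), cfg.n_patients)
    stay = np.minimum(stay, cfg.n_days - adm_day - 0.05)
    stay = np.maximum(stay, 1.5)
    adm_s = adm_day * 86400.0
    dis_s = (adm_day + stay) * 86400.0
    visits = pd.DataFrame(
        {
            "patient_id": pat_ids,
            "admission": start + pd.to_timedelta(np.floor(adm_s), unit="s"),
            "discharge": start + pd.to_timedelta(np.floor(dis_s), unit="s"),
        }
    )

    # --- patient staffing ----------------------------------------------
    team_of_patient = {p: teams[i % cfg.n_teams] for i, p in enumerate(pat_ids)}
    solo_of_patient: dict[str, list[str]] = {}
    for p in pat_ids:
        others = [h for h in hcw_ids if h not in team_of_patient[p]]
        n_solo = min(cfg.hcws_per_patient, len(others))
        solo_of_patient[p] = list(rng.choice(others, size=n_solo, replace=False))

    templates = _make_templates(rng, cfg)
    day_mult = np.array(
        [
            cfg.weekday_rate if (start + pd.Timedelta(days=d)).dayofweek < 5
            else cfg.weekend_rate
            for d in range(cfg.n_days)
        ]
    )

    ev_hcw: list[str] = []
    ev_pat: list[str] = []
    ev_act: list[int] = []
    ev_t: list[float] = []
    burst_rows: list[tuple] = []
    burst_id = 0

    def emit_bout(hcw: str, patient: str, t0: float, template: int, base_n: int,
                  planned: bool) -> None:
        """One burst plus geometric follow-up bursts after long gaps."""
        nonlocal burst_id
        t = t0
        n = base_n
        while True:
            gaps = rng.exponential(cfg.within_gap_s, size=n - 1) if n > 1 else []
            times = t + np.concatenate([[0.0], np.cumsum(gaps)]) if n > 1 else np.array([t])
            acts = rng.choice(cfg.n_actions, size=n, p=templates[template])
            ev_hcw.extend([hcw] * n)
            ev_pat.extend([patient] * n)
            ev_act.extend(acts.tolist())
            ev_t.extend(times.tolist())
            burst_rows.append((burst_id, hcw, patient, t, template, planned))
            burst_id += 1
            if rng.random() >= cfg.follow_up_prob:
                break
            t = times[-1] + rng.exponential(cfg.between_gap_s)
            n = 2 + rng.poisson(max(cfg.events_per_burst_mean - 2.0, 0.5))
            planned = False

    for pi, p in enumerate(pat_ids):
        a, d = adm_s[pi], dis_s[pi]
        d0, d1 = int(a // 86400), min(int(d // 86400) + 1, cfg.n_days)
        team = team_of_patient[p]
        for day in range(d0, d1):
            lo = max(a, day * 86400.0)
            hi = min(d, (day + 1) * 86400.0)
            if hi <= lo:
                continue
            mult = day_mult[day]
            # team bouts: members work the patient's record simultaneously
            for _ in range(rng.poisson(cfg.team_bursts_per_patient_day * mult)):
                t0 = rng.uniform(lo, hi)
                template = int(rng.integers(cfg.n_templates))
                base_n = 2 + rng.poisson(max(cfg.events_per_burst_mean - 2.0, 0.5))
                if rng.random() < cfg.team_propensity:
                    for h in team:
                        n = max(2, base_n + int(rng.integers(-1, 2)))
                        emit_bout(h, p, t0 + rng.uniform(0, cfg.within_gap_s),
                                  template, n, planned=True)
                else:
                    h = team[int(rng.integers(len(team)))]
                    emit_bout(h, p, t0, template, base_n, planned=False)
            # independent solo activity by the rest of the care team
            for h in solo_of_patient[p]:
                for _ in range(rng.poisson(cfg.solo_bursts_per_hcw_patient_day * mult)):
                    t0 = rng.uniform(lo, hi)
                    template = int(rng.integers(cfg.n_templates))
                    n = 2 + rng.poisson(max(cfg.events_per_burst_mean - 2.0, 0.5))
                    emit_bout(h, p, t0, template, n, planned=False)

    events = pd.DataFrame(
        {
            "hcw_id": ev_hcw,
            "patient_id": ev_pat,
            "action_id": [f"ACTION_{a:03d}" for a in ev_act],
            "timestamp": start + pd.to_timedelta(np.floor(np.array(ev_t)), unit="s"),
        }
    )
    events = sort_events(events)

    bursts = pd.DataFrame(
        burst_rows,
        columns=["burst_id", "hcw_id", "patient_id", "t0_s", "template",
                 "concurrent_planned"],
    )
    truth = GroundTruth(
        teams=teams,
        team_pairs=[tuple(p) for p in team_pairs],
        bursts=bursts,
        visits=visits,
        config=cfg,
    )
    return SimResult(events=events, hcw_meta=hcw_meta, visits=visits, truth=truth)


@dataclass
class RecoveryReport:
    """How well the pipeline recovered what the generator planted."""

    cutoff_s: float
    cutoff_in_range: bool
    edge_precision: float
    n_planted_pairs: int
    weekday_weekend_ratio: float
    single_cluster_fraction: float | None = None


def score_recovery(truth: GroundTruth, result) -> RecoveryReport:
    """Score a pipeline run against the generator's ground truth.

    ``result`` is a :class:`ehrcollab.pipeline.PipelineResult` produced from
    the same generated events (mismatched inputs raise).

    * cutoff: is the knee-estimated gap cutoff strictly between the
      generator's within- and between-burst gap scales;
    * edges: precision of the top-``|planted pairs|`` collaboration-graph
      edges (by weight, deterministic tie-break) against the planted pairs;
    * temporal: ratio of weekday to weekend hourly mean concurrent-interval
      counts on the intermediate-stay day.
    """
    from ehrcollab import temporal as temporal_mod

    cfg = truth.config
    if result.graph is not None:
        unknown = set(result.graph.nodes) - set(
            f"H{i:03d}" for i in range(cfg.n_hcws)
        )
        if unknown:
            raise ValueError(f"pipeline result does not match this run: {unknown}")

    cutoff_in = cfg.within_gap_s < result.cutoff_s < cfg.between_gap_s

    planted = {frozenset(p) for p in truth.team_pairs}
    precision = np.nan
    if result.graph is not None and result.graph.number_of_edges():
        edges = sorted(
            result.graph.edges(data="weight"),
            key=lambda e: (-e[2], e[0], e[1]),
        )[: len(planted)]
        hits = sum(frozenset((u, v)) in planted for u, v, _ in edges)
        precision = hits / len(planted)

    windows, _ = temporal_mod.phase_windows(truth.visits, "intermediate")
    wd = temporal_mod.hourly_pattern(result.labeled, windows, "weekday")
    we = temporal_mod.hourly_pattern(result.labeled, windows, "weekend")
    ratio = (
        wd.hourly_mean / we.hourly_mean
        if we.n_patients and wd.n_patients and we.hourly_mean > 0
        else np.nan
    )
    return RecoveryReport(
        cutoff_s=float(result.cutoff_s),
        cutoff_in_range=bool(cutoff_in),
        edge_precision=float(precision),
        n_planted_pairs=len(planted),
        weekday_weekend_ratio=float(ratio),
    )


def config_with(base: SimConfig | None = None, **overrides) -> SimConfig:
    """Convenience: a config derived from the defaults (or ``base``)."""
    return replace(base or SimConfig(), **overrides)
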
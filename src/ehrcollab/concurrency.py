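"""Concurrent-session detection and the intermediate data matrices.

A *concurrent session* is a set of temporally overlapping intervals on the
same patient's record by at least two distinct HCWs. Overlap must be
strictly positive (touching endpoints do not count), and a session is read
as a connected component of the pairwise-overlap graph: four intervals can
chain into one session without every pair overlapping. An alternative
``rule="clique"`` (greedy partition into mutually-overlapping groups) is
provided because the component reading, while the natural one, is an
interpretive choice. An *individual interval* is any interval in no session.

Pair detection is a per-patient sweep over start-sorted intervals
(O(n log n + k) for k overlapping pairs); within one HCW-patient stream
intervals never overlap by construction, but the same-patient requirement is
what keeps one HCW's wall-time-overlapping work on two patients from ever
forming a session.

From labeled intervals and sessions, :func:`build_matrices` assembles the
sparse intermediate matrices downstream analyses consume: concurrent
interval × action counts, interval × session and HCW × session/interval
indicators, plus duration-weighted variants of the HCW matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

PAIR_COLUMNS = ("interval_a", "interval_b", "overlap_s")
SESSION_COLUMNS = (
    "session_id",
    "patient_id",
    "start",
    "stop",
    "n_intervals",
    "n_hcws",
)


def find_overlap_pairs(intervals: pd.DataFrame) -> pd.DataFrame:
    """All pairs of positively overlapping same-patient, different-HCW intervals.

    Returns a frame with the two interval index labels (``interval_a`` <
    ``interval_b`` in start order) and the overlap in seconds
    (``min(stop) − max(start) > 0``).
    """
    out_a: list = []
    out_b: list = []
    out_ov: list = []
    if intervals.empty:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))
    for _, grp in intervals.groupby("patient_id", sort=False):
        starts_ts = grp["start"].to_numpy(dtype="datetime64[ns]")
        order = np.argsort(starts_ts, kind="stable")
        starts = starts_ts[order].astype("int64") / 1e9
        stops = grp["stop"].to_numpy(dtype="datetime64[ns]")[order].astype("int64") / 1e9
        idx = grp.index.to_numpy()[order]
        hcw = grp["hcw_id"].to_numpy()[order]
        # candidates j > i with start_j < stop_i
        ends = np.searchsorted(starts, stops, side="left")
        for i in range(len(starts)):
            hi = ends[i]
            if hi <= i + 1:
                continue
            js = np.arange(i + 1, hi)
            js = js[hcw[js] != hcw[i]]
            if js.size == 0:
                continue
            ov = np.minimum(stops[i], stops[js]) - starts[js]
            keep = ov > 0
            if keep.any():
                out_a.extend(idx[i] for _ in range(int(keep.sum())))
                out_b.extend(idx[js[keep]])
                out_ov.extend(ov[keep])
    return pd.DataFrame(
        {"interval_a": out_a, "interval_b": out_b, "overlap_s": out_ov}
    )


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = self.parent.setdefault(p, p)
            x = self.parent[x]
            p = self.parent.setdefault(x, x)
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def assemble_sessions(
    intervals: pd.DataFrame, pairs: pd.DataFrame, rule: str = "component"
) -> tuple[pd.DataFrame, pd.Series]:
    """Group overlapping intervals into concurrent sessions.

    Parameters
    ----------
    intervals:
        The full interval table (the session span and membership refer to
        its index labels).
    pairs:
        Output of :func:`find_overlap_pairs`.
    rule:
        ``"component"`` (default): sessions are connected components of the
        overlap graph. ``"clique"``: greedy partition of each patient's
        start-sorted intervals into groups whose members all pairwise
        overlap; chained-but-not-mutual overlaps then split.

    Returns
    -------
    sessions, membership:
        Session table (``session_id, patient_id, start, stop, n_intervals,
        n_hcws``) and a Series mapping each concurrent interval's index
        label to its ``session_id``. Session IDs are deterministic:
        ``"<patient>:<earliest start ISO>:<rank>"``.
    """
    if rule not in ("component", "clique"):
        raise ValueError("rule must be 'component' or 'clique'")
    if rule == "component":
        groups = _component_groups(pairs)
    else:
        groups = _clique_groups(intervals, pairs)

    records = []
    for members in groups:
        sub = intervals.loc[members]
        records.append(
            {
                "members": tuple(members),
                "patient_id": sub["patient_id"].iloc[0],
                "start": sub["start"].min(),
                "stop": sub["stop"].max(),
                "n_intervals": len(sub),
                "n_hcws": sub["hcw_id"].nunique(),
            }
        )
    if not records:
        return (
            pd.DataFrame(columns=list(SESSION_COLUMNS)),
            pd.Series(dtype=object, name="session_id"),
        )
    sess = pd.DataFrame(records).sort_values(
        ["patient_id", "start"], kind="stable"
    )
    rank = sess.groupby(["patient_id", "start"], sort=False).cumcount()
    sess["session_id"] = [
        f"{p}:{s.isoformat()}:{r}"
        for p, s, r in zip(sess["patient_id"], sess["start"], rank)
    ]
    membership = {}
    for sid, members in zip(sess["session_id"], sess["members"]):
        for m in members:
            membership[m] = sid
    sess = sess.drop(columns="members").reset_index(drop=True)
    return sess[list(SESSION_COLUMNS)], pd.Series(membership, name="session_id")


def _component_groups(pairs: pd.DataFrame) -> list[list]:
    uf = _UnionFind()
    for a, b in zip(pairs["interval_a"], pairs["interval_b"]):
        uf.union(a, b)
    comps: dict = {}
    for node in uf.parent:
        comps.setdefault(uf.find(node), []).append(node)
    return [sorted(v) for v in comps.values() if len(v) >= 2]


def _clique_groups(intervals: pd.DataFrame, pairs: pd.DataFrame) -> list[list]:
    # Greedy scan in start order: an interval joins the open group while it
    # positively overlaps every current member (start < min member stop).
    involved = pd.unique(
        pd.concat([pairs["interval_a"], pairs["interval_b"]], ignore_index=True)
    )
    if len(involved) == 0:
        return []
    sub = intervals.loc[involved]
    groups: list[list] = []
    for _, grp in sub.groupby("patient_id", sort=False):
        grp = grp.sort_values(["start", "stop"], kind="stable")
        current: list = []
        min_stop = None
        for idx, r in grp.iterrows():
            if current and r["start"] < min_stop:
                current.append(idx)
                min_stop = min(min_stop, r["stop"])
            else:
                if len(current) >= 2:
                    groups.append(sorted(current))
                current = [idx]
                min_stop = r["stop"]
        if len(current) >= 2:
            groups.append(sorted(current))
    # a greedy clique may collapse to one HCW only if sessionization were
    # violated; guard anyway
    return [
        g for g in groups if intervals.loc[g, "hcw_id"].nunique() >= 2
    ]


def label_intervals(
    intervals: pd.DataFrame, membership: pd.Series
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate intervals ``concurrent`` / ``individual``.

    Returns the labeled table (new ``session_id`` and boolean ``concurrent``
    columns) and the class counts.
    """
    out = intervals.copy()
    out["session_id"] = out.index.map(membership.to_dict().get)
    out["concurrent"] = out["session_id"].notna()
    counts = {
        "concurrent": int(out["concurrent"].sum()),
        "individual": int((~out["concurrent"]).sum()),
    }
    return out, counts


@dataclass
class MatrixSet:
    """Sparse intermediate matrices over *concurrent* intervals.

    Rows/columns are indexed by the parallel ID lists. ``interval_session``
    rows sum to one (membership is a partition); ``hcw_session`` columns sum
    to ≥ 2 (a session involves at least two HCWs); ``interval_action`` row
    sums equal each interval's event count. The ``*_duration`` variants
    weight the HCW indicators by interval duration in seconds.
    """

    interval_action: sp.csr_matrix
    interval_session: sp.csr_matrix
    hcw_session: sp.csr_matrix
    hcw_interval: sp.csr_matrix
    hcw_session_duration: sp.csr_matrix
    hcw_interval_duration: sp.csr_matrix
    interval_ids: list = field(default_factory=list)
    action_ids: list = field(default_factory=list)
    session_ids: list = field(default_factory=list)
    hcw_ids: list = field(default_factory=list)

    _NAMES = (
        "interval_action",
        "interval_session",
        "hcw_session",
        "hcw_interval",
        "hcw_session_duration",
        "hcw_interval_duration",
    )

    def to_dir(self, path: str | Path) -> None:
        """Write each matrix as triplet CSV (row_id, col_id, value) plus
        row/column index maps."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        maps = {
            "interval": self.interval_ids,
            "action": self.action_ids,
            "session": self.session_ids,
            "hcw": self.hcw_ids,
        }
        for name, ids in maps.items():
            pd.DataFrame({"index": range(len(ids)), "id": ids}).to_csv(
                path / f"index_{name}.csv", index=False
            )
        for name in self._NAMES:
            m = getattr(self, name).tocoo()
            pd.DataFrame(
                {"row": m.row, "col": m.col, "value": m.data}
            ).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "MatrixSet":
        path = Path(path)
        ids = {}
        for name in ("interval", "action", "session", "hcw"):
            df = pd.read_csv(path / f"index_{name}.csv")
            ids[name] = df["id"].tolist()
        shapes = {
            "interval_action": (len(ids["interval"]), len(ids["action"])),
            "interval_session": (len(ids["interval"]), len(ids["session"])),
            "hcw_session": (len(ids["hcw"]), len(ids["session"])),
            "hcw_interval": (len(ids["hcw"]), len(ids["interval"])),
            "hcw_session_duration": (len(ids["hcw"]), len(ids["session"])),
            "hcw_interval_duration": (len(ids["hcw"]), len(ids["interval"])),
        }
        mats = {}
        for name, shape in shapes.items():
            df = pd.read_csv(path / f"{name}.csv")
            mats[name] = sp.coo_matrix(
                (df["value"], (df["row"], df["col"])), shape=shape
            ).tocsr()
        return cls(
            **mats,
            interval_ids=ids["interval"],
            action_ids=ids["action"],
            session_ids=ids["session"],
            hcw_ids=ids["hcw"],
        )


def build_matrices(labeled: pd.DataFrame, sessions: pd.DataFrame) -> MatrixSet:
    """Assemble the intermediate matrices from labeled intervals."""
    conc = labeled[labeled["concurrent"]]
    interval_ids = list(conc.index)
    session_ids = list(sessions["session_id"])
    hcw_ids = sorted(conc["hcw_id"].unique())
    if "actions" in conc.columns and len(conc):
        action_ids = sorted({a for acts in conc["actions"] for a in acts})
    else:
        action_ids = []

    ipos = {v: i for i, v in enumerate(interval_ids)}
    spos = {v: i for i, v in enumerate(session_ids)}
    hpos = {v: i for i, v in enumerate(hcw_ids)}
    apos = {v: i for i, v in enumerate(action_ids)}

    ia_r, ia_c, ia_v = [], [], []
    if action_ids:
        for idx, acts in zip(conc.index, conc["actions"]):
            counts: dict = {}
            for a in acts:
                counts[a] = counts.get(a, 0) + 1
            for a, n in counts.items():
                ia_r.append(ipos[idx])
                ia_c.append(apos[a])
                ia_v.append(n)
    interval_action = sp.coo_matrix(
        (ia_v, (ia_r, ia_c)), shape=(len(interval_ids), len(action_ids))
    ).tocsr()

    is_r = [ipos[idx] for idx in conc.index]
    is_c = [spos[sid] for sid in conc["session_id"]]
    interval_session = sp.coo_matrix(
        (np.ones(len(is_r)), (is_r, is_c)),
        shape=(len(interval_ids), len(session_ids)),
    ).tocsr()

    h_r = [hpos[h] for h in conc["hcw_id"]]
    dur = conc["duration_s"].to_numpy(dtype=float)
    hcw_interval = sp.coo_matrix(
        (np.ones(len(h_r)), (h_r, is_r)),
        shape=(len(hcw_ids), len(interval_ids)),
    ).tocsr()
    hcw_interval_duration = sp.coo_matrix(
        (dur, (h_r, is_r)), shape=(len(hcw_ids), len(interval_ids))
    ).tocsr()
    hs = sp.coo_matrix(
        (np.ones(len(h_r)), (h_r, is_c)), shape=(len(hcw_ids), len(session_ids))
    ).tocsr()
    hcw_session = hs.sign()  # indicator, even if an HCW has 2 intervals in one session
    hcw_session_duration = sp.coo_matrix(
        (dur, (h_r, is_c)), shape=(len(hcw_ids), len(session_ids))
    ).tocsr()

    return MatrixSet(
        interval_action=interval_action,
        interval_session=interval_session,
        hcw_session=hcw_session,
        hcw_interval=hcw_interval,
        hcw_session_duration=hcw_session_duration,
        hcw_interval_duration=hcw_interval_duration,
        interval_ids=interval_ids,
        action_ids=action_ids,
        session_ids=session_ids,
        hcw_ids=hcw_ids,
    )
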
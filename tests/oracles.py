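"""Independent brute-force oracles the fast implementations are checked against.

Each oracle favors obviousness over speed: plain per-group linear scans,
all-pairs overlap comparison, transitive closure through networkx, iterative
k-core deletion, and per-session set unions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def naive_intervals(events: pd.DataFrame, cutoff_s: float) -> list[tuple]:
    """Per-(HCW, patient) linear scan: split whenever the gap exceeds the
    cutoff. Returns (hcw, patient, start, stop, n_events) tuples."""
    out = []
    for (h, p), grp in events.groupby(["hcw_id", "patient_id"], sort=True):
        times = list(grp["timestamp"])
        run = [times[0]]
        for prev, cur in zip(times, times[1:]):
            if (cur - prev).total_seconds() > cutoff_s:
                out.append((h, p, run[0], run[-1], len(run)))
                run = [cur]
            else:
                run.append(cur)
        out.append((h, p, run[0], run[-1], len(run)))
    return sorted(out)


def brute_pairs(intervals: pd.DataFrame) -> set[tuple]:
    """All-pairs overlap comparison; returns frozenset-free sorted id pairs."""
    pat = intervals["patient_id"].to_numpy()
    hcw = intervals["hcw_id"].to_numpy()
    start = intervals["start"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    stop = intervals["stop"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    idx = intervals.index.to_numpy()
    same_pat = pat[:, None] == pat[None, :]
    diff_hcw = hcw[:, None] != hcw[None, :]
    overlap = np.minimum(stop[:, None], stop[None, :]) - np.maximum(
        start[:, None], start[None, :]
    )
    mask = same_pat & diff_hcw & (overlap > 0)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    return {tuple(sorted((idx[i], idx[j]))) for i, j in zip(ii, jj)}


def brute_sessions(intervals: pd.DataFrame, pairs: set[tuple]) -> set[frozenset]:
    """Connected components of the overlap graph via networkx."""
    g = nx.Graph()
    g.add_edges_from(pairs)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


def brute_k_core(graph: nx.Graph, k: int) -> set:
    """Repeatedly delete nodes of degree < k until stable."""
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    while True:
        drop = [n for n in g.nodes if g.degree(n) < k]
        if not drop:
            return set(g.nodes)
        g.remove_nodes_from(drop)


def brute_session_cluster_counts(
    assignments: np.ndarray, interval_session
) -> np.ndarray:
    """Distinct clusters per session by explicit set union."""
    dense = np.asarray(interval_session.todense())
    counts = []
    for s in range(dense.shape[1]):
        members = np.nonzero(dense[:, s])[0]
        counts.append(len({int(assignments[m]) for m in members}))
    return np.array(counts)


def random_event_stream(
    rng: np.random.Generator,
    n_events: int,
    n_hcws: int = 4,
    n_patients: int = 3,
    start: str = "2020-06-01",
) -> pd.DataFrame:
    """Random bursty event stream with mixed gap scales for oracle tests."""
    from ehrcollab.audit_log import sort_events

    hcw = rng.integers(n_hcws, size=n_events)
    pat = rng.integers(n_patients, size=n_events)
    # mixture of short and long gaps per (hcw, patient) stream
    scale = np.where(rng.random(n_events) < 0.7, 20.0, 900.0)
    offsets = np.floor(rng.exponential(scale)).astype(int)
    df = pd.DataFrame(
        {
            "hcw_id": [f"H{i}" for i in hcw],
            "patient_id": [f"P{i}" for i in pat],
            "action_id": "ACT",
        }
    )
    # cumulative offsets within each stream
    key = hcw * n_patients + pat
    t = np.zeros(n_events, dtype=int)
    for k in np.unique(key):
        sel = key == k
        t[sel] = np.cumsum(offsets[sel])
    df["timestamp"] = pd.Timestamp(start) + pd.to_timedelta(t, unit="s")
    return sort_events(df)


def random_intervals(
    rng: np.random.Generator,
    n: int,
    n_hcws: int = 6,
    n_patients: int = 3,
    horizon_s: float = 20_000.0,
) -> pd.DataFrame:
    """Random interval table (possibly heavy overlap) for sweep tests."""
    start_s = rng.uniform(0, horizon_s, size=n)
    dur = rng.exponential(300.0, size=n) * (rng.random(n) > 0.1)  # some zero-length
    base = pd.Timestamp("2020-06-01")
    df = pd.DataFrame(
        {
            "hcw_id": [f"H{i}" for i in rng.integers(n_hcws, size=n)],
            "patient_id": [f"P{i}" for i in rng.integers(n_patients, size=n)],
            "start": base + pd.to_timedelta(np.floor(start_s), unit="s"),
            "stop": base + pd.to_timedelta(np.floor(start_s + dur), unit="s"),
        }
    )
    df["duration_s"] = (df["stop"] - df["start"]).dt.total_seconds()
    df["n_events"] = 1 + (df["duration_s"] // 60).astype(int)
    return df
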
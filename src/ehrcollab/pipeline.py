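"""End-to-end convenience pipeline: events -> intervals -> sessions -> network.

Bundles the standard processing order (cutoff estimation, sessionization,
workday flagging, overlap detection, session assembly, matrix construction,
intensity metrics and the collaboration graph) behind one call, returning
every intermediate product so downstream analyses — temporal profiling,
clustering, recovery scoring — can pick what they need.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ehrcollab import concurrency, metrics, network, sessionize
from ehrcollab.concurrency import MatrixSet


@dataclass
class PipelineResult:
    cutoff_s: float
    intervals: pd.DataFrame
    workdays: pd.DataFrame
    labeled: pd.DataFrame
    label_counts: dict[str, int]
    sessions: pd.DataFrame
    membership: pd.Series
    matrices: MatrixSet | None
    intensity: pd.DataFrame | None
    graph: nx.Graph | None


def run(
    events: pd.DataFrame,
    hcw_meta: pd.DataFrame | None = None,
    cutoff_s: float | str = "auto",
    candidate_cutoffs: np.ndarray = sessionize.DEFAULT_CANDIDATE_CUTOFFS,
    workday_cutoff_min: float = sessionize.DEFAULT_WORKDAY_CUTOFF_MIN,
    session_rule: str = "component",
    build_matrices: bool = True,
    compute_intensity: bool = True,
) -> PipelineResult:
    """Run the full event-to-network pipeline.

    ``cutoff_s="auto"`` estimates the gap cutoff at the knee of the
    interval-count curve over ``candidate_cutoffs``; pass a number to fix it.
    """
    if cutoff_s == "auto":
        cutoff = sessionize.estimate_cutoff(events, candidate_cutoffs)
    else:
        cutoff = float(cutoff_s)
    intervals = sessionize.build_intervals(events, cutoff)
    workdays = sessionize.flag_workdays(intervals, workday_cutoff_min)
    pairs = concurrency.find_overlap_pairs(intervals)
    sessions, membership = concurrency.assemble_sessions(
        intervals, pairs, rule=session_rule
    )
    labeled, counts = concurrency.label_intervals(intervals, membership)

    mats = concurrency.build_matrices(labeled, sessions) if build_matrices else None
    intensity = (
        metrics.compute_intensity(labeled, workdays) if compute_intensity else None
    )
    graph = None
    if mats is not None and len(mats.hcw_ids):
        prop_time = None
        if intensity is not None and len(intensity):
            prop_time = metrics.per_hcw_means(intensity).set_index("hcw_id")[
                "prop_time"
            ]
        graph = network.build_graph(mats, hcw_meta=hcw_meta, prop_time=prop_time)
    return PipelineResult(
        cutoff_s=cutoff,
        intervals=intervals,
        workdays=workdays,
        labeled=labeled,
        label_counts=counts,
        sessions=sessions,
        membership=membership,
        matrices=mats,
        intensity=intensity,
        graph=graph,
    )
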
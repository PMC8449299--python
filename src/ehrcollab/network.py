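"""Co-session collaboration networks over HCWs and role categories.

Two HCWs are linked when they participate in the same concurrent session;
the edge weight is the number of sessions they share, i.e. the dot product
of their rows of the HCW × session indicator matrix (the off-diagonal of
``M @ M.T``). K-core extraction (every node keeps ≥ k neighbors inside the
subgraph, unweighted degree) isolates the core of the collaboration
structure. Role-level aggregation sums HCW-pair weights between role
categories, conserving total edge weight (within-role pairs become role
self-loops). Graphs export to GraphML/GEXF for external visualization.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ehrcollab.audit_log import UNKNOWN_ROLE
from ehrcollab.concurrency import MatrixSet


def build_graph(
    matrices: MatrixSet,
    hcw_meta: pd.DataFrame | None = None,
    prop_time: pd.Series | None = None,
) -> nx.Graph:
    """HCW collaboration graph from the HCW × session indicator matrix.

    Edge ``weight`` = number of shared sessions (≥ 1, no self-loops).
    Node attributes ``specialty``/``role`` come from ``hcw_meta`` and the
    node-size attribute ``prop_time`` (mean proportion of EHR time spent in
    concurrent intervals) from the optional series indexed by ``hcw_id``.
    """
    m = matrices.hcw_session.astype(np.int64)
    co = (m @ m.T).tocoo()
    g = nx.Graph()
    g.add_nodes_from(matrices.hcw_ids)
    ids = matrices.hcw_ids
    for r, c, v in zip(co.row, co.col, co.data):
        if r < c and v > 0:
            g.add_edge(ids[r], ids[c], weight=int(v))
    if hcw_meta is not None:
        meta = hcw_meta.set_index("hcw_id")
        for n in g.nodes:
            if n in meta.index:
                g.nodes[n]["specialty"] = meta.loc[n, "specialty"]
                g.nodes[n]["role"] = meta.loc[n, "role"]
            else:
                g.nodes[n]["role"] = UNKNOWN_ROLE
    if prop_time is not None:
        for n in g.nodes:
            g.nodes[n]["prop_time"] = float(prop_time.get(n, 0.0))
    return g


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph where every node has ≥ k neighbors inside it.

    Degree is unweighted; the result may be empty.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if graph.number_of_nodes() == 0:
        return graph.copy()
    return nx.k_core(graph, k)


def aggregate_roles(graph: nx.Graph, hcw_meta: pd.DataFrame) -> nx.Graph:
    """Collapse the HCW graph to role categories.

    Role-pair weight sums the HCW-level co-session counts between members of
    the two roles; within-role weight becomes a self-loop, so total edge
    weight is conserved exactly.
    """
    role_of = dict(zip(hcw_meta["hcw_id"], hcw_meta["role"]))
    rg = nx.Graph()
    for u, v, data in graph.edges(data=True):
        ru = role_of.get(u, UNKNOWN_ROLE)
        rv = role_of.get(v, UNKNOWN_ROLE)
        w = data.get("weight", 1)
        if rg.has_edge(ru, rv):
            rg[ru][rv]["weight"] += w
        else:
            rg.add_edge(ru, rv, weight=w)
    for n in graph.nodes:
        rg.add_node(role_of.get(n, UNKNOWN_ROLE))
    return rg


def rank_relationships(
    role_graph: nx.Graph,
    n_top: int = 6,
    n_bottom: int = 6,
    include_self: bool = False,
) -> pd.DataFrame:
    """Label the strongest role pairs high-likelihood and the weakest low.

    Pairs are sorted by weight (ties broken lexicographically by role names,
    so the split is deterministic); within-role self-pairs are excluded by
    default. Raises if fewer than ``n_top + n_bottom`` pairs exist.
    """
    rows = []
    for u, v, data in role_graph.edges(data=True):
        if u == v and not include_self:
            continue
        a, b = sorted((u, v))
        rows.append({"role_a": a, "role_b": b, "weight": data.get("weight", 1)})
    pairs = pd.DataFrame(rows)
    if len(pairs) < n_top + n_bottom:
        raise ValueError(
            f"only {len(pairs)} role pairs; need {n_top + n_bottom}"
        )
    pairs = pairs.sort_values(
        ["weight", "role_a", "role_b"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    labels = np.array([""] * len(pairs), dtype=object)
    if n_top:
        labels[:n_top] = "high"
    if n_bottom:
        labels[len(pairs) - n_bottom:] = "low"
    pairs["label"] = labels
    return pairs[pairs["label"] != ""].reset_index(drop=True)


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """Export to GraphML (.graphml), GEXF (.gexf) or edge-list CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
    elif path.suffix == ".gexf":
        nx.write_gexf(graph, path)
    elif path.suffix == ".csv":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1)}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unsupported graph format: {path.suffix}")
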
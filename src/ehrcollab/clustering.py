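"""Cluster concurrent intervals by action composition; session complexity.

Features are the raw within-interval action counts (the concurrent
interval × action matrix). Dimensionality is first reduced linearly (PCA,
components kept until a cumulative explained-variance target), then embedded
in 2-D with t-SNE, and K-means is run on the embedded coordinates with the
cluster count picked at the elbow (knee) of the within-cluster
sum-of-squares (WSS) curve. Clustering in the embedded space mirrors common
practice for this kind of audit-log data but is statistically fragile;
``cluster_space="pca"`` clusters the linear components instead.

*Session complexity* is the number of distinct clusters represented among a
concurrent session's member intervals, computed as the matrix product of the
cluster × interval indicator with the interval × session indicator; a
session whose members all share one cluster is a single-task session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from ehrcollab.concurrency import MatrixSet
from ehrcollab.sessionize import KneeCurve, KneeNotFoundError, knee_point

DEFAULT_K_GRID = tuple(range(5, 101, 5))


@dataclass
class EmbedResult:
    coords: np.ndarray
    n_components: int
    explained_variance: float
    components: np.ndarray


def reduce_and_embed(
    interval_action: sp.spmatrix | np.ndarray,
    variance_target: float = 0.97,
    seed: int = 0,
    max_components: int = 50,
    perplexity: float | None = None,
) -> EmbedResult:
    """PCA to a variance target, then seeded t-SNE to 2-D.

    Components are retained until cumulative explained variance reaches
    ``variance_target`` (capped at ``max_components``). The embedding is
    deterministic for a fixed seed and input.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    x = interval_action.toarray() if sp.issparse(interval_action) else np.asarray(
        interval_action, dtype=float
    )
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 concurrent intervals to embed")
    if np.linalg.matrix_rank(x) < 2:
        raise ValueError("action matrix has rank < 2; nothing to embed")
    if np.ptp(x, axis=0).max() == 0:
        raise ValueError("all intervals share one action profile; no variance")
    cap = int(min(max_components, n - 1, x.shape[1]))
    pca = PCA(n_components=cap, random_state=seed)
    comps = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(max(n_keep, 1), cap)
    comps = comps[:, :n_keep]
    if perplexity is None:
        perplexity = float(min(30.0, max(5.0, (n - 1) / 3.0)))
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=min(perplexity, (n - 1) / 3.0),
        init="pca" if n_keep >= 2 else "random",
    )
    coords = tsne.fit_transform(comps)
    return EmbedResult(
        coords=coords,
        n_components=n_keep,
        explained_variance=float(cum[n_keep - 1]),
        components=comps,
    )


def wss_curve(
    points: np.ndarray,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-cluster sum of squares at each candidate k (best of
    ``n_init`` restarts per k)."""
    points = np.asarray(points, dtype=float)
    ks = np.array([k for k in k_grid if 2 <= k <= len(points) // 2], dtype=int)
    if len(ks) < 5:
        raise ValueError("k grid must leave at least 5 feasible candidates")
    wss = np.empty(len(ks))
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed)
        km.fit(points)
        wss[i] = km.inertia_
    return ks, wss


def choose_k(
    points: np.ndarray,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, KneeCurve]:
    """Elbow-selected cluster count: knee of the WSS-versus-k curve.

    Raises :class:`~ehrcollab.sessionize.KneeNotFoundError` when the curve
    is flat or linear (no elbow; the caller should treat any returned k as
    low-confidence in that regime).
    """
    ks, wss = wss_curve(points, k_grid, seed=seed, n_init=n_init)
    knee = knee_point(ks.astype(float), wss, smoothing=1)
    ys = wss.copy()
    xn = (ks - ks[0]) / (ks[-1] - ks[0])
    rng = np.ptp(ys)
    yn = (ys - ys.min()) / rng if rng else ys * 0.0
    if yn[-1] < yn[0]:
        yn = 1.0 - yn
    curve = KneeCurve(x=ks.astype(float), y=wss, knee=knee, difference=yn - xn)
    return int(round(knee)), curve


def cluster_intervals(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """K-means assignments (one cluster label per concurrent interval)."""
    km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed)
    return km.fit_predict(np.asarray(points, dtype=float))


@dataclass
class SessionComplexity:
    """Distinct-cluster counts per session and their distribution."""

    per_session: pd.DataFrame
    distribution: dict[str, float] = field(default_factory=dict)

    @property
    def single_cluster_fraction(self) -> float:
        return self.distribution.get("1", 0.0)


def session_complexity(
    assignments: np.ndarray, matrices: MatrixSet
) -> SessionComplexity:
    """Number of distinct action clusters among each session's intervals.

    Computed via the cluster × interval indicator matrix times the
    interval × session matrix; positive entries per session column are the
    distinct clusters. The distribution buckets sessions by 1, 2, and 3+
    clusters and sums to one.
    """
    assignments = np.asarray(assignments)
    n_intervals = matrices.interval_session.shape[0]
    if len(assignments) != n_intervals:
        raise ValueError(
            f"{len(assignments)} assignments for {n_intervals} concurrent intervals"
        )
    if len(assignments) and np.any(assignments < 0):
        raise ValueError("every concurrent interval must have an assignment")
    k = int(assignments.max()) + 1 if len(assignments) else 0
    indicator = sp.coo_matrix(
        (np.ones(len(assignments)), (assignments, np.arange(len(assignments)))),
        shape=(k, n_intervals),
    ).tocsr()
    per_session = (indicator @ matrices.interval_session > 0).sum(axis=0)
    n_clusters = np.asarray(per_session).ravel().astype(int)
    df = pd.DataFrame(
        {"session_id": matrices.session_ids, "n_clusters": n_clusters}
    )
    n = len(df)
    dist = {}
    if n:
        dist = {
            "1": float((n_clusters == 1).sum() / n),
            "2": float((n_clusters == 2).sum() / n),
            "3+": float((n_clusters >= 3).sum() / n),
        }
    return SessionComplexity(per_session=df, distribution=dist)
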
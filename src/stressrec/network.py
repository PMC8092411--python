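"""Similarity graph over temporal response profiles.

Each feature's day-course (per-day log2 fold change, or per-day mean log
level) is z-scored across days; pairwise Pearson correlation of these
profiles defines a similarity, and the graph is the union of a minimum
spanning tree on the correlation distance with each node's k nearest
neighbours.  The MST guarantees connectivity, the kNN edges supply the local
density that community detection works on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse.csgraph import minimum_spanning_tree

from .matrices import OmicsMatrix, TemporalProfileMatrix

#: floor for edge weights so MST edges over negative similarity stay positive
WEIGHT_EPS = 1e-6


def standardize_profiles(source, feature_subset=None) -> TemporalProfileMatrix:
    """Build z-scored per-feature day-courses.

    ``source`` is either a long-format differential table (per-day log2FC;
    day 0 is included as 0) or a log-scale :class:`OmicsMatrix` (per-day mean
    level).  Rows are z-scored with the population standard deviation;
    constant profiles are dropped and reported in ``dropped``.
    """
    if isinstance(source, OmicsMatrix):
        if not source.log_scale:
            raise ValueError("log-normalize the matrix first")
        days = source.days
        cols = {int(d): source.values[source.samples_at(int(d))].mean(axis=1) for d in days}
        profile = pd.DataFrame(cols)
    elif isinstance(source, pd.DataFrame) and {"feature_id", "day", "log2FC"} <= set(
        source.columns
    ):
        profile = source.pivot(index="feature_id", columns="day", values="log2FC")
        profile.insert(0, 0, 0.0)  # baseline day: zero fold change
        profile.columns = [int(c) for c in profile.columns]
    else:
        raise TypeError("source must be an OmicsMatrix or a differential table")

    if profile.shape[1] < 3:
        raise ValueError("need at least 3 days for a temporal profile")
    if feature_subset is not None:
        feature_subset = [f for f in feature_subset if f in profile.index]
        if not feature_subset:
            raise ValueError("feature_subset is empty or disjoint from features")
        profile = profile.loc[feature_subset]

    arr = profile.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    dropped = list(profile.index[constant])
    arr = arr[~constant]
    arr = (arr - arr.mean(axis=1, keepdims=True)) / sd[~constant, None]
    return TemporalProfileMatrix(
        profiles=pd.DataFrame(arr, index=profile.index[~constant], columns=profile.columns),
        dropped=dropped,
    )


def deregulated_features(table: pd.DataFrame) -> list[str]:
    """Features called up or down at one or more days (default graph scope)."""
    called = table.loc[table["call"] != "none", "feature_id"].unique()
    return list(called)


def similarity_graph(profiles: TemporalProfileMatrix, k: int = 5) -> nx.Graph:
    """MST-union-kNN graph on the correlation distance between profiles.

    Similarity s_ij is the Pearson correlation of z-scored day-courses; the
    distance d_ij = sqrt(2 (1 - s_ij)) is the Euclidean distance between the
    normalized profiles.  The edge set is the MST of d plus each node's k
    nearest neighbours; edge weights are max(s_ij, eps) so that bridging MST
    edges over anticorrelated profiles keep a positive (but negligible)
    weight.  The result is connected by construction.
    """
    ids = list(profiles.feature_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 features")
    if k < 1 or k >= n:
        raise ValueError("require 1 <= k < n_features")

    Z = profiles.profiles.to_numpy(dtype=float)
    m = Z.shape[1]
    sim = (Z @ Z.T) / m  # Pearson correlation of z-scored rows
    np.clip(sim, -1.0, 1.0, out=sim)
    dist = np.sqrt(np.maximum(2.0 * (1.0 - sim), 0.0))
    np.fill_diagonal(dist, 0.0)

    edges = set()
    # shift off-diagonal distances by a constant so zero distances (identical
    # profiles) still count as edges for csgraph; a constant shift leaves the
    # MST edge set invariant
    dist_mst = dist + 1e-9
    np.fill_diagonal(dist_mst, 0.0)
    mst = minimum_spanning_tree(dist_mst).tocoo()
    for i, j in zip(mst.row, mst.col):
        edges.add((min(i, j), max(i, j)))
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        neighbours = [j for j in order[i] if j != i][:k]
        for j in neighbours:
            edges.add((min(i, j), max(i, j)))

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j in sorted(edges):
        g.add_edge(ids[i], ids[j], weight=float(max(sim[i, j], WEIGHT_EPS)))
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["id_i", "id_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
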
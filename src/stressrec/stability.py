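"""Multiscale Markov Stability community detection.

The quality of a partition H of a weighted graph at Markov time t is the
clustered autocovariance of a continuous-time random walk,

    r(t, H) = trace[ H' (Pi exp(-t L) - pi pi') H ],

with L = I - D^{-1} A the random-walk Laplacian, pi_i = d_i / 2m the
stationary distribution and Pi = diag(pi).  Small t resolves fine
communities, large t coarse ones.  The linearization around t = 0,

    r_lin(t, H) = (1 - t) + t * sum_c W_c / 2m - sum_c pi_c^2,

equals Newman-Girvan modularity at t = 1 and is the default objective for
optimization (it is a generalized modularity with resolution 1/t, amenable
to Louvain-style greedy optimization).  Partitions are scanned across a
log-spaced grid of Markov times and a robust partition is selected from the
longest plateau in which the cluster count is constant and optimizer
restarts agree (low variation of information).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "Partition",
    "StabilityScan",
    "stationary_distribution",
    "partition_stability",
    "optimize_partition",
    "variation_of_information",
    "scan_markov_times",
    "select_robust_partition",
    "brute_force_optimum",
    "cluster_mean_profiles",
]

DEFAULT_N_EXACT = 2000


@dataclass
class Partition:
    """Assignment of graph nodes to contiguous cluster labels 0..c-1."""

    nodes: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.nodes) != len(self.labels):
            raise ValueError("nodes and labels length mismatch")
        self.labels = _contiguous(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.nodes, name="cluster")

    def indicator(self) -> np.ndarray:
        h = np.zeros((len(self.labels), self.n_clusters))
        h[np.arange(len(self.labels)), self.labels] = 1.0
        return h


def _contiguous(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _graph_arrays(graph: nx.Graph):
    """(nodes, CSR adjacency, degrees, 2m) for a weighted undirected graph."""
    nodes = list(graph.nodes)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    a = a.astype(float)
    deg = np.asarray(a.sum(axis=1)).ravel() + a.diagonal()  # self-loops count twice
    two_m = deg.sum()
    if two_m <= 0:
        raise ValueError("graph has no edge weight")
    return nodes, a, deg, two_m


def stationary_distribution(graph: nx.Graph) -> np.ndarray:
    """Random-walk stationary distribution pi_i = d_i / sum(d)."""
    if not nx.is_connected(graph):
        raise ValueError("graph must be connected")
    _, _, deg, two_m = _graph_arrays(graph)
    return deg / two_m


def partition_stability(
    graph: nx.Graph,
    partition: Partition | np.ndarray,
    t: float,
    mode: str = "linearized",
    n_exact: int = DEFAULT_N_EXACT,
) -> float:
    """Markov Stability r(t, H) of a partition, exact or linearized."""
    if mode not in ("exact", "linearized"):
        raise ValueError("mode must be 'exact' or 'linearized'")
    nodes, a, deg, two_m = _graph_arrays(graph)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    labels = _contiguous(labels)
    if len(labels) != len(nodes):
        raise ValueError("partition does not cover the graph")
    pi = deg / two_m
    if mode == "linearized":
        return _stability_linearized(a, deg, two_m, labels, t)
    n = len(nodes)
    if n > n_exact:
        raise ValueError(f"exact mode capped at n <= {n_exact}")
    # exp(-tL) with L = I - D^{-1}A via the symmetrized Laplacian:
    # D^{1/2} L D^{-1/2} is symmetric, so exp(-tL) = D^{-1/2} U e^{-t lam} U' D^{1/2}
    d_half = np.sqrt(deg)
    A = a.toarray()
    l_sym = np.eye(n) - (A / d_half[:, None]) / d_half[None, :]
    lam, u = np.linalg.eigh(l_sym)
    expl = (u * np.exp(-t * lam)) @ u.T
    exp_tl = (expl / d_half[:, None]) * d_half[None, :]
    h = np.zeros((n, labels.max() + 1))
    h[np.arange(n), labels] = 1.0
    m_mat = (pi[:, None] * exp_tl) - np.outer(pi, pi)
    return float(np.trace(h.T @ m_mat @ h))


def _stability_linearized(a, deg, two_m, labels, t) -> float:
    pi = deg / two_m
    c = labels.max() + 1
    w_in = np.zeros(c)
    coo = a.tocoo()
    same = labels[coo.row] == labels[coo.col]
    np.add.at(w_in, labels[coo.row[same]], coo.data[same])
    pi_c = np.bincount(labels, weights=pi, minlength=c)
    return float((1 - t) + t * w_in.sum() / two_m - (pi_c**2).sum())


# ---------------------------------------------------------------------------
# Louvain-style greedy optimizer for the linearized objective
# ---------------------------------------------------------------------------

def _louvain_level(indptr, indices, data, loops, deg, two_m, gamma, order, labels):
    """One local-moving phase; mutates ``labels`` in place.

    Gain of moving node i into community c (with i removed from its own):
    k_{i,c} - gamma * d_i * sigma_c / 2m, where k_{i,c} is the weight from i
    to c and sigma_c the total degree of c.
    """
    sigma = np.bincount(labels, weights=deg, minlength=labels.max() + 1)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in order:
            ci = labels[i]
            di = deg[i]
            sigma[ci] -= di
            # weights to neighbouring communities
            k_ic: dict[int, float] = {}
            for ptr in range(indptr[i], indptr[i + 1]):
                j = indices[ptr]
                if j == i:
                    continue
                cj = labels[j]
                k_ic[cj] = k_ic.get(cj, 0.0) + data[ptr]
            k_ic.setdefault(ci, 0.0)
            best_c, best_gain = ci, k_ic[ci] - gamma * di * sigma[ci] / two_m
            for cj, w in k_ic.items():
                if cj == ci:
                    continue
                gain = w - gamma * di * sigma[cj] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = cj, gain
            labels[i] = best_c
            sigma[best_c] += di
            if best_c != ci:
                moved = True
                improved = True
    return improved


def _aggregate(a_csr, loops, labels):
    """Collapse communities into super-nodes; returns (adjacency, loops)."""
    c = labels.max() + 1
    coo = a_csr.tocoo()
    rows = labels[coo.row]
    cols = labels[coo.col]
    agg = sparse.coo_matrix((coo.data, (rows, cols)), shape=(c, c)).tocsr()
    new_loops = np.asarray(agg.diagonal()).ravel() / 2.0 + np.bincount(
        labels, weights=loops, minlength=c
    )
    agg.setdiag(0)
    agg.eliminate_zeros()
    return agg, new_loops


def _refine(a_csr, deg, two_m, gamma, labels, order) -> np.ndarray:
    """Node-level local moves on the original graph from a warm start.

    The aggregation phase can lock single nodes inside their super-node;
    one more sweep of individual moves at the finest level repairs this.
    """
    labels = _contiguous(labels.copy())
    _louvain_level(
        a_csr.indptr, a_csr.indices, a_csr.data, np.zeros(a_csr.shape[0]),
        deg, two_m, gamma, order, labels,
    )
    return _contiguous(labels)


def _louvain_run(a_csr, deg, two_m, gamma, rng) -> np.ndarray:
    n = a_csr.shape[0]
    node_map = np.arange(n)  # original node -> current super-node
    cur_a = a_csr.copy()
    cur_a.setdiag(0)
    cur_a.eliminate_zeros()
    cur_loops = np.zeros(n)
    cur_deg = deg.copy()
    while True:
        nn = cur_a.shape[0]
        labels = np.arange(nn)
        order = rng.permutation(nn)
        improved = _louvain_level(
            cur_a.indptr, cur_a.indices, cur_a.data, cur_loops, cur_deg, two_m, gamma,
            order, labels,
        )
        labels = _contiguous(labels)
        if not improved or labels.max() + 1 == nn or labels.max() == 0:
            final = node_map if not improved else labels[node_map]
            return _refine(a_csr, deg, two_m, gamma, final, rng.permutation(n))
        node_map = labels[node_map]
        cur_a, cur_loops = _aggregate(cur_a, cur_loops, labels)
        cur_deg = np.asarray(cur_a.sum(axis=1)).ravel() + 2.0 * cur_loops


def optimize_partition(
    graph: nx.Graph, t: float, n_restarts: int = 50, seed: int = 0
) -> Partition:
    """Best-of-restarts Louvain optimization of linearized stability.

    The linearized objective at Markov time t is a generalized modularity
    with resolution gamma = 1/t; each restart shuffles the node visiting
    order with its own deterministic child seed and the partition with the
    highest r(t) is returned.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    parts = optimize_partition_restarts(graph, t, n_restarts, seed)
    nodes, a, deg, two_m = _graph_arrays(graph)
    scores = [_stability_linearized(a, deg, two_m, p.labels, t) for p in parts]
    return parts[int(np.argmax(scores))]


def optimize_partition_restarts(
    graph: nx.Graph, t: float, n_restarts: int, seed: int
) -> list[Partition]:
    """All restart partitions (used for robustness VI estimates)."""
    nodes, a, deg, two_m = _graph_arrays(graph)
    gamma = 1.0 / t
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        labels = _louvain_run(a, deg, two_m, gamma, rng)
        out.append(Partition(nodes=nodes, labels=labels))
    return out


# ---------------------------------------------------------------------------
# partition comparison and scan
# ---------------------------------------------------------------------------

def variation_of_information(p: Partition, q: Partition) -> float:
    """VI(P, Q) = H(P) + H(Q) - 2 I(P; Q), in nats; 0 iff identical."""
    if list(p.nodes) != list(q.nodes):
        raise ValueError("partitions cover different node sets")
    cont = contingency_matrix(p.labels, q.labels, sparse=False).astype(float)
    n = cont.sum()
    pij = cont / n
    pi_ = pij.sum(axis=1)
    pj_ = pij.sum(axis=0)
    hp = -np.sum(pi_[pi_ > 0] * np.log(pi_[pi_ > 0]))
    hq = -np.sum(pj_[pj_ > 0] * np.log(pj_[pj_ > 0]))
    nz = pij > 0
    mi = np.sum(pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pi_, pj_)[nz])))
    return float(max(hp + hq - 2 * mi, 0.0))


@dataclass
class StabilityScan:
    """Per-Markov-time optimization results across a log-spaced grid."""

    t_grid: np.ndarray
    partitions: list
    stability: np.ndarray
    n_clusters: np.ndarray
    mean_restart_vi: np.ndarray
    consecutive_vi: np.ndarray = field(default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "stability": self.stability,
                "n_clusters": self.n_clusters,
                "mean_restart_vi": self.mean_restart_vi,
            }
        )


def default_t_grid(n_points: int = 50) -> np.ndarray:
    return np.logspace(-2, 2, n_points)


def scan_markov_times(
    graph: nx.Graph,
    t_grid: np.ndarray | None = None,
    n_restarts: int = 50,
    seed: int = 0,
    max_vi_pairs: int = 10,
) -> StabilityScan:
    """Optimize the partition at every Markov time on the grid.

    Per t the scan records the best partition, its stability, the cluster
    count, and the mean pairwise VI across restart partitions (restricted to
    ``max_vi_pairs`` restarts to keep the pair count bounded).  VI between
    consecutive best partitions is also recorded.
    """
    if t_grid is None:
        t_grid = default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) == 0:
        raise ValueError("empty Markov-time grid")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t grid must be strictly increasing")
    nodes, a, deg, two_m = _graph_arrays(graph)
    seeds = np.random.SeedSequence(seed).spawn(len(t_grid))
    parts, stab, ncl, mean_vi = [], [], [], []
    for t, t_seed in zip(t_grid, seeds):
        restarts = optimize_partition_restarts(
            graph, t, n_restarts, t_seed.generate_state(1)[0] % (2**31)
        )
        scores = [_stability_linearized(a, deg, two_m, p.labels, t) for p in restarts]
        best = restarts[int(np.argmax(scores))]
        parts.append(best)
        stab.append(max(scores))
        ncl.append(best.n_clusters)
        sub = restarts[:max_vi_pairs]
        if len(sub) > 1:
            vis = [
                variation_of_information(p, q)
                for p, q in itertools.combinations(sub, 2)
            ]
            mean_vi.append(float(np.mean(vis)))
        else:
            mean_vi.append(0.0)
    consec = np.array(
        [variation_of_information(parts[i], parts[i + 1]) for i in range(len(parts) - 1)]
    )
    return StabilityScan(
        t_grid=t_grid,
        partitions=parts,
        stability=np.array(stab),
        n_clusters=np.array(ncl),
        mean_restart_vi=np.array(mean_vi),
        consecutive_vi=consec,
    )


def select_robust_partition(
    scan: StabilityScan, vi_max: float | None = None
) -> tuple[Partition, dict]:
    """Pick the partition at the centre of the longest robust t-plateau.

    A plateau is a maximal run of consecutive Markov times with a constant
    cluster count and mean restart VI <= vi_max (default 0.05 ln n).  Ties
    between equally long plateaus break toward larger t; with no plateau the
    globally best-stability partition is returned, flagged as a fallback.
    """
    if len(scan.t_grid) == 0:
        raise ValueError("empty scan")
    n = len(scan.partitions[0].labels)
    if vi_max is None:
        vi_max = 0.05 * np.log(n) if n > 1 else 0.05
    ok = scan.mean_restart_vi <= vi_max
    runs = []  # (length, start, end) inclusive
    i, n_t = 0, len(scan.t_grid)
    while i < n_t:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_t and ok[j + 1] and scan.n_clusters[j + 1] == scan.n_clusters[i]:
            j += 1
        runs.append((j - i + 1, i, j))
        i = j + 1
    # single-cluster plateaus carry no structure; prefer informative ones
    informative = [r for r in runs if scan.partitions[r[1]].n_clusters > 1]
    pool = informative if informative else runs
    if not pool:
        best = int(np.argmax(scan.stability))
        return scan.partitions[best], {
            "fallback": True,
            "t": float(scan.t_grid[best]),
            "vi_max": vi_max,
        }
    length = max(r[0] for r in pool)
    # ties toward larger t: take the last run of maximal length
    run = [r for r in pool if r[0] == length][-1]
    centre = run[1] + run[0] // 2
    return scan.partitions[centre], {
        "fallback": False,
        "t": float(scan.t_grid[centre]),
        "plateau": (float(scan.t_grid[run[1]]), float(scan.t_grid[run[2]])),
        "plateau_length": length,
        "vi_max": vi_max,
    }


# ---------------------------------------------------------------------------
# exhaustive oracle and cluster summaries
# ---------------------------------------------------------------------------

def _set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, k):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(0, 0)


def brute_force_optimum(graph: nx.Graph, t: float, mode: str = "linearized") -> Partition:
    """Exhaustive argmax of r(t, .) over all set partitions (n <= 10)."""
    nodes, a, deg, two_m = _graph_arrays(graph)
    n = len(nodes)
    if n > 10:
        raise ValueError("brute force capped at n <= 10")
    best, best_r = None, -np.inf
    for labels in _set_partitions(n):
        if mode == "linearized":
            r = _stability_linearized(a, deg, two_m, labels, t)
        else:
            r = partition_stability(graph, labels, t, mode=mode)
        if r > best_r + 1e-15:
            best, best_r = labels.copy(), r
    return Partition(nodes=nodes, labels=best)


def cluster_mean_profiles(partition: Partition, profiles) -> pd.DataFrame:
    """Per-cluster mean day-course with standard errors and sizes.

    ``profiles`` is a :class:`TemporalProfileMatrix` or a DataFrame indexed
    by feature id with day columns.  Returns a DataFrame indexed by cluster
    with ``mean_<day>``, ``se_<day>`` and ``size`` columns.
    """
    df = profiles.profiles if hasattr(profiles, "profiles") else profiles
    assign = partition.as_series()
    missing = [f for f in assign.index if f not in df.index]
    if missing:
        raise ValueError(f"profiles missing for {len(missing)} partition features")
    rows = {}
    for cluster, members in assign.groupby(assign):
        sub = df.loc[members.index]
        if len(sub) == 0:
            raise ValueError(f"empty cluster {cluster}")
        mean = sub.mean(axis=0)
        se = sub.std(axis=0, ddof=1).fillna(0.0) / np.sqrt(len(sub))
        row = {f"mean_{int(d)}": mean[d] for d in df.columns}
        row.update({f"se_{int(d)}": se[d] for d in df.columns})
        row["size"] = len(sub)
        rows[cluster] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster")
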
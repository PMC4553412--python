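"""Sparsity thresholding, efficiency metrics, null models, small-worldness.

A weighted connectivity matrix is binarized over a sparsity grid (the
fraction of possible edges retained; default 0.02-0.40 in steps of
0.02).  For each binary graph G with N nodes:

    global efficiency   E_glob = (1/(N(N-1))) sum_{i != j} 1/d_ij
    nodal efficiency    e_i    = (1/(N-1))    sum_{j != i} 1/d_ij
    local efficiency    E_loc  = (1/N) sum_i E_glob(G_i)

with d_ij the unweighted shortest-path length and G_i the subgraph
induced by the neighbors of i (i excluded).  Disconnected pairs
contribute 0 (1/inf); a neighbor subgraph with fewer than two nodes has
efficiency 0.  Metric curves over the grid are summarized by the
trapezoidal area under the curve (AUC).

Small-worldness is judged against degree-preserving random graphs
(Maslov-Sneppen rewiring): normalized local efficiency > 1 together with
normalized global efficiency approximately 1.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .wavelet_fc import ConnectivityMatrix

try:  # numba accelerates the inner BFS loops; scipy covers its absence
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = [
    "BinaryGraph",
    "NullEnsemble",
    "EfficiencyProfile",
    "default_sparsity_grid",
    "threshold_by_sparsity",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "rewire_preserving_degree",
    "build_null_ensemble",
    "normalize_against_null",
    "is_small_world",
    "auc_over_sparsity",
    "efficiency_profile",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph as a boolean adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.dtype != bool:
            object.__setattr__(self, "adjacency", a.astype(bool))
            a = self.adjacency
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class NullEnsemble:
    """Efficiencies of degree-matched rewired surrogates of one graph."""

    e_glob: np.ndarray
    e_loc: np.ndarray
    seed: int

    @property
    def n_null(self) -> int:
        return len(self.e_glob)

    @property
    def mean_e_glob(self) -> float:
        return float(self.e_glob.mean())

    @property
    def mean_e_loc(self) -> float:
        return float(self.e_loc.mean())


@dataclass
class EfficiencyProfile:
    """Efficiency curves of one connectivity matrix over the sparsity grid.

    ``nodal_glob``/``nodal_loc`` are ``(n_sparsity, n_nodes)`` arrays of
    per-node global (e_i) and local (E_glob of the neighbor subgraph)
    efficiencies; AUC fields summarize each curve over the grid.
    Normalized curves (vs. null-ensemble means) are present only where a
    null ensemble was requested, NaN elsewhere.
    """

    subject_id: str
    modality: str
    scale: int | None
    sparsity_grid: np.ndarray
    e_glob: np.ndarray
    e_loc: np.ndarray
    nodal_glob: np.ndarray
    nodal_loc: np.ndarray
    normalized_e_glob: np.ndarray
    normalized_e_loc: np.ndarray
    auc_e_glob: float = field(init=False)
    auc_e_loc: float = field(init=False)
    auc_nodal_glob: np.ndarray = field(init=False)
    auc_nodal_loc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        g = self.sparsity_grid
        self.auc_e_glob = auc_over_sparsity(self.e_glob, g)
        self.auc_e_loc = auc_over_sparsity(self.e_loc, g)
        self.auc_nodal_glob = np.trapezoid(self.nodal_glob, g, axis=0)
        self.auc_nodal_loc = np.trapezoid(self.nodal_loc, g, axis=0)

    def mean_normalized(self) -> tuple[float, float]:
        """Mean normalized (global, local) efficiency over evaluated sparsities."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(self.normalized_e_glob)), float(
                np.nanmean(self.normalized_e_loc)
            )


def default_sparsity_grid(
    lo: float = 0.02, hi: float = 0.40, step: float = 0.02
) -> np.ndarray:
    """The study grid: 0.02 <= sparsity <= 0.40, interval 0.02 (20 points)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def threshold_by_sparsity(matrix: ConnectivityMatrix | np.ndarray, s: float) -> BinaryGraph:
    """Keep the ``round(s * N(N-1)/2)`` strongest edges of a weighted matrix.

    Missing weights (NaN) are never selected.  Ties at the cut are broken
    deterministically by (weight desc, i asc, j asc) over the upper
    triangle.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju].astype(float)
    vals[np.isnan(vals)] = -np.inf
    k = int(round(s * n * (n - 1) / 2))
    adj = np.zeros((n, n), dtype=bool)
    if k > 0:
        # stable sort on -weight preserves (i asc, j asc) among ties
        order = np.argsort(-vals, kind="stable")[:k]
        order = order[np.isfinite(vals[order])]
        if len(order) < k:
            warnings.warn(
                f"only {len(order)} finite weights available for {k} requested edges"
            )
        adj[iu[order], ju[order]] = True
        adj |= adj.T
    if k == 0:
        warnings.warn(f"sparsity {s} yields an empty graph on {n} nodes")
    return BinaryGraph(adj)


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(adj.astype(np.int8)), method="D", unweighted=True)


# BFS over bitset adjacency rows: one 64-node block per machine word, so a
# breadth-first sweep costs O(N^2/64) words per source instead of O(N + K)
# pointer chases.  These kernels back both the whole-graph efficiencies and
# the per-neighbor-subgraph sweeps of local efficiency.
_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_U1 = np.uint64(1)
_U0 = np.uint64(0)


@_njit(cache=False)
def _popcount64(x: np.uint64) -> np.uint64:  # pragma: no cover - numba kernel
    x = x - ((x >> _U1) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


@_njit(cache=False)
def _bitset_invsums(R: np.ndarray, k: int, wk: int) -> np.ndarray:  # pragma: no cover - numba kernel
    out = np.zeros(k)
    visited = np.empty(wk, np.uint64)
    frontier = np.empty(wk, np.uint64)
    nxt = np.empty(wk, np.uint64)
    for s in range(k):
        acc = 0.0
        cnt = 0
        for t in range(wk):
            frontier[t] = R[s, t]
            visited[t] = R[s, t]
            cnt += int(_popcount64(frontier[t]))
        visited[s >> 6] |= _U1 << np.uint64(s & 63)
        level = 1
        while cnt > 0:
            acc += cnt / level
            for t in range(wk):
                nxt[t] = _U0
            for t in range(wk):
                word = frontier[t]
                base = t << 6
                while word != _U0:
                    lsb = word & (~word + _U1)
                    b = base + int(_popcount64(lsb - _U1))
                    for q in range(wk):
                        nxt[q] |= R[b, q]
                    word ^= lsb
            cnt = 0
            for t in range(wk):
                nxt[t] &= ~visited[t]
                visited[t] |= nxt[t]
                frontier[t] = nxt[t]
                cnt += int(_popcount64(nxt[t]))
            level += 1
        out[s] = acc
    return out


@_njit(cache=False)
def _bfs_inv_sums_csr(indptr: np.ndarray, indices: np.ndarray, n: int) -> np.ndarray:  # pragma: no cover - numba kernel
    w = (n + 63) >> 6
    R = np.zeros((n, w), np.uint64)
    for u in range(n):
        for idx in range(indptr[u], indptr[u + 1]):
            v = indices[idx]
            R[u, v >> 6] |= _U1 << np.uint64(v & 63)
    return _bitset_invsums(R, n, w)


@_njit(cache=False)
def _local_eff_csr(indptr: np.ndarray, indices: np.ndarray, n: int) -> np.ndarray:  # pragma: no cover - numba kernel
    vals = np.zeros(n)
    pos = np.full(n, -1, np.int32)
    maxk = 2
    for i in range(n):
        d = indptr[i + 1] - indptr[i]
        if d > maxk:
            maxk = d
    wmax = (maxk + 63) >> 6
    R = np.zeros((maxk, wmax), np.uint64)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k < 2:
            continue
        nbrs = indices[indptr[i] : indptr[i + 1]]
        for a in range(k):
            pos[nbrs[a]] = a
        wk = (k + 63) >> 6
        for a in range(k):
            for t in range(wk):
                R[a, t] = _U0
        for a in range(k):
            u = nbrs[a]
            for idx in range(indptr[u], indptr[u + 1]):
                p = pos[indices[idx]]
                if p >= 0:
                    R[a, p >> 6] |= _U1 << np.uint64(p & 63)
        total = 0.0
        sums = _bitset_invsums(R[:k, :wk], k, wk)
        for a in range(k):
            total += sums[a]
        vals[i] = total / (k * (k - 1))
        for a in range(k):
            pos[nbrs[a]] = -1
    return vals


def _to_csr(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    c = csr_array(adj.astype(np.int8))
    return c.indptr.astype(np.int32), c.indices.astype(np.int32), adj.shape[0]


def _inv_distance_sums(adj: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        indptr, indices, n = _to_csr(adj)
        return _bfs_inv_sums_csr(indptr, indices, n)
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency undefined for N < 2")
    return float(_inv_distance_sums(g.adjacency).sum() / (n * (n - 1)))


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("nodal efficiency undefined for N < 2")
    return _inv_distance_sums(g.adjacency) / (n - 1)


def _subgraph_efficiency(adj: np.ndarray, members: np.ndarray) -> float:
    """E_glob of the induced subgraph; 0 when it has fewer than 2 nodes."""
    m = len(members)
    if m < 2:
        return 0.0
    sub = adj[np.ix_(members, members)]
    return float(_inv_distance_sums(sub).sum() / (m * (m - 1)))


def local_efficiency(g: BinaryGraph, per_node: bool = False) -> float | np.ndarray:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("local efficiency undefined for N < 2")
    adj = g.adjacency
    if _HAVE_NUMBA:
        indptr, indices, _ = _to_csr(adj)
        vals = _local_eff_csr(indptr, indices, n)
    else:
        vals = np.empty(n)
        for i in range(n):
            vals[i] = _subgraph_efficiency(adj, np.flatnonzero(adj[i]))
    return vals if per_node else float(vals.mean())


def rewire_preserving_degree(
    g: BinaryGraph, n_swap_per_edge: int = 10, seed: int = 0
) -> BinaryGraph:
    """Maslov-Sneppen degree-preserving randomization.

    ``n_swap_per_edge * K`` double-edge-swap trials; trials that would
    introduce a self-loop or multi-edge are rejected, so the degree
    sequence is preserved exactly.  Rigid graphs (e.g. complete graphs)
    come back unchanged with a warning.  Backed by igraph's C rewiring,
    seeded through Python's ``random`` module.
    """
    k = g.n_edges
    if k < 2:
        raise ValueError("need at least 2 edges to rewire")
    src, dst = np.nonzero(np.triu(g.adjacency, k=1))
    graph = ig.Graph(n=g.n_nodes, edges=list(zip(src.tolist(), dst.tolist())))
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        graph.rewire(n=n_swap_per_edge * k, mode="simple")
    finally:
        _pyrandom.setstate(state)
    edges = np.asarray(graph.get_edgelist(), dtype=int)
    adj = np.zeros_like(g.adjacency)
    adj[edges[:, 0], edges[:, 1]] = True
    adj |= adj.T
    out = BinaryGraph(adj)
    if np.array_equal(out.adjacency, g.adjacency) and k > 2:
        warnings.warn("rewiring left the graph unchanged (rigid or unlucky trials)")
    return out


def build_null_ensemble(
    g: BinaryGraph,
    n_null: int = 100,
    n_swap_per_edge: int = 10,
    seed: int = 0,
    with_local: bool = True,
) -> NullEnsemble:
    """Efficiencies of ``n_null`` independent degree-matched surrogates."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_null)
    eg = np.empty(n_null)
    el = np.empty(n_null)
    for i, s in enumerate(sub_seeds):
        null = rewire_preserving_degree(g, n_swap_per_edge, int(s))
        eg[i] = global_efficiency(null)
        el[i] = local_efficiency(null) if with_local else np.nan
    return NullEnsemble(e_glob=eg, e_loc=el, seed=seed)


def normalize_against_null(
    e_glob: float, e_loc: float, ensemble: NullEnsemble
) -> tuple[float, float]:
    """Ratio of each observed efficiency to the null-ensemble mean."""
    ng = e_glob / ensemble.mean_e_glob if ensemble.mean_e_glob > 0 else float("nan")
    nl = e_loc / ensemble.mean_e_loc if ensemble.mean_e_loc > 0 else float("nan")
    if np.isnan(ng) or np.isnan(nl):
        warnings.warn("null-ensemble mean is 0; normalized efficiency undefined")
    return ng, nl


def is_small_world(
    normalized_e_loc: float, normalized_e_glob: float, tol: float = 0.1
) -> bool:
    """Normalized local efficiency > 1 with normalized global efficiency ~ 1.

    The "approximately equal to 1" clause is quantified as
    ``|normalized_e_glob - 1| <= tol`` (default 0.1).
    """
    if not (np.isfinite(normalized_e_loc) and np.isfinite(normalized_e_glob)):
        return False
    return normalized_e_loc > 1.0 and abs(normalized_e_glob - 1.0) <= tol


def auc_over_sparsity(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal area of a metric curve over the sparsity grid."""
    values = np.asarray(values, float)
    grid = np.asarray(grid, float)
    if len(values) != len(grid) or len(grid) < 2:
        raise ValueError("values and grid must share a length >= 2")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if np.isnan(values).any():
        bad = grid[np.isnan(values)]
        raise ValueError(f"NaN metric values at sparsities {bad.tolist()}")
    return float(np.trapezoid(values, grid))


def efficiency_profile(
    matrix: ConnectivityMatrix,
    sparsity_grid: np.ndarray | None = None,
    n_null: int = 0,
    null_sparsity_stride: int = 1,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> EfficiencyProfile:
    """Threshold a matrix over the grid and compute the full efficiency profile.

    ``n_null > 0`` additionally builds a degree-matched null ensemble at
    every ``null_sparsity_stride``-th grid point and records normalized
    efficiencies there (NaN at skipped points).
    """
    grid = default_sparsity_grid() if sparsity_grid is None else np.asarray(sparsity_grid)
    n_s = len(grid)
    n = matrix.n_nodes
    e_glob = np.empty(n_s)
    e_loc = np.empty(n_s)
    nodal_g = np.empty((n_s, n))
    nodal_l = np.empty((n_s, n))
    norm_g = np.full(n_s, np.nan)
    norm_l = np.full(n_s, np.nan)
    rng = np.random.default_rng(seed)
    for si, s in enumerate(grid):
        g = threshold_by_sparsity(matrix, float(s))
        e_glob[si] = global_efficiency(g)
        nodal_g[si] = nodal_efficiency(g)
        nodal_l[si] = local_efficiency(g, per_node=True)
        e_loc[si] = nodal_l[si].mean()
        if n_null > 0 and si % null_sparsity_stride == 0:
            ens = build_null_ensemble(
                g, n_null, n_swap_per_edge, seed=int(rng.integers(2**31 - 1))
            )
            norm_g[si], norm_l[si] = normalize_against_null(e_glob[si], e_loc[si], ens)
    return EfficiencyProfile(
        subject_id=matrix.subject_id,
        modality=matrix.modality,
        scale=matrix.scale,
        sparsity_grid=grid,
        e_glob=e_glob,
        e_loc=e_loc,
        nodal_glob=nodal_g,
        nodal_loc=nodal_l,
        normalized_e_glob=norm_g,
        normalized_e_loc=norm_l,
    )


def profiles_to_frame(profiles: list[EfficiencyProfile]) -> pd.DataFrame:
    """Long-format table of global curves and AUCs across subjects."""
    rows = []
    for p in profiles:
        for si, s in enumerate(p.sparsity_grid):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "modality": p.modality,
                    "scale": p.scale,
                    "sparsity": float(s),
                    "e_glob": p.e_glob[si],
                    "e_loc": p.e_loc[si],
                    "normalized_e_glob": p.normalized_e_glob[si],
                    "normalized_e_loc": p.normalized_e_loc[si],
                }
            )
    return pd.DataFrame(rows)
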
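"""Graph-theoretic characterization of binary similarity networks.

All metrics are computed on the binary adjacency matrix.  Efficiency-family
measures follow the inverse-shortest-path formulation, which degrades
gracefully on disconnected graphs (unreachable pairs contribute 1/inf = 0);
the characteristic path length instead averages over reachable pairs only
and is flagged undefined when none exist.

Conventions
-----------
* Global efficiency   E_glob = (1 / N(N-1)) * sum_{i != j} 1/d_ij
* Nodal global eff.   E_nod_glob(i) = (1 / (N-1)) * sum_{j != i} 1/d_ij
* Local efficiency    E_loc = (1/N) * sum_i E_glob(G_i), where G_i is the
  subgraph induced by the neighbors of i (i itself excluded; nodes with
  fewer than 2 neighbors contribute 0).  A variant including node i in G_i
  is available behind ``include_self=True``.
* Nodal strength      S(i) = sum_j w_ij; equals degree on binary graphs.
* Betweenness is reported unnormalized (pair counts), with a normalized
  column alongside.
* Small-worldness     sigma = (C / C_rand) / (L / L_rand) against
  degree-preserving rewired null networks.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .simnet import BinaryNetwork, CubeParcellation

__all__ = [
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_global_efficiency",
    "local_efficiency",
    "nodal_local_efficiency",
    "nodal_strength",
    "degree_centrality",
    "betweenness_centrality",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_worldness",
    "density_and_strength",
    "compute_nodal_metrics",
    "compute_global_metrics",
    "aggregate_to_rois",
]


def _adj(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(network, BinaryNetwork):
        return network.adjacency
    a = np.asarray(network, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, False)
    return a


def _graph(adj: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(adj.astype(np.uint8))


def shortest_path_lengths(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix; unreachable pairs are inf."""
    adj = _adj(network)
    if adj.shape[0] == 1:
        return np.zeros((1, 1))
    d = _csgraph_sp(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)
    return d


def _inverse_distances(adj: np.ndarray) -> np.ndarray:
    d = shortest_path_lengths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(network: BinaryNetwork | np.ndarray) -> float:
    adj = _adj(network)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    return float(_inverse_distances(adj).sum() / (n * (n - 1)))


def nodal_global_efficiency(
    network: BinaryNetwork | np.ndarray, i: int | None = None
) -> float | np.ndarray:
    """Mean inverse distance from node i to all others (vector if i is None)."""
    adj = _adj(network)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal global efficiency undefined for fewer than 2 nodes")
    e = _inverse_distances(adj).sum(axis=1) / (n - 1)
    return e if i is None else float(e[i])


def _neighbor_subgraph(adj: np.ndarray, i: int, include_self: bool) -> np.ndarray:
    nbrs = np.flatnonzero(adj[i])
    if include_self:
        nbrs = np.sort(np.append(nbrs, i))
    return adj[np.ix_(nbrs, nbrs)]


def nodal_local_efficiency(
    network: BinaryNetwork | np.ndarray, i: int | None = None,
    include_self: bool = False,
) -> float | np.ndarray:
    """Efficiency of communication among node i's neighbors.

    Computed as the global efficiency of the subgraph induced by the
    neighbors of i (node i excluded by default); nodes with fewer than two
    neighbors score 0.
    """
    adj = _adj(network)

    def one(j: int) -> float:
        sub = _neighbor_subgraph(adj, j, include_self)
        if sub.shape[0] < 2:
            return 0.0
        m = sub.shape[0]
        return float(_inverse_distances(sub).sum() / (m * (m - 1)))

    if i is not None:
        return one(i)
    return np.array([one(j) for j in range(adj.shape[0])])


def local_efficiency(
    network: BinaryNetwork | np.ndarray, include_self: bool = False
) -> float:
    adj = _adj(network)
    if adj.shape[0] < 2:
        raise ValueError("local efficiency undefined for fewer than 2 nodes")
    return float(np.mean(nodal_local_efficiency(adj, include_self=include_self)))


def nodal_strength(
    weights: np.ndarray, i: int | None = None
) -> float | np.ndarray:
    """Sum of incident edge weights; on binary adjacency this is the degree."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    s = w.sum(axis=1)
    return s if i is None else float(s[i])


def degree_centrality(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _adj(network).sum(axis=1).astype(int)


def betweenness_centrality(
    network: BinaryNetwork | np.ndarray, normalized: bool = False
) -> np.ndarray:
    """Shortest-path betweenness per node (Brandes), unnormalized by default."""
    adj = _adj(network)
    bc = nx.betweenness_centrality(_graph(adj), normalized=normalized)
    return np.array([bc[i] for i in range(adj.shape[0])])


def clustering_coefficient(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    adj = _adj(network)
    cc = nx.clustering(_graph(adj))
    return np.array([cc[i] for i in range(adj.shape[0])])


def characteristic_path_length(network: BinaryNetwork | np.ndarray) -> float:
    """Mean shortest path over reachable ordered pairs; NaN if none exist."""
    adj = _adj(network)
    d = shortest_path_lengths(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def small_worldness(
    network: BinaryNetwork | np.ndarray,
    n_null: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
) -> float:
    """sigma = (C/C_rand) / (L/L_rand) vs degree-preserving rewired nulls.

    Each null network applies ``swap_factor * n_edges`` double-edge swaps to
    a copy of the input; C_rand and L_rand are means over ``n_null`` nulls.
    """
    if n_null < 20:
        raise ValueError(f"n_null must be >= 20, got {n_null}")
    adj = _adj(network)
    n = adj.shape[0]
    n_edges = int(adj.sum() // 2)
    if n_edges == 0 or n_edges == n * (n - 1) // 2:
        raise ValueError(
            "small-worldness undefined at density 0 or 1: no degree-preserving "
            "rewiring is possible"
        )
    g = _graph(adj)
    c_obs = float(np.mean(list(nx.clustering(g).values())))
    l_obs = characteristic_path_length(adj)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_null):
        gr = g.copy()
        nswap = swap_factor * n_edges
        try:
            nx.double_edge_swap(gr, nswap=nswap, max_tries=nswap * 100,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            pass  # swap budget exhausted: use however far rewiring got
        c_rand.append(float(np.mean(list(nx.clustering(gr).values()))))
        l_rand.append(characteristic_path_length(nx.to_numpy_array(gr) > 0))
    c_rand_m = float(np.mean(c_rand))
    l_rand_m = float(np.nanmean(l_rand))
    if c_rand_m == 0 or l_rand_m == 0 or not np.isfinite(l_obs):
        return float("nan")
    return float((c_obs / c_rand_m) / (l_obs / l_rand_m))


def density_and_strength(
    network: BinaryNetwork | np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Network density and average nodal strength.

    Density = edges / possible edges.  Strength defaults to the binary
    adjacency (mean degree); pass the pre-threshold similarity matrix as
    ``weights`` for the weighted variant.
    """
    adj = _adj(network)
    n = adj.shape[0]
    possible = n * (n - 1) / 2
    dens = float(adj.sum() / 2 / possible) if possible else 0.0
    w = adj.astype(float) if weights is None else np.asarray(weights, float)
    return dens, float(np.mean(nodal_strength(w)))


def compute_nodal_metrics(
    network: BinaryNetwork | np.ndarray,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """All per-node metrics as one DataFrame (node index = row index)."""
    adj = _adj(network)
    n = adj.shape[0]
    deg = degree_centrality(adj)
    bet = betweenness_centrality(adj, normalized=False)
    norm = (n - 1) * (n - 2) / 2.0
    out = pd.DataFrame({
        "degree_centrality": deg,
        "betweenness_centrality": bet,
        "betweenness_normalized": bet / norm if norm > 0 else bet * 0.0,
        "clustering": clustering_coefficient(adj),
        "nodal_global_efficiency": nodal_global_efficiency(adj),
        "nodal_local_efficiency": nodal_local_efficiency(adj),
        "nodal_strength": nodal_strength(
            adj.astype(float) if weights is None else weights
        ),
    })
    out.index.name = "node"
    return out


def compute_global_metrics(
    network: BinaryNetwork | np.ndarray,
    weights: np.ndarray | None = None,
    include_small_world: bool = False,
    n_null: int = 100,
    seed: int = 0,
) -> dict:
    adj = _adj(network)
    dens, avg_strength = density_and_strength(adj, weights)
    out = {
        "global_efficiency": global_efficiency(adj),
        "local_efficiency": local_efficiency(adj),
        "clustering_mean": float(np.mean(clustering_coefficient(adj))),
        "char_path_length": characteristic_path_length(adj),
        "density": dens,
        "average_strength": avg_strength,
    }
    if include_small_world:
        out["sigma_small_world"] = small_worldness(adj, n_null=n_null, seed=seed)
    return out


def aggregate_to_rois(
    nodal: pd.DataFrame,
    parcellation: CubeParcellation,
    n_rois: int,
) -> pd.DataFrame:
    """Average cube-level nodal metrics within each ROI.

    Returns exactly ``n_rois`` rows indexed by ROI label 1..n_rois; cubes
    with ROI label 0 (background majority) are dropped, and ROIs without any
    member cube carry NaN (missing, not zero) with n_cubes = 0.
    """
    if len(nodal) != parcellation.n_nodes:
        raise ValueError(
            f"nodal table has {len(nodal)} rows but parcellation has "
            f"{parcellation.n_nodes} cubes"
        )
    df = nodal.copy()
    df["roi"] = parcellation.cube_roi
    df = df[df["roi"] > 0]
    agg = df.groupby("roi").mean()
    counts = df.groupby("roi").size()
    agg = agg.reindex(range(1, n_rois + 1))
    agg["n_cubes"] = counts.reindex(range(1, n_rois + 1)).fillna(0).astype(int)
    agg.index.name = "roi"
    return agg
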
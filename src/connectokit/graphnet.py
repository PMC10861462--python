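"""Graph-theoretic network attributes of thresholded connectivity matrices.

Correlation matrices (node-wise 17 x 17 or edge-wise 136 x 136) are
binarized by keeping entries whose Pearson correlation is significant at
p < alpha (t-transform with T - 2 degrees of freedom, two-sided, on |r| by
default). On the binary graph the classic attributes are computed:
clustering coefficient Cp, characteristic path length Lp (mean over
connected pairs), global efficiency Eglob (disconnected pairs contribute
0), local efficiency Eloc, degree assortativity r, Newman modularity Q of
a greedy partition, betweenness and degree centrality, and the small-world
indices gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda
against degree-preserving rewired nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

#: acceptance band for "lambda approximately 1" in the small-world criterion
LAMBDA_BAND = (0.8, 1.2)


@dataclass
class Graph:
    """Binary undirected graph without self-loops."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("self-loops not allowed")
        self.adjacency = (a != 0).astype(int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


@dataclass
class GraphMetrics:
    """Global and nodal attributes of one graph."""

    lp: float = np.nan
    eglob: float = np.nan
    eloc: float = np.nan
    cp: float = np.nan
    assortativity: float = np.nan
    modularity: float = np.nan
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan
    degree: np.ndarray | None = None
    betweenness: np.ndarray | None = None
    betweenness_raw: np.ndarray | None = None
    nodal_cp: np.ndarray | None = None
    nodal_eloc: np.ndarray | None = None
    small_world_criterion: dict = field(default_factory=dict)


def correlation_pvalues(c: np.ndarray, t_samples: int) -> np.ndarray:
    """Two-sided p-values of Pearson correlations with `t_samples` points."""
    if t_samples < 4:
        raise ValueError("need at least 4 samples")
    r = np.clip(np.asarray(c, dtype=float), -1.0, 1.0)
    df = t_samples - 2
    p = np.zeros_like(r)
    sub = np.abs(r) < 1.0
    tval = np.abs(r[sub]) * np.sqrt(df / (1.0 - r[sub] ** 2))
    p[sub] = 2.0 * stats.t.sf(tval, df)
    return p  # |r| = 1 keeps p = 0


def threshold_significant(
    c: np.ndarray,
    t_samples: int,
    alpha: float = 0.05,
    positive_only: bool = False,
) -> Graph:
    """Binarize a correlation matrix by per-entry significance at `alpha`.

    By default both signs count (significance of |r|); `positive_only`
    restricts to positive correlations.
    """
    c = np.asarray(c, dtype=float)
    p = correlation_pvalues(c, t_samples)
    adj = (p < alpha).astype(int)
    if positive_only:
        adj &= (c > 0).astype(int)
    np.fill_diagonal(adj, 0)
    adj = np.minimum(adj + adj.T, 1)
    return Graph(adjacency=adj)


def _pairwise_lp(g: nx.Graph) -> float:
    """Mean shortest path length over connected distinct pairs (else nan)."""
    total, count = 0, 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if dst != src:
                total += d
                count += 1
    return total / count if count else float("nan")


def global_metrics(g: Graph, seed: int = 0) -> GraphMetrics:
    """Global attributes (excluding the small-world indices).

    Assortativity is nan when every node has the same degree (the Pearson
    correlation of end-node degrees is then undefined). Modularity uses the
    greedy agglomerative Newman-Q partition, which is deterministic.
    """
    gx = g.to_networkx()
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    m = GraphMetrics()
    m.cp = nx.average_clustering(gx)
    m.lp = _pairwise_lp(gx)
    m.eglob = nx.global_efficiency(gx)
    nodal = nodal_metrics(g)
    m.eloc = float(np.mean(nodal.nodal_eloc))
    deg = np.array([d for _, d in gx.degree()])
    if gx.number_of_edges() > 0 and len(set(deg[deg > 0])) > 1:
        m.assortativity = float(nx.degree_assortativity_coefficient(gx))
    if gx.number_of_edges() > 0:
        comms = nx.community.greedy_modularity_communities(gx)
        m.modularity = float(nx.community.modularity(gx, comms))
    else:
        m.modularity = 0.0
    m.degree = nodal.degree
    m.betweenness = nodal.betweenness
    m.betweenness_raw = nodal.betweenness_raw
    m.nodal_cp = nodal.nodal_cp
    m.nodal_eloc = nodal.nodal_eloc
    return m


def nodal_metrics(g: Graph) -> GraphMetrics:
    """Per-node degree, betweenness (normalized + raw), Cp and Eloc."""
    gx = g.to_networkx()
    n = g.n_nodes
    out = GraphMetrics()
    out.degree = g.adjacency.sum(axis=1).astype(float)
    bc_raw = nx.betweenness_centrality(gx, normalized=False)
    bc_norm = nx.betweenness_centrality(gx, normalized=True)
    out.betweenness_raw = np.array([bc_raw[i] for i in range(n)])
    out.betweenness = np.array([bc_norm[i] for i in range(n)])
    clust = nx.clustering(gx)
    out.nodal_cp = np.array([clust[i] for i in range(n)])
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = list(gx.neighbors(i))
        if len(nbrs) >= 2:
            eloc[i] = nx.global_efficiency(gx.subgraph(nbrs))
    out.nodal_eloc = eloc
    return out


def degree_preserving_null(
    g: Graph, n_swaps: int | None = None, seed: int = 0
) -> Graph:
    """Randomized graph with the exact degree sequence (double edge swaps)."""
    gx = g.to_networkx()
    n_edges = gx.number_of_edges()
    if n_edges < 2:
        return Graph(adjacency=g.adjacency.copy())
    if n_swaps is None:
        n_swaps = 10 * n_edges
    try:
        nx.double_edge_swap(
            gx, nswap=n_swaps, max_tries=100 * n_swaps + 100, seed=seed
        )
    except nx.NetworkXException:
        pass  # too few swappable edges (e.g. a triangle or near-complete
        # graph); whatever swaps succeeded are kept
    return Graph(adjacency=nx.to_numpy_array(gx, nodelist=range(g.n_nodes)))


def small_world(
    g: Graph, n_null: int = 100, seed: int = 0
) -> tuple[float, float, float, dict]:
    """Small-world indices against a degree-preserving null ensemble.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda.
    The returned criterion records gamma > 1, lambda within the accepted
    band and sigma > 1.
    """
    gx = g.to_networkx()
    cp = nx.average_clustering(gx)
    lp = _pairwise_lp(gx)
    cps, lps = [], []
    for i in range(n_null):
        null = degree_preserving_null(g, seed=seed + i)
        nxg = null.to_networkx()
        cps.append(nx.average_clustering(nxg))
        lps.append(_pairwise_lp(nxg))
    cp_null = float(np.mean(cps))
    lp_null = float(np.nanmean(lps))
    gamma = cp / cp_null if cp_null > 0 else float("nan")
    lam = lp / lp_null if lp_null > 0 else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) else float("nan")
    criterion = {
        "gamma_gt_1": bool(gamma > 1),
        "lambda_near_1": bool(LAMBDA_BAND[0] <= lam <= LAMBDA_BAND[1]),
        "sigma_gt_1": bool(sigma > 1),
    }
    return gamma, lam, sigma, criterion


def graph_metrics(
    c: np.ndarray,
    t_samples: int,
    alpha: float = 0.05,
    n_null: int = 100,
    seed: int = 0,
) -> GraphMetrics:
    """Threshold a correlation matrix and compute all attributes."""
    g = threshold_significant(c, t_samples, alpha)
    m = global_metrics(g, seed=seed)
    m.gamma, m.lam, m.sigma, m.small_world_criterion = small_world(
        g, n_null=n_null, seed=seed
    )
    return m
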
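"""Community structure of the edge-wise functional network.

The E = K(K-1)/2 edges are grouped into communities in two steps:

1. the number of modules is selected by recursive Newman spectral
   bipartitioning of the signed modularity matrix of the eFC matrix,
   splitting while the modularity gain is positive;
2. the edges are partitioned into that many communities by k-means on the
   eFC rows under correlation distance (1 - Pearson), with farthest-point
   reseeding of empty clusters and multiple restarts.

Communities are mapped back to the K networks by counting, for every
community, how many member edges touch each network (each edge contributes
its two endpoint networks), and community-level FC is the correlation
between the mean member edge time series of each community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import EdgeTimeSeries, EfcMatrix


@dataclass
class EdgeCommunities:
    """Community assignment of the E edges (labels in 0..k-1)."""

    labels: np.ndarray
    k: int
    network_counts: np.ndarray | None = None  # K x k incidence counts

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels out of range")


# ---------------------------------------------------------------------------
# module-count selection: signed spectral modularity
# ---------------------------------------------------------------------------

def _signed_modularity_matrix(w: np.ndarray) -> np.ndarray:
    """B = B+ - B- for a signed weight matrix (diagonal removed).

    B+/- are the Newman modularity matrices of the positive / negative
    parts: B+-_ij = W+-_ij - s_i s_j / (2 m+-).
    """
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    wp = np.clip(w, 0, None)
    wn = np.clip(-w, 0, None)
    b = np.zeros_like(w)
    for part, sign in ((wp, 1.0), (wn, -1.0)):
        two_m = part.sum()
        if two_m > 0:
            s = part.sum(axis=1)
            b += sign * (part - np.outer(s, s) / two_m)
    return b


def _fine_tune(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Newman's vertex-moving refinement of a bipartition sign vector.

    Greedy passes flip the single vertex that most increases s^T B s until
    no flip helps. Flipping vertex i changes the quadratic form by
    -4 s_i (B s)_i (B has zero diagonal after the subdivision correction
    is folded in separately), computed here exactly via the update below.
    """
    s = s.copy()
    improved = True
    while improved:
        improved = False
        bs = bg @ s
        # exact gain of flipping i: -4 s_i bs_i + 4 B_ii (diag handled exactly)
        gains = -4.0 * s * bs + 4.0 * np.diag(bg)
        i = int(np.argmax(gains))
        if gains[i] > 1e-12:
            s[i] = -s[i]
            improved = True
    return s


def _split(b: np.ndarray, idx: np.ndarray, out: list[np.ndarray],
           tol: float) -> None:
    """Recursive spectral bipartition on the generalized modularity matrix."""
    if idx.size <= 1:
        out.append(idx)
        return
    bg = b[np.ix_(idx, idx)].copy()
    bg -= np.diag(bg.sum(axis=1))  # Newman's subdivision correction
    vals, vecs = np.linalg.eigh(bg)
    lead = vecs[:, -1]
    if vals[-1] <= tol:
        out.append(idx)
        return
    s = np.where(lead >= 0, 1.0, -1.0)
    s = _fine_tune(bg, s)
    gain = s @ bg @ s
    if gain <= tol or (s > 0).all() or (s < 0).all():
        out.append(idx)
        return
    _split(b, idx[s > 0], out, tol)
    _split(b, idx[s < 0], out, tol)


def spectral_modules(efc, tol: float = 1e-9) -> np.ndarray:
    """Module labels from recursive signed spectral modularity optimization."""
    w = efc.values if isinstance(efc, EfcMatrix) else np.asarray(efc, float)
    if np.ptp(w) < 1e-15:
        raise ValueError("constant matrix; no modular structure to find")
    b = _signed_modularity_matrix(w)
    scale = max(np.abs(b).sum(), 1.0)
    groups: list[np.ndarray] = []
    _split(b, np.arange(w.shape[0]), groups, tol * scale)
    labels = np.empty(w.shape[0], dtype=int)
    for c, idx in enumerate(groups):
        labels[idx] = c
    return labels


def optimal_module_count(efc) -> int:
    """Number of modules found by the spectral modularity recursion."""
    return int(spectral_modules(efc).max()) + 1


# ---------------------------------------------------------------------------
# modified k-means under correlation distance
# ---------------------------------------------------------------------------

def _corr_dist(rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson between every row and every centroid."""
    def standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        n = np.linalg.norm(a, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return a / n

    return 1.0 - standardize(rows) @ standardize(centroids).T


def edge_kmeans(
    efc,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 100,
) -> EdgeCommunities:
    """Cluster eFC rows into k communities by correlation-distance k-means.

    Centroids are mean member rows; an emptied cluster is reseeded at the
    point farthest from its current centroid; the best of `n_restarts`
    seeded restarts (lowest total within-cluster distance) is returned.
    """
    rows = efc.values if isinstance(efc, EfcMatrix) else np.asarray(efc, float)
    e = rows.shape[0]
    if k > e:
        raise ValueError("k exceeds number of edges")
    if k == 1:
        return EdgeCommunities(labels=np.zeros(e, dtype=int), k=1)
    rng = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(n_restarts):
        centroids = rows[rng.choice(e, size=k, replace=False)].copy()
        labels = np.zeros(e, dtype=int)
        for _ in range(max_iter):
            d = _corr_dist(rows, centroids)
            new_labels = d.argmin(axis=1)
            for c in range(k):
                if not (new_labels == c).any():
                    # reseed at the point farthest from its assigned centroid
                    cand = d[np.arange(e), new_labels].copy()
                    counts = np.bincount(new_labels, minlength=k)
                    cand[counts[new_labels] <= 1] = -np.inf
                    new_labels[int(cand.argmax())] = c
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if members.any():
                    centroids[c] = rows[members].mean(axis=0)
        cost = float(_corr_dist(rows, centroids)[np.arange(e), labels].sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels.copy()
    return EdgeCommunities(labels=best_labels, k=k)


def community_network_counts(
    labels: np.ndarray, edges: list[tuple[int, int]], k_networks: int
) -> np.ndarray:
    """K x k counts of how often each network appears in each community.

    Every edge contributes its two endpoint networks to its community, so
    each column sums to twice the community size.
    """
    labels = np.asarray(labels, dtype=int)
    n_comm = int(labels.max()) + 1
    counts = np.zeros((k_networks, n_comm), dtype=int)
    for (i, j), c in zip(edges, labels):
        counts[i, c] += 1
        counts[j, c] += 1
    return counts


def community_fc(
    ets: EdgeTimeSeries,
    communities: EdgeCommunities,
    tc=None,
    basis: str = "edge",
) -> np.ndarray:
    """k x k Pearson correlations between community representative series.

    With the default edge basis a community's representative is the mean of
    its member edge time series. The alternative node basis averages the
    node time courses of the networks its edges touch (requires `tc`).
    """
    k = communities.k
    reps = np.zeros((k, ets.n_frames))
    for c in range(k):
        members = communities.labels == c
        if basis == "edge":
            reps[c] = ets.ets[members].mean(axis=0)
        elif basis == "node":
            if tc is None:
                raise ValueError("node basis requires network time courses")
            x = np.asarray(getattr(tc, "tc", tc), dtype=float)
            nets = sorted(
                {n for (i, j), m in zip(ets.edges, members) if m
                 for n in (i, j)}
            )
            reps[c] = x[:, nets].mean(axis=1)
        else:
            raise ValueError("basis must be 'edge' or 'node'")
    if k == 1:
        return np.ones((1, 1))
    from .connectivity import _safe_corrcoef

    return _safe_corrcoef(reps, "community_fc")
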
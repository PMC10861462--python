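"""Node-wise and edge-centric functional network connectivity.

From a subject's K network time courses this module derives:

* the K x K functional network connectivity (FNC) matrix of Pearson
  correlations between node series;
* the E = K(K-1)/2 edge time series, the per-frame products of the two
  z-scored node series of each network pair — with population (1/T)
  variance scaling the time average of an edge series equals the Pearson
  correlation of its node pair;
* the E x E edge-wise FC (eFC) matrix of correlations between edge series;
* the root-sum-square (RSS) co-fluctuation amplitude per frame, its
  top/bottom tails, and the transition counts between bottom/normal/top
  amplitude levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

LEVELS = ("B", "N", "T")  # bottom, normal, top amplitude levels


def edge_index_map(k: int) -> list[tuple[int, int]]:
    """Ordered (i, j), i < j network pairs in lexicographic order."""
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


@dataclass
class FncMatrix:
    """K x K Pearson correlation matrix between network time courses."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FNC must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FNC must be symmetric")
        if (np.abs(v) > 1 + 1e-10).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.k, 1)
        return self.values[iu]


@dataclass
class EdgeTimeSeries:
    """E x T co-fluctuation matrix; row e corresponds to `edges[e]`."""

    ets: np.ndarray
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.ets = np.asarray(self.ets, dtype=float)
        if self.ets.shape[0] != len(self.edges):
            raise ValueError("row count must equal number of edge pairs")

    @property
    def n_edges(self) -> int:
        return self.ets.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ets.shape[1]


@dataclass
class EfcMatrix:
    """E x E Pearson correlation matrix between edge time series."""

    values: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RssProfile:
    """Per-frame co-fluctuation amplitude with tail sets and level labels."""

    rss: np.ndarray
    top: np.ndarray
    bottom: np.ndarray
    labels: np.ndarray  # array of "B"/"N"/"T" per frame

    def __post_init__(self) -> None:
        if np.intersect1d(self.top, self.bottom).size:
            raise ValueError("top and bottom sets must be disjoint")


def _safe_corrcoef(rows: np.ndarray, what: str) -> np.ndarray:
    """Pearson correlations between rows; constant rows zeroed, warned."""
    sd = rows.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%s: %d constant series zeroed", what, int(const.sum()))
    safe = rows.copy()
    safe[const] = np.random.default_rng(0).standard_normal(rows.shape[1])
    c = np.corrcoef(safe)
    c[const, :] = 0.0
    c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def node_fnc(tc) -> FncMatrix:
    """K x K FNC: Pearson correlations between the network time courses."""
    x = np.asarray(getattr(tc, "tc", tc), dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    return FncMatrix(values=_safe_corrcoef(x.T, "node_fnc"))


def edge_time_series(tc) -> EdgeTimeSeries:
    """Per-frame products of z-scored node series for every pair i < j.

    Columns are z-scored with population (1/T) variance so that the time
    mean of edge (i, j) equals the Pearson correlation r(i, j).
    """
    x = np.asarray(getattr(tc, "tc", tc), dtype=float)
    t, k = x.shape
    if t < 3:
        raise ValueError("need at least 3 frames")
    sd = x.std(axis=0)  # population convention
    if (sd == 0).any():
        raise ValueError("zero-variance network time course")
    z = (x - x.mean(axis=0)) / sd
    edges = edge_index_map(k)
    ii = np.array([e[0] for e in edges])
    jj = np.array([e[1] for e in edges])
    return EdgeTimeSeries(ets=(z[:, ii] * z[:, jj]).T, edges=edges)


def edge_fnc(ets: EdgeTimeSeries) -> EfcMatrix:
    """E x E eFC: Pearson correlations between the edge time series."""
    return EfcMatrix(
        values=_safe_corrcoef(ets.ets, "edge_fnc"), edges=list(ets.edges)
    )


def rss_profile(ets: EdgeTimeSeries, frac: float = 0.05) -> RssProfile:
    """Root-sum-square amplitude per frame with top/bottom `frac` tails.

    The tail size is k = ceil(frac * T) frames; ties are broken in favour of
    the earlier frame. Frames are labelled B (bottom), T (top) or N.
    """
    if not (0 < frac < 0.5):
        raise ValueError("frac must be in (0, 0.5)")
    rss = np.sqrt(np.sum(ets.ets**2, axis=0))
    t = rss.size
    k = math.ceil(frac * t)
    order = np.argsort(rss, kind="stable")        # ascending; earlier wins ties
    bottom = np.sort(order[:k])
    desc = np.argsort(-rss, kind="stable")        # descending; earlier wins ties
    top = np.sort(desc[:k])
    labels = np.full(t, "N", dtype="<U1")
    labels[bottom] = "B"
    labels[top] = "T"
    return RssProfile(rss=rss, top=top, bottom=bottom, labels=labels)


def tail_amplitude(profile: RssProfile, which: str) -> float:
    """Mean RSS over the chosen tail ("top" or "bottom")."""
    if which == "top":
        return float(profile.rss[profile.top].mean())
    if which == "bottom":
        return float(profile.rss[profile.bottom].mean())
    raise ValueError("which must be 'top' or 'bottom'")


def count_transitions(labels: np.ndarray) -> np.ndarray:
    """3 x 3 transition counts between B/N/T levels (row = from, col = to).

    Rows and columns follow the order B, N, T; self-transitions count; the
    total equals T - 1.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    idx = {lev: i for i, lev in enumerate(LEVELS)}
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        counts[idx[str(a)], idx[str(b)]] += 1
    return counts
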
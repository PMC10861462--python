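"""Personalized functional network mapping via spatially regularized NMF.

The decomposition writes a subject's normalized time x voxel matrix X as
W H with W (T x K) the network time courses and H (K x V) the non-negative
spatial loadings, minimizing

    ||X - W H||_F^2 + beta * tr(H L H^T) + alpha * ||H - H_prior||_F^2

where L is the graph Laplacian of the voxel adjacency (spatial smoothness)
and H_prior is a group atlas used as a personalization anchor (alpha = 0
when no prior is given). The default solver alternates per-component
non-negative least-squares sweeps (HALS); a Lee-Seung multiplicative
variant with the same two penalties is available and serves as a monotone
fallback, so the recorded objective trace is always non-increasing.

The group stage concatenates many subjects along time, decomposes with
several random restarts, and fuses the restart atlases into a consensus by
spectral clustering of their rows.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import SpectralClustering

logger = logging.getLogger(__name__)

_EPS = 1e-12  # denominator floor in multiplicative updates


@dataclass
class NetworkAtlas:
    """K x V non-negative spatial loading (probability-like) matrix."""

    loadings: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be (K, V)")
        if (self.loadings < 0).any():
            raise ValueError("loadings must be non-negative")
        if (self.loadings.sum(axis=1) == 0).any():
            raise ValueError("atlas contains an all-zero network row")

    @property
    def n_networks(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.loadings.shape[1]


@dataclass
class NetworkTimecourses:
    """T x K non-negative network activation series (NMF factor W)."""

    tc: np.ndarray

    def __post_init__(self) -> None:
        self.tc = np.asarray(self.tc, dtype=float)
        if self.tc.ndim != 2:
            raise ValueError("tc must be (T, K)")
        if (self.tc < 0).any():
            raise ValueError("tc must be non-negative")


@dataclass
class NmfConfig:
    """Decomposition settings.

    `beta` and `alpha` are relative weights: the effective penalties are
    beta * ||X||_F^2 / V and alpha * ||X||_F^2 / V so regularization scales
    with the data energy.
    """

    k: int = 17
    beta: float = 1e-5
    alpha: float = 1e-1
    max_iter: int = 500
    tol: float = 1e-5
    repeats: int = 50
    init_seed: int = 0
    solver: str = "hals"  # "hals" (default) or "mu"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.solver not in ("hals", "mu"):
            raise ValueError("solver must be 'hals' or 'mu'")


@dataclass
class NmfResult:
    w: np.ndarray
    h: np.ndarray
    objective: list[float] = field(default_factory=list)


def normalize_nonnegative(signal: np.ndarray) -> np.ndarray:
    """Shift each voxel series to be non-negative and scale to [0, 1].

    Per voxel: subtract the minimum, then divide by the resulting maximum.
    Constant voxels map to all-zeros.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.min(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return x / mx


def build_voxel_graph(coords: np.ndarray, neighborhood: int = 6) -> sp.csr_matrix:
    """Graph Laplacian L = D - A of the voxel adjacency on an integer grid.

    `neighborhood` selects 6 (faces), 18 (faces+edges) or 26 (full cube)
    connectivity. L is symmetric with zero row sums; isolated voxels give
    zero rows.
    """
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (V, 3) integer grid positions")
    if neighborhood not in (6, 18, 26):
        raise ValueError("neighborhood must be 6, 18 or 26")
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue  # keep one orientation per pair
                order = abs(dx) + abs(dy) + abs(dz)
                if neighborhood == 6 and order > 1:
                    continue
                if neighborhood == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols = [], []
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                rows += [i, j]
                cols += [j, i]
    v = len(coords)
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(v, v))
    d = sp.diags(np.asarray(a.sum(axis=1)).ravel())
    return (d - a).tocsr()


def grid_coords(n_voxels: int) -> np.ndarray:
    """Row-major coordinates of `n_voxels` points on a near-cubic grid."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    grid = np.stack(
        np.meshgrid(*([np.arange(side)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return grid[:n_voxels]


def _objective(
    xt: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
    beta_eff: float,
    laplacian: sp.spmatrix | None,
    alpha_eff: float,
    h_prior: np.ndarray | None,
) -> float:
    val = float(np.linalg.norm(xt - w @ h) ** 2)
    if beta_eff > 0 and laplacian is not None:
        val += beta_eff * float(np.sum(h * (laplacian @ h.T).T))
    if alpha_eff > 0 and h_prior is not None:
        val += alpha_eff * float(np.linalg.norm(h - h_prior) ** 2)
    return val


def _rescale(w: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix scale indeterminacy: max-normalize rows of H, rescale W inversely."""
    scale = h.max(axis=1)
    scale[scale == 0] = 1.0
    return w * scale[None, :], h / scale[:, None]


def nmf_decompose(
    x: np.ndarray,
    cfg: NmfConfig,
    h_init: np.ndarray | None = None,
    w_init: np.ndarray | None = None,
    h_prior: np.ndarray | None = None,
    laplacian: sp.spmatrix | None = None,
    rng: np.random.Generator | None = None,
) -> NmfResult:
    """Regularized NMF by alternating non-negative updates (HALS or MU).

    Parameters
    ----------
    x : (V, T) non-negative matrix (transposed internally to T x V).
    h_prior : optional (K, V) group atlas; activates the alpha penalty.
    laplacian : optional sparse (V, V) Laplacian; activates the beta penalty.

    Returns W (T x K), H (K x V) and the per-iteration objective trace
    (which is non-increasing). After convergence H rows are max-normalized
    and W rescaled inversely, leaving the product W H unchanged.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("X must be non-negative")
    xt = np.ascontiguousarray(x.T)  # T x V
    t, v = xt.shape
    k = cfg.k
    if laplacian is not None and laplacian.shape != (v, v):
        raise ValueError("Laplacian dimension mismatch")
    if h_prior is not None and h_prior.shape != (k, v):
        raise ValueError("prior shape must be (K, V)")

    scale = float(np.sum(xt**2)) / v
    beta_eff = cfg.beta * scale if laplacian is not None else 0.0
    alpha_eff = cfg.alpha * scale if h_prior is not None else 0.0

    if rng is None:
        rng = np.random.default_rng(cfg.init_seed)
    mean = max(xt.mean(), _EPS)
    w = np.abs(w_init).astype(float) if w_init is not None else rng.uniform(
        0, np.sqrt(mean / k), size=(t, k))
    h = np.abs(h_init).astype(float) if h_init is not None else rng.uniform(
        0, 1.0, size=(k, v))

    adj = deg_vec = None
    if beta_eff > 0:
        lap = laplacian.tocsr()
        deg_vec = lap.diagonal()
        adj = (sp.diags(deg_vec) - lap).tocsr()  # A = D - L

    def mu_step(w: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lee-Seung multiplicative update extended with both penalties
        (each factor's auxiliary-function bound makes it non-increasing)."""
        num = xt @ h.T
        den = w @ (h @ h.T) + _EPS
        w = w * (num / den)
        num = w.T @ xt
        den = (w.T @ w) @ h + _EPS
        if beta_eff > 0:
            num = num + beta_eff * (adj @ h.T).T
            den = den + beta_eff * h * deg_vec[None, :]
        if alpha_eff > 0:
            num = num + alpha_eff * h_prior
            den = den + alpha_eff * h
        h = h * (num / den)
        return w, h

    def hals_step(w: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-component alternating least squares (Gauss-Seidel sweeps);
        the Laplacian coupling uses the D/A splitting at the current H."""
        hht = h @ h.T
        xht = xt @ h.T
        for c in range(k):
            num = xht[:, c] - w @ hht[:, c] + w[:, c] * hht[c, c]
            w[:, c] = np.maximum(num / max(hht[c, c], _EPS), 0.0)
            if not w[:, c].any():
                w[:, c] = _EPS  # keep dead components revivable
        wtw = w.T @ w
        wtx = w.T @ xt
        for c in range(k):
            num = wtx[c] - wtw[c] @ h + wtw[c, c] * h[c]
            den = np.full(v, wtw[c, c])
            if beta_eff > 0:
                num = num + beta_eff * (adj @ h[c])
                den = den + beta_eff * deg_vec
            if alpha_eff > 0:
                num = num + alpha_eff * h_prior[c]
                den = den + alpha_eff
            h[c] = np.maximum(num / np.maximum(den, _EPS), 0.0)
            if not h[c].any():
                h[c] = _EPS
        return w, h

    obj = [_objective(xt, w, h, beta_eff, laplacian, alpha_eff, h_prior)]
    slack = 1e-10
    for _ in range(cfg.max_iter):
        w_prev, h_prev = w.copy(), h.copy()
        if cfg.solver == "hals":
            w, h = hals_step(w, h)
            new = _objective(xt, w, h, beta_eff, laplacian, alpha_eff, h_prior)
            if new > obj[-1] * (1 + slack) + slack:
                # rare: splitting approximation increased the objective;
                # redo the iteration with the monotone multiplicative step
                w, h = mu_step(w_prev, h_prev)
                new = _objective(xt, w, h, beta_eff, laplacian, alpha_eff,
                                 h_prior)
        else:
            w, h = mu_step(w, h)
            new = _objective(xt, w, h, beta_eff, laplacian, alpha_eff, h_prior)
        obj.append(new)
        if abs(obj[-2] - obj[-1]) <= cfg.tol * max(abs(obj[-2]), _EPS):
            break
    w, h = _rescale(w, h)
    return NmfResult(w=w, h=h, objective=obj)


def _subject_rng(cfg: NmfConfig, tag: str) -> np.random.Generator:
    salt = zlib.crc32(tag.encode()) & 0x7FFFFFFF
    return np.random.default_rng((cfg.init_seed, salt))


def group_initialize(
    scans: list,
    cfg: NmfConfig,
    laplacian: sp.spmatrix | None = None,
    max_subjects: int = 50,
) -> list[NetworkAtlas]:
    """Group network initialization: repeated NMF of a concatenated matrix.

    Normalized subject matrices are concatenated along time (up to
    `max_subjects` subjects, sampled without replacement when more are
    available) and decomposed `cfg.repeats` times with fresh random
    non-negative initializations; each repeat's H is returned.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    v = scans[0].signal.shape[0]
    if any(s.signal.shape[0] != v for s in scans):
        raise ValueError("subjects have mismatched voxel counts")
    rng = np.random.default_rng(cfg.init_seed)
    use = scans
    if len(scans) > max_subjects:
        idx = rng.choice(len(scans), size=max_subjects, replace=False)
        use = [scans[i] for i in sorted(idx)]
    big = np.vstack([normalize_nonnegative(s.signal).T for s in use])  # sumT x V
    atlases = []
    for _ in range(cfg.repeats):
        res = nmf_decompose(big.T, cfg, laplacian=laplacian, rng=rng)
        atlases.append(NetworkAtlas(loadings=np.maximum(res.h, 0)))
    return atlases


def consensus_atlas(
    atlases: list[NetworkAtlas], k: int | None = None, seed: int = 0,
    max_retries: int = 5,
) -> NetworkAtlas:
    """Fuse repeat atlases into one consensus atlas by spectral clustering.

    All rows of all repeats are pooled and clustered into K groups using
    spectral clustering on the pairwise-correlation similarity; the
    consensus row of a cluster is the mean of its members, max-rescaled.
    An empty cluster triggers a re-run with a new seed (up to a cap).
    """
    if not atlases:
        raise ValueError("no atlases given")
    k = k if k is not None else atlases[0].n_networks
    v = atlases[0].n_voxels
    if any(a.n_voxels != v for a in atlases):
        raise ValueError("atlases have mismatched voxel counts")
    rows = np.vstack([a.loadings for a in atlases])
    if len(atlases) == 1:
        return NetworkAtlas(loadings=_max_rescale(rows))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rows)
    corr = np.nan_to_num(corr, nan=0.0)
    affinity = (corr + 1.0) / 2.0
    for attempt in range(max_retries):
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed",
            random_state=seed + attempt, assign_labels="kmeans",
        )
        labels = sc.fit_predict(affinity)
        sizes = np.bincount(labels, minlength=k)
        if (sizes > 0).all():
            break
        logger.warning("empty consensus cluster; retrying (%d)", attempt + 1)
    else:
        raise RuntimeError("spectral clustering produced empty clusters")
    cons = np.vstack([rows[labels == c].mean(axis=0) for c in range(k)])
    return NetworkAtlas(loadings=_max_rescale(cons))


def _max_rescale(h: np.ndarray) -> np.ndarray:
    mx = h.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return h / mx


def personalize(
    scan,
    group_atlas: NetworkAtlas,
    cfg: NmfConfig,
    laplacian: sp.spmatrix | None = None,
) -> tuple[NetworkTimecourses, NetworkAtlas]:
    """Subject-level decomposition anchored on the group atlas.

    The subject's normalized matrix is decomposed with H initialized at the
    group atlas and the prior penalty active, so row k of the subject atlas
    stays in correspondence with row k of the group atlas.
    """
    if scan.signal.shape[0] != group_atlas.n_voxels:
        raise ValueError("voxel count mismatch with group atlas")
    x = normalize_nonnegative(scan.signal)
    rng = _subject_rng(cfg, str(scan.subject_id))
    res = nmf_decompose(
        x, cfg,
        h_init=group_atlas.loadings.copy(),
        h_prior=group_atlas.loadings,
        laplacian=laplacian,
        rng=rng,
    )
    return NetworkTimecourses(tc=res.w), NetworkAtlas(loadings=res.h)


def assign_voxels(atlas: NetworkAtlas) -> np.ndarray:
    """Label each voxel by the network with maximum loading.

    Ties go to the lowest network index (argmax convention, logged).
    """
    h = atlas.loadings
    labels = np.argmax(h, axis=0)
    n_ties = int((np.sum(h == h.max(axis=0, keepdims=True), axis=0) > 1).sum())
    if n_ties:
        logger.info("assign_voxels: %d voxels had tied loadings "
                    "(assigned to lowest index)", n_ties)
    return labels


def reconstruction_accuracy(
    scans: list,
    tcs: list[NetworkTimecourses],
    atlases: list[NetworkAtlas],
    labels: np.ndarray,
) -> np.ndarray:
    """Per-network mean Pearson r between original and reconstructed signal.

    For each subject the normalized signal is compared voxel-wise with the
    reconstruction (W H); correlations are averaged over all voxels assigned
    to each network and over subjects. Constant series contribute r = 0.
    """
    k = atlases[0].n_networks
    sums = np.zeros(k)
    counts = np.zeros(k)
    for scan, tc, atlas in zip(scans, tcs, atlases):
        x = normalize_nonnegative(scan.signal)
        recon = (tc.tc @ atlas.loadings).T  # V x T
        xc = x - x.mean(axis=1, keepdims=True)
        rc = recon - recon.mean(axis=1, keepdims=True)
        num = np.sum(xc * rc, axis=1)
        den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(rc**2, axis=1))
        r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        for net in range(k):
            mask = labels == net
            sums[net] += r[mask].sum()
            counts[net] += mask.sum()
    counts[counts == 0] = 1.0
    return sums / counts


def network_variability(
    subject_atlases: list[NetworkAtlas],
) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject median absolute deviation of the spatial loadings.

    Returns the (K, V) MAD map (median over subjects of the absolute
    deviation from the across-subject median loading) and its per-voxel
    summary, the mean over the K networks.
    """
    stack = np.stack([a.loadings for a in subject_atlases])  # S x K x V
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)
    return mad, mad.mean(axis=0)


def label_networks(
    atlas: NetworkAtlas, reference_labels: np.ndarray
) -> dict[int, str]:
    """Name each network by its best-overlap (Dice) reference label.

    `reference_labels` holds one canonical name per voxel. Networks sharing
    a best name are suffixed -1, -2, ... in order of descending total
    loading mass.
    """
    reference_labels = np.asarray(reference_labels)
    assigned = assign_voxels(atlas)
    names = []
    for k in range(atlas.n_networks):
        mine = assigned == k
        best_name, best_dice = None, -1.0
        for ref in np.unique(reference_labels):
            theirs = reference_labels == ref
            denom = mine.sum() + theirs.sum()
            dice = 2.0 * np.sum(mine & theirs) / denom if denom else 0.0
            if dice > best_dice:
                best_name, best_dice = str(ref), dice
        names.append(best_name)
    mass = atlas.loadings.sum(axis=1)
    out: dict[int, str] = {}
    for name in set(names):
        ks = [k for k in range(atlas.n_networks) if names[k] == name]
        if len(ks) == 1:
            out[ks[0]] = name
        else:
            ks.sort(key=lambda k: -mass[k])
            for i, k in enumerate(ks, start=1):
                out[k] = f"{name}-{i}"
    return out
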
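"""Synthetic multi-subject resting-state cohorts with known ground truth.

Generates cohorts with the statistical structure the downstream analysis
assumes: K latent networks with subject-specific non-negative spatial
loadings over V voxels, latent network time series drawn from group- and
subject-specific covariance matrices with AR(1) temporal smoothing,
additive voxel noise at a stated SNR, random-walk head-motion traces scaled
to a per-group mean framewise displacement, and clinical scores generated
from true network metrics at target correlations.

Every quantity the pipeline later estimates (atlas, network covariance,
planted group effects, edge-community structure) is recorded in a
GroundTruth object so parameter recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netmap import NetworkAtlas, grid_coords
from .preprocess import SubjectScan, compute_fd

_SPD_FLOOR = 1e-6


@dataclass
class CohortDesign:
    """Declarative description of a synthetic cohort.

    Defaults mirror the emulated study conditions: 180-frame scans at
    TR = 2 s, K = 17 networks, four diagnostic groups. `fnc_effects` plants
    group-specific network-covariance shifts as (group, (i, j), delta);
    `clinical_links` requests score columns correlated with a true metric
    ("fnc:i:j" for a network-pair correlation, or "mean_fd") at a target r.
    """

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("TD", 15), ("ASD", 15),
                                 ("ADHD-C", 15), ("ADHD-I", 15)]
    )
    n_voxels: int = 2000
    k: int = 17
    t_raw: int = 180
    tr: float = 2.0
    fnc_effects: list[tuple[str, tuple[int, int], float]] = field(
        default_factory=list
    )
    motion_level: dict[str, float] = field(default_factory=dict)
    clinical_links: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    # generator conditions (see docs/methods.md)
    ar_coeff: float = 0.3          # AR(1) smoothness of latent series
    snr: float = 2.0               # voxel signal RMS / noise sd
    base_corr: float = 0.1         # baseline off-diagonal latent correlation
    subject_cov_jitter: float = 0.05   # sd of subject-level covariance noise
    subject_map_jitter: float = 0.1    # sd of subject-level loading noise
    nuisance_weight: float = 0.3       # global-signal coupling strength
    n_edge_modules: int | None = None  # planted edge-community count

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} needs >= 2 subjects")
        if self.n_voxels < self.k:
            raise ValueError("V must be >= K")
        for grp, (i, j), delta in self.fnc_effects:
            if grp not in dict(self.groups):
                raise ValueError(f"effect on unknown group {grp!r}")
            if not (0 < abs(delta) < 1):
                raise ValueError("covariance delta must satisfy 0 < |d| < 1")
            if not (0 <= i < self.k and 0 <= j < self.k and i != j):
                raise ValueError("effect pair out of range")

    @property
    def group_labels(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass
class SubjectTruth:
    """Per-subject generative parameters recorded for recovery scoring."""

    loadings: np.ndarray          # K x V subject-specific spatial maps
    cov: np.ndarray               # K x K latent covariance
    group: str


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    design: CohortDesign
    atlas: NetworkAtlas
    voxel_coords: np.ndarray
    group_cov: dict[str, np.ndarray]
    edge_partition: np.ndarray | None = None
    clinical_coeffs: list[tuple[str, str, float]] = field(default_factory=list)
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)


def _project_spd(m: np.ndarray, floor: float = _SPD_FLOOR) -> np.ndarray:
    """Nearest-eigenvalue SPD projection: clip eigenvalues at a floor."""
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _base_covariance(k: int, base_corr: float) -> np.ndarray:
    cov = np.full((k, k), base_corr)
    np.fill_diagonal(cov, 1.0)
    return cov


def make_ground_truth(design: CohortDesign) -> GroundTruth:
    """Build the generative atlas, group covariances and planted structure.

    The atlas partitions the V voxels into K contiguous blocks (row-major
    over a near-cubic grid); each voxel's dominant loading is its block's
    network, with weaker random cross-loadings elsewhere. Group covariances
    are a shared base matrix plus the planted deltas, projected back to SPD;
    a planted delta that the projection cannot essentially preserve raises.
    """
    rng = np.random.default_rng(design.seed)
    k, v = design.k, design.n_voxels

    blocks = np.array_split(np.arange(v), k)
    h = 0.25 * rng.uniform(size=(k, v))      # weak cross-loadings
    for net, block in enumerate(blocks):
        h[net, block] = 0.7 + 0.3 * rng.uniform(size=block.size)
    atlas = NetworkAtlas(loadings=h)

    base = _base_covariance(k, design.base_corr)
    group_cov: dict[str, np.ndarray] = {}
    for label in design.group_labels:
        target = base.copy()
        for grp, (i, j), delta in design.fnc_effects:
            if grp == label:
                target[i, j] += delta
                target[j, i] += delta
        cov = _project_spd(target)
        for grp, (i, j), delta in design.fnc_effects:
            if grp == label and abs(cov[i, j] - target[i, j]) > 0.5 * abs(delta):
                raise ValueError(
                    f"planted delta on {label}:{(i, j)} destroyed by SPD "
                    "projection; reduce |delta| or base correlation"
                )
        group_cov[label] = cov

    edge_partition = None
    if design.n_edge_modules is not None:
        n_edges = k * (k - 1) // 2
        edge_partition = np.arange(n_edges) % design.n_edge_modules
        rng.shuffle(edge_partition)

    return GroundTruth(
        design=design,
        atlas=atlas,
        voxel_coords=grid_coords(v),
        group_cov=group_cov,
        edge_partition=edge_partition,
        clinical_coeffs=list(design.clinical_links),
    )


def _ar1_latent(
    cov: np.ndarray, t: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """T x K latent draws: AR(1) in time, stationary covariance = cov."""
    chol = np.linalg.cholesky(cov)
    k = cov.shape[0]
    innov = rng.standard_normal((t, k)) @ chol.T
    z = np.empty((t, k))
    z[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for i in range(1, t):
        z[i] = phi * z[i - 1] + scale * innov[i]
    return z


def _motion_trace(
    t: int, mean_fd: float, rng: np.random.Generator, radius_mm: float = 50.0
) -> np.ndarray:
    """Random-walk rigid-body trace with expected mean FD `mean_fd` (mm).

    Translation and rotation steps are scaled so each contributes half the
    FD budget; |N(0, s)| has mean s*sqrt(2/pi), and FD sums six terms.
    """
    if mean_fd <= 0:
        return np.zeros((t, 6))
    s_t = mean_fd / (6.0 * np.sqrt(2.0 / np.pi))
    s_r = s_t / radius_mm
    steps = rng.standard_normal((t, 6))
    steps[:, :3] *= s_t
    steps[:, 3:] *= s_r
    steps *= t / max(t - 1, 1)  # fd[0]=0 removes one frame from the mean
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_subject(
    truth: GroundTruth,
    group: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectScan:
    """Draw one subject's scan from the generative model.

    Latent network series come from a subject-specific SPD perturbation of
    the group covariance with AR(1) smoothing; voxel signals are the
    subject loadings applied to the latents plus i.i.d. Gaussian noise at
    the design SNR plus a weak global nuisance component. The true subject
    loadings and covariance are recorded in `truth.subjects`.
    """
    design = truth.design
    if group not in truth.group_cov:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng((design.seed, subject_seed))
    sid = subject_id or f"{group}_{subject_seed:04d}"

    cov = truth.group_cov[group]
    k = design.k
    jit = design.subject_cov_jitter * rng.standard_normal((k, k))
    cov_s = _project_spd(cov + (jit + jit.T) / 2.0)

    h = truth.atlas.loadings
    h_s = np.clip(
        h + design.subject_map_jitter * rng.standard_normal(h.shape), 0, None
    )
    h_s[h_s.sum(axis=1) == 0] = h[h_s.sum(axis=1) == 0]

    z = _ar1_latent(cov_s, design.t_raw, design.ar_coeff, rng)   # T x K
    signal = h_s.T @ z.T                                         # V x T

    nuisance = _ar1_latent(np.eye(3), design.t_raw, 0.8, rng)    # T x 3
    if design.nuisance_weight > 0:
        signal = signal + (design.nuisance_weight * signal.std()
                           * nuisance[:, 0][None, :])

    if design.snr > 0:
        noise_sd = signal.std() / design.snr
        signal = signal + noise_sd * rng.standard_normal(signal.shape)

    motion = _motion_trace(
        design.t_raw, design.motion_level.get(group, 0.1), rng
    )
    truth.subjects[sid] = SubjectTruth(loadings=h_s, cov=cov_s, group=group)
    return SubjectScan(
        signal=signal, motion=motion, tr=design.tr,
        subject_id=sid, group=group, nuisance=nuisance,
    )


def _true_metric(truth: GroundTruth, sid: str, metric: str) -> float:
    st = truth.subjects[sid]
    if metric.startswith("fnc:"):
        _, i, j = metric.split(":")
        c = st.cov
        d = np.sqrt(np.diag(c))
        return float(c[int(i), int(j)] / (d[int(i)] * d[int(j)]))
    raise ValueError(f"unknown clinical link metric {metric!r}")


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[SubjectScan], pd.DataFrame, GroundTruth]:
    """Generate the full cohort: scans, phenotype table, ground truth.

    Phenotype columns: subject_id, group, age, sex, mean_fd, plus one
    column per clinical link, generated as a linear function of the true
    linked metric with noise calibrated to the target correlation.
    """
    truth = make_ground_truth(design)
    rng = np.random.default_rng((design.seed, 0xC0C0))
    scans: list[SubjectScan] = []
    rows: list[dict] = []
    counter = 0
    for label, n in design.groups:
        for _ in range(n):
            counter += 1
            scan = simulate_subject(
                truth, label, subject_seed=counter,
                subject_id=f"sub-{counter:04d}",
            )
            scans.append(scan)
            rows.append({
                "subject_id": scan.subject_id,
                "group": label,
                "age": float(np.clip(rng.normal(11.5, 2.6), 6, 18)),
                "sex": "M" if rng.uniform() < 0.8 else "F",
                "mean_fd": compute_fd(scan.motion).mean_fd,
            })
    pheno = pd.DataFrame(rows)

    for score, metric, target_r in design.clinical_links:
        if metric == "mean_fd":
            vals = pheno["mean_fd"].to_numpy()
        else:
            vals = np.array(
                [_true_metric(truth, s.subject_id, metric) for s in scans]
            )
        z = (vals - vals.mean()) / max(vals.std(), 1e-12)
        eps = rng.standard_normal(len(z))
        raw = target_r * z + np.sqrt(max(1 - target_r**2, 0.0)) * eps
        pheno[score] = 50.0 + 10.0 * raw
    return scans, pheno, truth


def planted_edge_ets(
    n_networks: int = 17,
    n_modules: int = 8,
    t: int = 170,
    within_r: float = 0.5,
    seed: int = 0,
    partition: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic edge time series with a planted module structure.

    Each of the E = K(K-1)/2 edges belongs to one of `n_modules` modules;
    an edge's series is sqrt(w) * module latent + sqrt(1-w) * private noise
    with w = `within_r`, so within-module series correlate at about
    `within_r` and across-module series at about 0. Used as the recovery
    oracle for edge-community detection.

    Returns (ets (E, T), module labels (E,)).
    """
    if not (0 < within_r < 1):
        raise ValueError("within_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    e = n_networks * (n_networks - 1) // 2
    if partition is None:
        # balanced planted partition (sizes differ by at most one), shuffled
        partition = np.arange(e) % n_modules
        rng.shuffle(partition)
    if t <= n_modules:
        raise ValueError("need more frames than modules")
    # module signals orthogonalized in-sample so chance correlations between
    # module latents do not couple whole blocks of edges
    raw = rng.standard_normal((t, n_modules))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    latents = (q / q.std(axis=0)).T
    noise = rng.standard_normal((e, t))
    ets = (np.sqrt(within_r) * latents[partition]
           + np.sqrt(1 - within_r) * noise)
    return ets, partition


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(
    out_dir: str | Path,
    scans: list[SubjectScan],
    pheno: pd.DataFrame,
    fmt: str = "npz",
) -> None:
    """Write one signal file and one motion TSV per subject + phenotype TSV.

    `fmt` is "npz" (compact binary) or "tsv" (plain text, V rows x T cols).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scan in scans:
        stem = out / scan.subject_id
        if fmt == "npz":
            np.savez_compressed(
                stem.with_suffix(".npz"),
                signal=scan.signal, nuisance=scan.nuisance
                if scan.nuisance is not None else np.zeros((scan.n_frames, 0)),
            )
        elif fmt == "tsv":
            np.savetxt(stem.with_suffix(".tsv"), scan.signal, delimiter="\t")
        else:
            raise ValueError("fmt must be 'npz' or 'tsv'")
        np.savetxt(
            out / f"{scan.subject_id}_motion.tsv", scan.motion, delimiter="\t"
        )
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    meta = {
        "tr": scans[0].tr,
        "format": fmt,
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group} for s in scans
        ],
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectScan], pd.DataFrame]:
    """Read a cohort written by `write_cohort`."""
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    pheno = pd.read_csv(src / "phenotype.tsv", sep="\t")
    scans = []
    for entry in meta["subjects"]:
        sid = entry["subject_id"]
        nuisance = None
        if meta["format"] == "npz":
            with np.load(src / f"{sid}.npz") as z:
                signal = z["signal"]
                if z["nuisance"].shape[1]:
                    nuisance = z["nuisance"]
        else:
            signal = np.loadtxt(src / f"{sid}.tsv", delimiter="\t")
        motion = np.loadtxt(src / f"{sid}_motion.tsv", delimiter="\t")
        scans.append(SubjectScan(
            signal=signal, motion=motion, tr=meta["tr"],
            subject_id=sid, group=entry["group"], nuisance=nuisance,
        ))
    return scans, pheno


def export_nifti(
    scan: SubjectScan, out_path: str | Path, mask_path: str | Path | None = None
) -> None:
    """Optional 4-D NIfTI export (voxels placed row-major on a cubic grid)."""
    import nibabel as nib

    coords = grid_coords(scan.n_voxels)
    shape = tuple(coords.max(axis=0) + 1)
    vol = np.zeros(shape + (scan.n_frames,), dtype=np.float32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = scan.signal
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(out_path))
    if mask_path is not None:
        mask = np.zeros(shape, dtype=np.uint8)
        mask[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
        nib.save(nib.Nifti1Image(mask, np.eye(4)), str(mask_path))
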
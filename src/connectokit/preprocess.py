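"""Numerical preprocessing of masked voxel BOLD time series.

Implements the per-subject chain applied before network mapping: dropping
initial volumes, detrending + nuisance regression (Friston-24 motion
expansion, global/WM/CSF surrogates), 0.01-0.1 Hz band-pass filtering,
framewise-displacement (FD) computation, motion scrubbing with cubic-spline
interpolation, and cohort-level subject exclusion.

Image-domain operations (rigid-body realignment, template registration,
spatial smoothing) are out of scope: the chain operates on already-masked
voxel x time matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.linalg import qr

logger = logging.getLogger(__name__)

#: sphere radius (mm) used to convert rotations to arc displacement (Power FD)
DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass
class SubjectScan:
    """One subject's masked voxel x time signal plus motion and metadata.

    Attributes
    ----------
    signal : (V, T) array
        BOLD signal, arbitrary units; rows are voxels, columns frames.
    motion : (T, 6) array
        Rigid-body parameters per frame: 3 translations (mm) then
        3 rotations (rad).
    tr : float
        Repetition time in seconds.
    subject_id, group : str
        Identifiers used by the phenotype table and the stats layer.
    nuisance : (T, p) array or None
        Extra nuisance series (global mean, white matter, CSF surrogates).
    """

    signal: np.ndarray
    motion: np.ndarray
    tr: float
    subject_id: str = ""
    group: str = ""
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (V, T) matrix")
        if self.signal.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if self.motion.shape != (self.signal.shape[1], 6):
            raise ValueError(
                f"motion shape {self.motion.shape} does not match "
                f"(T={self.signal.shape[1]}, 6)"
            )
        if not (np.isfinite(self.signal).all() and np.isfinite(self.motion).all()):
            raise ValueError("signal/motion contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]


@dataclass
class MotionTrace:
    """Framewise displacement (mm) derived from rigid-body parameters."""

    fd: np.ndarray
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if (self.fd < 0).any():
            raise ValueError("fd must be non-negative")
        if self.fd[0] != 0:
            raise ValueError("fd[0] must be 0 by convention")
        self.mean_fd = float(self.fd.mean())


def drop_initial_volumes(scan: SubjectScan, n_drop: int = 10) -> SubjectScan:
    """Remove the first `n_drop` frames (magnetization-equilibrium volumes).

    Both the signal and the motion trace are truncated so they stay aligned.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= scan.n_frames:
        raise ValueError(f"n_drop={n_drop} >= T={scan.n_frames}")
    if n_drop == 0:
        return scan
    nuis = scan.nuisance[n_drop:] if scan.nuisance is not None else None
    return replace(
        scan,
        signal=scan.signal[:, n_drop:],
        motion=scan.motion[n_drop:],
        nuisance=nuis,
    )


def compute_fd(
    motion: np.ndarray, radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> MotionTrace:
    """Power framewise displacement from a (T, 6) motion trace.

    fd[t] = sum of absolute backward differences of the 3 translations (mm)
    plus `radius_mm` times those of the 3 rotations (rad); fd[0] = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6)")
    if not np.isfinite(motion).all():
        raise ValueError("motion contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return MotionTrace(fd=fd)


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [R, R^2, R_{t-1}, R_{t-1}^2].

    Lagged columns are zero-padded at the first frame.
    """
    r = np.asarray(motion, dtype=float)
    if r.ndim != 2 or r.shape[1] != 6:
        raise ValueError("motion must be (T, 6)")
    r_lag = np.zeros_like(r)
    r_lag[1:] = r[:-1]
    return np.hstack([r, r**2, r_lag, r_lag**2])


def regress_nuisance(
    scan: SubjectScan,
    regressors: np.ndarray | None = None,
    include_trend: bool = True,
) -> SubjectScan:
    """Replace each voxel series by its least-squares residual.

    The design contains an intercept, optionally a linear trend, and the
    supplied regressor columns. Collinear columns are dropped (with a
    warning) before solving, so the residuals are always orthogonal to the
    retained design.
    """
    t = scan.n_frames
    cols = [np.ones(t)]
    if include_trend:
        cols.append(np.linspace(-1.0, 1.0, t))
    if regressors is not None:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise ValueError("regressor rows must match T")
        if regressors.shape[1] >= t:
            raise ValueError("more regressors than frames")
        cols.append(regressors)
    design = np.column_stack(cols)

    # drop collinear columns via rank-revealing QR
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        keep = np.sort(piv[:rank])
        logger.warning(
            "rank-deficient nuisance design: dropping %d collinear column(s)",
            design.shape[1] - rank,
        )
        design = design[:, keep]

    beta, *_ = np.linalg.lstsq(design, scan.signal.T, rcond=None)
    resid = scan.signal.T - design @ beta
    return replace(scan, signal=resid.T)


def bandpass(
    scan: SubjectScan, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> SubjectScan:
    """Zero-phase Butterworth band-pass of every voxel series.

    Forward-backward filtering (filtfilt) gives zero phase distortion; the
    effective attenuation is the square of the single-pass response.
    """
    nyq = 1.0 / (2.0 * scan.tr)
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=1.0 / scan.tr,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, scan.signal, axis=1)
    return replace(scan, signal=filtered)


def scrub_interpolate(
    scan: SubjectScan, trace: MotionTrace, fd_thresh: float = 0.5
) -> SubjectScan:
    """Replace high-motion frames (fd > threshold) by cubic-spline values.

    The spline is fit per voxel over the clean frames; flagged frames before
    the first / after the last clean frame get the nearest clean value
    (splines extrapolate poorly).
    """
    fd = trace.fd
    if fd.shape[0] != scan.n_frames:
        raise ValueError("fd length must match T")
    bad = fd > fd_thresh
    if not bad.any():
        return scan
    clean = np.flatnonzero(~bad)
    if clean.size < 4:
        raise ValueError("fewer than 4 clean frames; cannot scrub")
    t_all = np.arange(scan.n_frames)
    spline = CubicSpline(clean, scan.signal[:, clean], axis=1)
    out = scan.signal.copy()
    bad_idx = np.flatnonzero(bad)
    interior = bad_idx[(bad_idx > clean[0]) & (bad_idx < clean[-1])]
    if interior.size:
        out[:, interior] = spline(t_all[interior])
    before = bad_idx[bad_idx < clean[0]]
    if before.size:
        out[:, before] = scan.signal[:, [clean[0]]]
    after = bad_idx[bad_idx > clean[-1]]
    if after.size:
        out[:, after] = scan.signal[:, [clean[-1]]]
    return replace(scan, signal=out)


def exclude_subjects(
    cohort: list[SubjectScan],
    max_mean_fd: float = 0.5,
    max_abs_motion_voxels: float = 1.0,
    voxel_size_mm: float = 3.0,
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
) -> tuple[list[SubjectScan], list[dict]]:
    """Drop subjects with excessive head motion.

    A subject is excluded when mean FD exceeds `max_mean_fd` (mm) or any
    absolute motion excursion (translations in mm, rotations converted via
    the sphere radius) exceeds `max_abs_motion_voxels` voxels.

    Returns the surviving cohort and a report of exclusions
    (subject_id, reason, value).
    """
    limit_mm = max_abs_motion_voxels * voxel_size_mm
    kept: list[SubjectScan] = []
    report: list[dict] = []
    for scan in cohort:
        trace = compute_fd(scan.motion, radius_mm=radius_mm)
        disp = np.abs(scan.motion - scan.motion[0])
        max_disp = max(disp[:, :3].max(), radius_mm * disp[:, 3:].max())
        if trace.mean_fd > max_mean_fd:
            report.append(
                {"subject_id": scan.subject_id, "reason": "mean_fd",
                 "value": trace.mean_fd}
            )
        elif max_disp > limit_mm:
            report.append(
                {"subject_id": scan.subject_id, "reason": "max_motion",
                 "value": float(max_disp)}
            )
        else:
            kept.append(scan)
    if not kept:
        raise ValueError("all subjects excluded by motion criteria")
    return kept, report


def load_nifti_scan(
    image_path,
    mask_path,
    motion: np.ndarray | None = None,
    tr: float | None = None,
    subject_id: str = "",
    group: str = "",
) -> SubjectScan:
    """Read a 4-D NIfTI plus binary mask into a SubjectScan.

    Voxels are ordered row-major over the nonzero mask entries (0-based).
    `tr` defaults to the pixdim time step of the image header; `motion`
    defaults to zeros.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image")
    signal = data[mask]  # (V, T), row-major over the mask
    t = signal.shape[1]
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 2.0
    if motion is None:
        motion = np.zeros((t, 6))
    return SubjectScan(signal=signal, motion=motion, tr=tr,
                       subject_id=subject_id, group=group)


def preprocess_subject(
    scan: SubjectScan,
    n_drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    fd_thresh: float = 0.5,
    use_friston24: bool = True,
) -> tuple[SubjectScan, MotionTrace]:
    """Full numerical chain in pipeline order.

    drop -> detrend + nuisance regression -> band-pass -> scrub. The FD
    trace is computed on the post-drop motion parameters and returned for
    the exclusion rule and as a statistics covariate.
    """
    scan = drop_initial_volumes(scan, n_drop)
    regs = []
    if use_friston24:
        regs.append(friston24(scan.motion))
    if scan.nuisance is not None:
        regs.append(scan.nuisance)
    regressors = np.hstack(regs) if regs else None
    scan = regress_nuisance(scan, regressors=regressors, include_trend=True)
    scan = bandpass(scan, low_hz, high_hz)
    trace = compute_fd(scan.motion)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            scan = scrub_interpolate(scan, trace, fd_thresh)
        except ValueError:
            logger.warning(
                "subject %s: too few clean frames to scrub; left unscrubbed",
                scan.subject_id,
            )
    return scan, trace
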
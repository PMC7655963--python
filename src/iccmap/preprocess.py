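"""Post-normalization BOLD denoising: volume trimming, nuisance
confound construction and regression, band-pass filtering, and
motion-based subject screening.

The chain operates on images already aligned to a common space.  The
fixed stage order is trim -> confound regression -> band-pass; the
subject screen uses mean frame-wise displacement (FD) with the standard
0.2 mm cutoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .types import BoldSeries, MotionTrace

logger = logging.getLogger(__name__)

DEFAULT_TRIM = 5
DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_FD_RADIUS_MM = 50.0
DEFAULT_BAND_HZ = (0.01, 0.1)


def trim_initial_volumes(
    series: BoldSeries, trace: MotionTrace, k: int = DEFAULT_TRIM
) -> tuple[BoldSeries, MotionTrace]:
    """Drop the first ``k`` volumes of a series and its motion trace.

    The initial volumes of an EPI acquisition are discarded to let the
    longitudinal magnetization reach steady state.
    """
    if trace.n_volumes != series.n_volumes:
        raise ValueError(
            f"motion trace has {trace.n_volumes} rows but series has {series.n_volumes} volumes"
        )
    if series.n_volumes <= k:
        raise ValueError(f"cannot trim {k} volumes from a {series.n_volumes}-volume series")
    return (
        BoldSeries(series.data[..., k:], series.affine, series.tr_seconds),
        MotionTrace(trace.params[k:]),
    )


def build_motion_confounds(trace: MotionTrace) -> tuple[np.ndarray, list[str]]:
    """24-regressor head-motion confound model.

    Columns are the 6 realignment parameters R_t, their element-wise
    squares R_t^2, the one-volume-lagged parameters R_{t-1}, and the
    lagged squares R_{t-1}^2; the lag at t=0 is filled with zero.

    Returns
    -------
    (T, 24) matrix and the 24 column labels.
    """
    r = trace.params
    lagged = np.zeros_like(r)
    lagged[1:] = r[:-1]
    blocks = [r, r**2, lagged, lagged**2]
    names = []
    for tag in ("", "_sq", "_lag", "_lag_sq"):
        names += [c + tag for c in ("x", "y", "z", "alpha", "beta", "gamma")]
    return np.hstack(blocks), names


def compute_fd(trace: MotionTrace, rotation_radius_mm: float = DEFAULT_FD_RADIUS_MM) -> np.ndarray:
    """Per-volume frame-wise displacement in mm.

    FD_t = |dx|+|dy|+|dz| + radius*(|da|+|db|+|dg|) with backward
    differences; FD at the first volume is 0.  Rotations are converted
    to arc length on a sphere of ``rotation_radius_mm`` (50 mm by
    convention).
    """
    d = np.abs(np.diff(trace.params, axis=0))
    fd = np.zeros(trace.n_volumes)
    fd[1:] = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def screen_subjects(
    fd_by_subject: dict[str, np.ndarray], threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
) -> pd.DataFrame:
    """Partition subjects by the mean-FD motion criterion.

    A subject is rejected iff mean FD is strictly greater than the
    threshold (mean FD exactly at the threshold is kept).
    """
    if not threshold_mm > 0:
        raise ValueError("threshold_mm must be positive")
    rows = [
        {"subject_id": sid, "mean_fd": float(np.mean(fd)), "kept": not float(np.mean(fd)) > threshold_mm}
        for sid, fd in fd_by_subject.items()
    ]
    return pd.DataFrame(rows)


def _sphere_voxels(
    center_mm: np.ndarray, radius_mm: float, shape: tuple[int, int, int], affine: np.ndarray
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within radius of a world
    point; the nearest voxel is forced in when the sphere misses all
    centers."""
    ijk = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((world - np.asarray(center_mm, dtype=np.float64)) ** 2).sum(axis=1)
    inside = d2 <= radius_mm**2
    if not inside.any():
        inside[np.argmin(d2)] = True
    return inside.reshape(shape)


def extract_tissue_signals(
    series: BoldSeries,
    csf_center_mm: np.ndarray,
    wm_center_mm: np.ndarray,
    global_mask: np.ndarray,
    sphere_radius_mm: float = 4.0,
) -> tuple[np.ndarray, list[str]]:
    """Mean CSF/WM sphere signals, the global signal, and their
    backward-difference derivatives (first element 0): 6 columns.

    The CSF and WM regions are 4 mm spheres at configured world
    coordinates; the global signal is the mean over ``global_mask``.
    """
    shape = series.spatial_shape
    inv = np.linalg.inv(series.affine)
    cols, names = [], []
    for name, center in (("csf", csf_center_mm), ("wm", wm_center_mm)):
        vox = (inv[:3, :3] @ np.asarray(center, dtype=np.float64) + inv[:3, 3])
        if np.any(vox < -0.5) or np.any(vox > np.array(shape) - 0.5):
            raise ValueError(f"{name} sphere center {center} lies outside the volume")
        sph = _sphere_voxels(center, sphere_radius_mm, shape, series.affine)
        cols.append(series.data[sph].mean(axis=0))
        names.append(name)
    gmask = np.asarray(global_mask, dtype=bool)
    if gmask.shape != shape or not gmask.any():
        raise ValueError("global mask must be nonempty and match the series grid")
    cols.append(series.data[gmask].mean(axis=0))
    names.append("global")
    out = [np.asarray(c) for c in cols]
    for c, name in zip(list(out), list(names)):
        d = np.zeros_like(c)
        d[1:] = np.diff(c)
        out.append(d)
        names.append(name + "_deriv")
    return np.column_stack(out), names


def _independent_columns(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR with
    column pivoting)."""
    from scipy.linalg import qr

    if x.size == 0:
        return np.array([], dtype=int)
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int((diag > tol * diag[0]).sum())
    return np.sort(piv[:rank])


def regress_confounds(series: BoldSeries, confounds: np.ndarray | None) -> BoldSeries:
    """Voxel-wise OLS residualization against the confound matrix.

    An intercept is always included, so residuals are demeaned and
    orthogonal to every confound column.  Linearly dependent confound
    columns (e.g. from an all-zero motion trace) are dropped with a
    warning rather than raising.
    """
    t = series.n_volumes
    design = np.ones((t, 1))
    if confounds is not None and np.asarray(confounds).size:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
        if confounds.shape[0] != t:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows but series has {t} volumes"
            )
        design = np.hstack([design, confounds])
    keep = _independent_columns(design)
    if keep.size < design.shape[1]:
        logger.warning(
            "confound matrix rank-deficient: dropping %d dependent column(s)",
            design.shape[1] - keep.size,
        )
        design = design[:, keep]
    y = series.data.reshape(-1, t).T  # T x V
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return BoldSeries(resid.T.reshape(series.data.shape), series.affine, series.tr_seconds)


def bandpass(
    series: BoldSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 4,
) -> BoldSeries:
    """Zero-phase Butterworth band-pass along the time axis.

    The filter is applied forward and backward (``sosfiltfilt``) so
    phase — and therefore lagged correlation structure — is untouched.
    """
    fs = 1.0 / series.tr_seconds
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq:.4g} Hz)")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, series.data, axis=-1)
    return BoldSeries(filtered, series.affine, series.tr_seconds)


def denoise(
    series: BoldSeries,
    trace: MotionTrace,
    extra_confounds: np.ndarray | None = None,
    trim: int = DEFAULT_TRIM,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> BoldSeries:
    """Full single-subject chain: trim -> motion (24) + extra confound
    regression -> band-pass.  ``extra_confounds`` rows must match the
    post-trim length."""
    series, trace = trim_initial_volumes(series, trace, trim)
    confounds, _ = build_motion_confounds(trace)
    if extra_confounds is not None:
        confounds = np.hstack([confounds, np.atleast_2d(extra_confounds)])
    series = regress_confounds(series, confounds)
    return bandpass(series, low_hz, high_hz)


def qc_table(
    traces: dict[str, MotionTrace],
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    rotation_radius_mm: float = DEFAULT_FD_RADIUS_MM,
) -> pd.DataFrame:
    """Per-subject motion QC: mean FD and kept/rejected flag."""
    fd = {sid: compute_fd(tr, rotation_radius_mm) for sid, tr in traces.items()}
    return screen_subjects(fd, threshold_mm)
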
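"""Lesion-aware per-subject preprocessing.

Stage order for the pipeline: hemisphere flip -> drop initial volumes ->
motion QC -> nuisance regression (24 motion regressors + WM/CSF means,
linear trend absorbed into the same design) -> hemodynamic-lag correction
(patients) -> band-pass filtering. Degree centrality is computed on the
unsmoothed output and its map smoothed afterwards; seed FC uses spatially
smoothed series. The global signal is deliberately not removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import BoldSeries, MotionTrace

__all__ = [
    "flip_to_ipsilesional",
    "enantiomorphic_fill",
    "compute_fd",
    "qc_exclude",
    "QCDecision",
    "build_friston24",
    "nuisance_regress",
    "detrend_linear",
    "bandpass",
    "estimate_and_correct_lag",
    "smooth_gaussian",
    "build_group_mask",
    "slice_timing",
    "drop_initial_volumes",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def flip_to_ipsilesional(volume: np.ndarray, lesion_side: str) -> np.ndarray:
    """Mirror a 3D/4D volume along the left-right axis for right lesions.

    Axis 0 must be the left-right axis. Left-lesion volumes pass through
    unchanged, so after this step the ipsilesional hemisphere is always
    on the conventional (left) side.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(f"unknown lesion side {lesion_side!r}")
    if lesion_side == "left":
        return np.asarray(volume)
    return np.flip(volume, axis=0)


def enantiomorphic_fill(structural: np.ndarray, lesion: np.ndarray) -> np.ndarray:
    """Replace lesioned voxels by their mirror across the midsagittal plane.

    Mirroring is about the grid's central sagittal plane (index i maps to
    nx-1-i on axis 0). If the mirror voxel is itself lesioned, the original
    value is kept and a warning logged.
    """
    structural = np.asarray(structural, dtype=float)
    lesion = np.asarray(lesion, dtype=bool)
    if structural.shape != lesion.shape:
        raise ValueError("structural and lesion grids differ")
    mirrored = structural[::-1]
    mirror_lesion = lesion[::-1]
    out = structural.copy()
    fill = lesion & ~mirror_lesion
    out[fill] = mirrored[fill]
    n_bad = int((lesion & mirror_lesion).sum())
    if n_bad:
        log.warning("enantiomorphic fill: %d lesion voxels have lesioned "
                    "mirrors; original values kept", n_bad)
    return out


def compute_fd(params: np.ndarray, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement, Power convention.

    fd[t] = sum |delta translations| + R * sum |delta rotations(rad)| with
    R = 50 mm; fd[0] = 0.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[0] != 6:
        raise ValueError(f"expected (6, T) motion parameters, got {params.shape}")
    if params.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    d = np.abs(np.diff(params, axis=1))
    fd = np.concatenate([[0.0], d[:3].sum(axis=0) + sphere_radius_mm * d[3:].sum(axis=0)])
    return fd


@dataclass
class QCDecision:
    keep: bool
    reason: str | None  # first failing criterion, None when kept
    max_disp_mm: float
    max_rot_deg: float
    mean_fd: float


def qc_exclude(motion: MotionTrace, max_disp_mm: float = 3.0,
               max_rot_deg: float = 3.0, max_mean_fd: float = 0.5) -> QCDecision:
    """Motion QC with strict thresholds: values exactly at a limit are kept."""
    fd = motion.fd if motion.fd is not None else compute_fd(motion.params)
    disp = float(np.abs(motion.params[:3]).max())
    rot = float(np.degrees(np.abs(motion.params[3:]).max()))
    mean_fd = float(fd.mean())
    reason = None
    if disp > max_disp_mm:
        reason = "max_disp"
    elif rot > max_rot_deg:
        reason = "max_rot"
    elif mean_fd > max_mean_fd:
        reason = "mean_fd"
    return QCDecision(keep=reason is None, reason=reason, max_disp_mm=disp,
                      max_rot_deg=rot, mean_fd=mean_fd)


def build_friston24(params: np.ndarray) -> np.ndarray:
    """24-parameter motion design: [p, p(t-1), p^2, p(t-1)^2], (24, T).

    The lagged rows are zero-padded at t = 0.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[0] != 6:
        raise ValueError(f"expected (6, T) motion parameters, got {params.shape}")
    lagged = np.zeros_like(params)
    lagged[:, 1:] = params[:, :-1]
    return np.vstack([params, lagged, params ** 2, lagged ** 2])


def _design_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of every row of Y on columns of X (intercept included)."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("nuisance design rank-deficient (%d/%d); collinear columns "
                    "are resolved by the pseudoinverse", rank, X.shape[1])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def nuisance_regress(bold: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Remove nuisance time courses (rows of ``regressors``) per voxel.

    An intercept is added internally; ordinary-least-squares residuals are
    returned. Rank-deficient designs are handled by the pseudoinverse.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    T = bold.n_timepoints
    if regressors.shape[1] != T:
        raise ValueError("regressor length does not match the series")
    X = np.column_stack([np.ones(T), regressors.T])
    Y = bold.data.reshape(-1, T).astype(float)
    resid = _design_residuals(Y, X)
    return bold.with_data(resid.reshape(bold.data.shape))


def detrend_linear(bold: BoldSeries) -> BoldSeries:
    """Remove per-voxel intercept and linear trend."""
    flat = bold.data.reshape(-1, bold.n_timepoints).astype(float)
    out = signal.detrend(flat, axis=1, type="linear")
    return bold.with_data(out.reshape(bold.data.shape))


def _band_bins(T: int, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=tr)
    return (freqs >= low_hz) & (freqs <= high_hz)


def min_timepoints_for_band(tr: float, low_hz: float, high_hz: float,
                            t_max: int = 100000) -> int:
    for T in range(4, t_max):
        if _band_bins(T, tr, low_hz, high_hz).any():
            return T
    raise ValueError("no usable series length for this band")


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldSeries:
    """Ideal DFT-mask band-pass: bins with frequency in [low, high] are kept.

    This is the rectangular frequency-domain filter used by the REST-family
    toolboxes; bin-aligned sinusoids pass through exactly.
    """
    tr = bold.tr_seconds
    nyquist = 0.5 / tr
    if high_hz >= nyquist:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyquist:g})")
    T = bold.n_timepoints
    keep = _band_bins(T, tr, low_hz, high_hz)
    if not keep.any():
        t_min = min_timepoints_for_band(tr, low_hz, high_hz)
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz contains no DFT bin at T={T}, "
            f"TR={tr}s; need at least T={t_min}")
    flat = bold.data.reshape(-1, T).astype(float)
    spec = np.fft.rfft(flat, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=1)
    return bold.with_data(out.reshape(bold.data.shape))


def _overlap_corr(x: np.ndarray, ref: np.ndarray, s: int) -> np.ndarray:
    """Pearson r of voxel rows x (V, T) against ref shifted by s TRs.

    A positive s means the voxel lags the reference: x[:, s:] is compared
    with ref[:T-s].
    """
    T = x.shape[1]
    if s >= 0:
        xa, ra = x[:, s:], ref[:T - s] if s else ref
    else:
        xa, ra = x[:, :T + s], ref[-s:]
    xa = xa - xa.mean(axis=1, keepdims=True)
    ra = ra - ra.mean()
    xn = np.linalg.norm(xa, axis=1)
    rn = np.linalg.norm(ra)
    denom = xn * rn
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xa @ ra) / denom
    r[denom == 0] = -np.inf  # zero-variance rows never win
    return r


def estimate_and_correct_lag(bold: BoldSeries, reference: np.ndarray,
                             max_lag_tr: int = 4,
                             mask: np.ndarray | None = None
                             ) -> tuple[np.ndarray, BoldSeries]:
    """Per-voxel integer hemodynamic lag by time-shift analysis.

    For each voxel the lag is the integer shift s in [-max_lag_tr,
    +max_lag_tr] maximising the Pearson correlation between the shifted
    voxel series and the reference (truncated-overlap cross-correlation);
    ties prefer the smaller \\|s\\|, then the negative shift. The corrected
    series is the voxel series advanced by its lag with edge samples
    repeated. Zero-variance voxels get lag 0 and are flagged.
    """
    if max_lag_tr < 1:
        raise ValueError("max_lag_tr must be >= 1")
    T = bold.n_timepoints
    if T <= 2 * max_lag_tr + 2:
        raise ValueError("series too short for the requested lag range")
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (T,):
        raise ValueError("reference must be a length-T series")
    grid = bold.grid_shape
    flat = bold.data.reshape(-1, T).astype(float)
    if mask is not None:
        sel = np.flatnonzero(np.asarray(mask, bool).ravel())
    else:
        sel = np.arange(flat.shape[0])
    x = flat[sel]

    # candidate order encodes the tie-break: |s| ascending, negative first
    cands = sorted(range(-max_lag_tr, max_lag_tr + 1), key=lambda s: (abs(s), s))
    best_r = np.full(x.shape[0], -np.inf)
    best_s = np.zeros(x.shape[0], dtype=np.int16)
    for s in cands:
        r = _overlap_corr(x, ref, s)
        better = r > best_r
        best_r[better] = r[better]
        best_s[better] = s
    zero_var = ~np.isfinite(best_r)
    best_s[zero_var] = 0

    lag_map = np.zeros(int(np.prod(grid)), dtype=np.int16)
    lag_map[sel] = best_s
    lag_map = lag_map.reshape(grid)

    corrected = flat.copy()
    for s in np.unique(best_s):
        if s == 0:
            continue
        rows = sel[best_s == s]
        if s > 0:  # voxel lags: advance the series, repeat the last sample
            corrected[rows, :T - s] = flat[rows, s:]
            corrected[rows, T - s:] = flat[rows, -1:]
        else:
            corrected[rows, -s:] = flat[rows, :T + s]
            corrected[rows, :-s] = flat[rows, :1]
    out = bold.with_data(corrected.reshape(bold.data.shape))
    out_flags = np.zeros(int(np.prod(grid)), dtype=bool)
    out_flags[sel[zero_var]] = True
    return lag_map, out


def smooth_gaussian(data: np.ndarray, voxel_size_mm, fwhm_mm: float = 6.0) -> np.ndarray:
    """Separable spatial Gaussian smoothing with reflective boundaries.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) converted to voxel units. 4D
    inputs are smoothed volume by volume (no temporal smoothing).
    """
    data = np.asarray(data, dtype=float)
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vox
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
    if data.ndim == 4:
        sigma = tuple(sigma_vox) + (0.0,)
        return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
    raise ValueError("expected a 3D map or 4D series")


def build_group_mask(subject_brain_masks: list[np.ndarray], atlas_mask: np.ndarray,
                     lesions: list[np.ndarray]) -> np.ndarray:
    """Intersection of subject brain masks and the atlas, minus all lesions."""
    out = np.asarray(atlas_mask, dtype=bool).copy()
    for m in subject_brain_masks:
        out &= np.asarray(m, dtype=bool)
    for les in lesions:
        out &= ~np.asarray(les, dtype=bool)
    if not out.any():
        raise ValueError("group mask is empty")
    return out


def slice_timing(bold: BoldSeries) -> BoldSeries:
    """Registered no-op hook (synthetic volumes have no slice structure)."""
    return bold


def drop_initial_volumes(bold: BoldSeries, n: int = 10) -> BoldSeries:
    """Discard the first ``n`` volumes (scanner equilibration period)."""
    if n < 0 or n >= bold.n_timepoints - 1:
        raise ValueError("cannot drop that many volumes")
    return bold.with_data(bold.data[..., n:])
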
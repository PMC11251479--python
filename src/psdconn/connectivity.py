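"""Voxel-wise degree centrality and seed-based functional connectivity.

Degree centrality treats every in-mask voxel as a node of the whole-brain
correlation graph and counts (or sums) the connections whose Pearson
correlation strictly exceeds a threshold (default r > 0.32). The map is
normalised by its mean. Computation streams over voxel blocks so the full
V x V correlation matrix is never materialised.

Seed FC correlates the seed's mean time course with every in-mask voxel
and applies the Fisher r-to-z transform, capping |r| at 1 - 1e-7 so the
map stays finite; capped voxels are flagged in the map metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BoldSeries, ScalarMap, SeedSpec

__all__ = [
    "DCConfig",
    "compute_dc",
    "compute_seed_fc",
    "extract_roi_mean",
    "bonferroni_r_threshold",
    "FISHER_Z_CAP",
]

FISHER_Z_CAP = 1.0 - 1e-7


@dataclass
class DCConfig:
    """Degree-centrality options.

    r_threshold : correlation threshold; only r strictly greater counts.
    binary : count supra-threshold edges (True) or sum their r (False).
    normalize : divide the map by its in-mask mean.
    block_size : voxels per streamed block (memory contract).
    dtype : accumulation dtype; float32 trades ~1e-6 accuracy for speed.
    """

    r_threshold: float = 0.32
    binary: bool = True
    normalize: bool = True
    block_size: int = 1024
    dtype: str = "float64"

    def validate(self) -> None:
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (-1, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


def _normalized_series(bold: BoldSeries, mask: np.ndarray, dtype) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centred unit-norm series for in-mask voxels.

    Returns (Xn, in_mask_flat_indices, zero_variance_flags).
    """
    mask = np.asarray(mask, dtype=bool)
    sel = np.flatnonzero(mask.ravel())
    X = bold.data.reshape(-1, bold.n_timepoints)[sel].astype(dtype)
    X = X - X.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(X, axis=1)
    zero_var = nrm == 0
    nrm[zero_var] = 1.0
    X /= nrm[:, None]
    X[zero_var] = 0.0  # zero rows correlate 0 with everything
    return X, sel, zero_var


def compute_dc(bold: BoldSeries, mask: np.ndarray, cfg: DCConfig | None = None) -> ScalarMap:
    """Normalised voxel-wise degree-centrality map.

    For voxel i the raw degree is sum_{j != i} 1[r_ij > r_threshold]
    (binary) or the sum of those r_ij (weighted). Zero-variance voxels are
    dropped from the graph, assigned DC 0 and flagged. With
    ``cfg.normalize`` the map is divided by its mean over the mask.
    """
    cfg = cfg or DCConfig()
    cfg.validate()
    dtype = np.dtype(cfg.dtype)
    Xn, sel, zero_var = _normalized_series(bold, mask, dtype)
    V = Xn.shape[0]
    if V < 2:
        raise ValueError("need at least 2 in-mask voxels")
    thr = dtype.type(cfg.r_threshold)
    degree = np.zeros(V, dtype=np.float64)
    for start in range(0, V, cfg.block_size):
        stop = min(start + cfg.block_size, V)
        R = Xn[start:stop] @ Xn.T  # (b, V): never the full V x V matrix
        above = R > thr
        if cfg.binary:
            deg = above.sum(axis=1).astype(np.float64)
        else:
            deg = np.where(above, R, 0).sum(axis=1).astype(np.float64)
        # remove the self-connection (r_ii = 1 > thr for valid voxels)
        self_r = R[np.arange(stop - start), np.arange(start, stop)]
        self_above = self_r > thr
        deg -= (self_above if cfg.binary else np.where(self_above, self_r, 0))
        degree[start:stop] = deg
    degree[zero_var] = 0.0

    data = np.zeros(bold.grid_shape, dtype=float)
    if cfg.normalize:
        mean_deg = degree.mean()
        if mean_deg <= 0:
            raise ValueError(
                "all degrees are zero; lower r_threshold or check the data")
        degree = degree / mean_deg
    data.ravel()[sel] = degree
    flags = np.zeros(bold.grid_shape, dtype=bool)
    flags.ravel()[sel[zero_var]] = True
    return ScalarMap(data=data, mask=np.asarray(mask, bool), kind="dc",
                     affine=bold.affine,
                     extras={"zero_variance": flags, "config": cfg})


def compute_seed_fc(bold: BoldSeries, seed: SeedSpec, mask: np.ndarray) -> ScalarMap:
    """Fisher-z seed-based functional connectivity map.

    z(v) = atanh(r(seed mean series, voxel v)) for every in-mask voxel,
    seed voxels included. |r| is capped at 1 - 1e-7 and capped voxels are
    flagged under ``extras['capped']``.
    """
    T = bold.n_timepoints
    flat = bold.data.reshape(-1, T).astype(float)
    seed_series = flat[seed.voxels].mean(axis=0)
    seed_series = seed_series - seed_series.mean()
    seed_norm = np.linalg.norm(seed_series)
    if seed_norm == 0:
        raise ValueError(f"seed {seed.roi_id!r} mean series has zero variance")

    Xn, sel, zero_var = _normalized_series(bold, mask, np.float64)
    r = Xn @ (seed_series / seed_norm)
    capped = np.abs(r) > FISHER_Z_CAP
    r = np.clip(r, -FISHER_Z_CAP, FISHER_Z_CAP)
    z = np.arctanh(r)
    z[zero_var] = 0.0

    data = np.zeros(bold.grid_shape, dtype=float)
    data.ravel()[sel] = z
    cap_map = np.zeros(bold.grid_shape, dtype=bool)
    cap_map.ravel()[sel[capped]] = True
    return ScalarMap(data=data, mask=np.asarray(mask, bool), kind="fc_z",
                     affine=bold.affine,
                     extras={"capped": cap_map, "seed": seed.roi_id,
                             "zero_variance_count": int(zero_var.sum())})


def extract_roi_mean(scalar_map: ScalarMap, roi: SeedSpec) -> float:
    """Arithmetic mean of the map over the ROI's in-mask voxels."""
    grid = scalar_map.data.shape
    roi_mask = roi.to_mask(grid) & scalar_map.mask
    if not roi_mask.any():
        raise ValueError(f"ROI {roi.roi_id!r} does not intersect the map mask")
    return float(scalar_map.data[roi_mask].mean())


def bonferroni_r_threshold(n_timepoints: int, n_voxels: int,
                           alpha: float = 0.05) -> float:
    """Correlation threshold with voxel-pair Bonferroni control.

    Returns the r whose two-sided p equals alpha / C(V, 2) under the
    t-distributed null with T - 2 degrees of freedom. The conventional
    default r = 0.32 remains the pipeline constant; this helper documents
    how such a constant arises from T and V.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints")
    m = n_voxels * (n_voxels - 1) / 2.0
    df = n_timepoints - 2
    tcrit = stats.t.isf(alpha / m / 2.0, df)
    return float(tcrit / np.sqrt(df + tcrit ** 2))
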
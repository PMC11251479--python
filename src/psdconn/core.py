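"""Core in-memory containers shared by every pipeline stage.

All volumes live on one common voxel grid. By convention axis 0 is the
left-right axis with the positive direction pointing to the subject's
right, so "flipping to the ipsilesional-left convention" is a reversal
along axis 0. Grid geometry is carried as a NIfTI-style 4x4 affine whose
diagonal holds the voxel size in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoldSeries",
    "MotionTrace",
    "MaskSet",
    "ScalarMap",
    "SeedSpec",
    "default_affine",
    "load_bold",
    "load_volume",
    "save_volume",
]


def default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    """Diagonal RAS affine for an isotropic grid (axis 0 = left-right)."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclass
class BoldSeries:
    """One subject's 4D BOLD run on the common grid.

    Parameters
    ----------
    data : (x, y, z, t) array
    tr_seconds : repetition time in seconds
    affine : 4x4 voxel-to-mm transform; the diagonal gives voxel size
    flipped : True once the volume has been mirrored so the ipsilesional
        hemisphere sits on the conventional (left) side
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=default_affine)
    flipped: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def with_data(self, data: np.ndarray, **kw) -> "BoldSeries":
        return replace(self, data=data, **kw)


@dataclass
class MotionTrace:
    """Rigid-body motion parameters and their framewise displacement.

    ``params`` has shape (6, T): three translations in mm then three
    rotations in radians. ``fd`` follows the Power convention (rotations
    projected to arc length on a 50 mm sphere) with fd[0] = 0.
    """

    params: np.ndarray
    fd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[0] != 6:
            raise ValueError(f"motion params must be (6, T), got {self.params.shape}")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[1]


@dataclass
class MaskSet:
    """Binary tissue/lesion masks on the common grid."""

    gray_matter: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    lesion: np.ndarray
    group_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.gray_matter, self.wm, self.csf, self.lesion)}
        if len(shapes) != 1:
            raise ValueError(f"mask grids differ: {shapes}")
        if np.any(np.asarray(self.gray_matter, bool) & np.asarray(self.lesion, bool)):
            raise ValueError("gray-matter and lesion masks overlap")


@dataclass
class ScalarMap:
    """A per-voxel 3D statistic image (DC, FC-z, t, F or p).

    Values are defined only inside ``mask``; outside voxels are zero.
    ``extras`` carries side information such as flagged (zero-variance or
    correlation-capped) voxels.
    """

    data: np.ndarray
    mask: np.ndarray
    kind: str
    affine: np.ndarray = field(default_factory=default_affine)
    extras: dict = field(default_factory=dict)

    _KINDS = ("dc", "fc_z", "t", "F", "p")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the map mask")

    def values(self) -> np.ndarray:
        """In-mask values as a flat vector (C order)."""
        return self.data[self.mask]


@dataclass
class SeedSpec:
    """A seed/region of interest given as flat voxel indices on the grid."""

    roi_id: str
    voxels: np.ndarray  # flat C-order indices into the 3D grid
    provenance: str = "user"  # or "dc_specificity"

    def __post_init__(self) -> None:
        self.voxels = np.unique(np.asarray(self.voxels, dtype=np.intp))
        if self.voxels.size == 0:
            raise ValueError(f"seed {self.roi_id!r} is empty")

    def to_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(int(np.prod(grid_shape)), dtype=bool)
        m[self.voxels] = True
        return m.reshape(grid_shape)


# ---------------------------------------------------------------------------
# NIfTI I/O helpers


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray,
                description: str = "") -> Path:
    """Write an array as uncompressed NIfTI-1, recording ``description``."""
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    if description:
        img.header["descrip"] = description.encode()[:79]
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def load_bold(path: str | Path, tr_seconds: float) -> BoldSeries:
    data, affine = load_volume(path)
    return BoldSeries(data=data, tr_seconds=tr_seconds, affine=affine)
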
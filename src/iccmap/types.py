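"""Core data containers shared across the pipeline.

Everything downstream of the scanner is represented by four small
dataclasses: a subject's 4-D BOLD series, the 6-parameter rigid-body
motion trace that accompanies it, the binary gray-matter analysis mask,
and the per-voxel ICC map the pipeline produces.  All containers carry
the voxel-index -> world-mm affine so distances and peak coordinates are
always reported in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

MOTION_COLUMNS = ("x_mm", "y_mm", "z_mm", "alpha_rad", "beta_rad", "gamma_rad")


@dataclass
class BoldSeries:
    """A single subject's 4-D BOLD array (i, j, k, t) in a common space.

    Parameters
    ----------
    data
        4-D float array, spatial axes first, time last. Arbitrary units.
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention).
    tr_seconds
        Repetition time in seconds (volume-to-volume sampling interval).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D (i,j,k,t); got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD series must contain at least one volume")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str, tr_seconds: float | None = None) -> "BoldSeries":
        img = nib.load(path)
        tr = tr_seconds if tr_seconds is not None else float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr)


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters, one row per volume.

    Columns follow the SPM realignment dialect: three translations in mm
    followed by three rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=np.float64))
        if self.params.shape[1] != 6:
            raise ValueError(f"motion trace must have 6 columns; got {self.params.shape[1]}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def to_txt(self, path: str) -> None:
        np.savetxt(path, self.params, fmt="%.10g")

    @classmethod
    def from_txt(cls, path: str) -> "MotionTrace":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass
class GMMask:
    """Binary gray-matter inclusion mask obtained by thresholding a
    tissue-probability map (voxels with probability strictly exceeding
    ``source_threshold`` are in)."""

    mask: np.ndarray
    affine: np.ndarray
    source_threshold: float = 0.2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask.ndim != 3:
            raise ValueError("GM mask must be 3-D")
        if self.n_voxels < 2:
            raise ValueError("GM mask must contain at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def world_coords(self) -> np.ndarray:
        """World-mm coordinates of the centers of all in-mask voxels, (V, 3)."""
        ijk = np.column_stack(np.nonzero(self.mask)).astype(np.float64)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ICCMap:
    """A 3-D map of ICC values on a gray-matter mask.

    ``values`` is zero outside the mask.  ``per_voxel_counts`` holds the
    number of voxel pairs n_i entering each voxel's mean; for the
    whole-brain mode this is n-1 everywhere on the mask.
    """

    values: np.ndarray
    mask: GMMask
    mode: str  # whole | short | long
    standardized: bool = False
    d_thr_mm: float | None = None
    per_voxel_counts: np.ndarray | None = None
    zero_variance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("whole", "short", "long"):
            raise ValueError(f"mode must be whole|short|long; got {self.mode!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("ICC values and mask shapes differ")

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask.mask]

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.mask.affine), path)
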
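"""Seed-based connectivity and resting-state-network overlap.

A spherical seed region is placed at a cluster peak (4 mm radius by
convention), its mean denoised time series is correlated with every
in-mask voxel, the per-subject correlation maps are Fisher-transformed
and tested against zero at the group level with permutation
cluster-extent correction, and the resulting binary significance map is
scored against each of 14 canonical RSN templates by the overlap ratio

    R = N_overlap / N_RSN ,

the fraction of a template's voxels covered by the corrected map.  A
seed whose map overlaps several templates substantially is a connector
hub; a seed confined to a single template is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import (
    DEFAULT_ALPHA,
    DEFAULT_CDT_P,
    DEFAULT_CONNECTIVITY,
    DEFAULT_N_PERM,
    OneSampleTTest,
    significance_mask,
)
from .icc import ICCMap
from .types import BoldSeries, GMMask

#: Canonical labels of the 14 reference resting-state networks.
CANONICAL_RSN_LABELS = (
    "dDMN", "vDMN", "Prec", "LECN", "RECN", "aSal", "pSal",
    "Lang", "Visu", "BG", "hVis", "pVis", "Aud", "SMN",
)

DEFAULT_SEED_RADIUS_MM = 4.0


@dataclass
class RoiSpec:
    """A spherical seed: world-mm center and radius."""

    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_SEED_RADIUS_MM
    label: str = ""

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("seed radius must be positive")


@dataclass
class RSNTemplate:
    """A binary resting-state-network template mask."""

    name: str
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"RSN template {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapProfile:
    """Per-template overlap ratios for one seed's corrected map."""

    seed_label: str
    ratios: pd.DataFrame  # columns: template, n_overlap, n_rsn, ratio

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ratios["template"], self.ratios["ratio"]))


def make_spherical_roi(
    spec: RoiSpec, shape: tuple[int, int, int], affine: np.ndarray
) -> np.ndarray:
    """Boolean voxel mask of a sphere: voxel-center world distance to
    the seed center <= radius (boundary inclusive).  Guaranteed
    nonempty: if the sphere falls between voxel centers the nearest
    voxel is forced in."""
    affine = np.asarray(affine, dtype=np.float64)
    center = np.asarray(spec.center_mm, dtype=np.float64)
    inv = np.linalg.inv(affine)
    vox = inv[:3, :3] @ center + inv[:3, 3]
    if np.any(vox < -0.5) or np.any(vox > np.array(shape) - 0.5):
        raise ValueError(f"seed center {spec.center_mm} lies outside the volume")
    ijk = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((world - center) ** 2).sum(axis=1)
    inside = d2 <= spec.radius_mm**2
    if not inside.any():
        inside[np.argmin(d2)] = True
    return inside.reshape(shape)


def seed_connectivity_map(series: BoldSeries, roi_mask: np.ndarray, analysis_mask: GMMask) -> np.ndarray:
    """Pearson correlation of the ROI-mean time series with every
    in-mask voxel; zero outside the analysis mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != series.spatial_shape:
        raise ValueError("ROI mask grid does not match the series")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    seed_ts = series.data[roi_mask].mean(axis=0)
    seed_c = seed_ts - seed_ts.mean()
    seed_norm = np.linalg.norm(seed_c)
    if seed_norm == 0:
        raise ValueError("ROI mean time series has zero variance")
    x = series.data[analysis_mask.mask]
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    norms[norms == 0] = np.inf  # zero-variance voxels -> r = 0
    r = (xc @ seed_c) / (norms * seed_norm)
    out = np.zeros(series.spatial_shape)
    out[analysis_mask.mask] = r
    return out


def group_seed_map(
    subject_r_maps: list[np.ndarray],
    mask: GMMask,
    cdt_p: float = DEFAULT_CDT_P,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    connectivity: int = DEFAULT_CONNECTIVITY,
    fisher: bool = True,
) -> np.ndarray:
    """Binary group-level significance map for one seed.

    Per-subject correlation maps are Fisher r-to-z transformed
    (variance stabilization; disable with ``fisher=False``), tested
    voxel-wise against zero with a one-sample t, and thresholded by
    permutation cluster-extent FWE correction (sign-flip null).
    """
    from scipy import stats as _st

    maps = []
    for r in subject_r_maps:
        vals = np.asarray(r, dtype=np.float64)
        if fisher:
            vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
        maps.append(ICCMap(vals, mask, mode="whole", standardized=True))
    res = OneSampleTTest(maps).fit()
    table = res.cluster_correct(cdt_p=cdt_p, n_perm=n_perm, seed=seed, alpha=alpha,
                                connectivity=connectivity)
    thr = _st.t.isf(cdt_p, res.dof)
    return significance_mask(table, res.t_flat, mask, thr, connectivity)


def _resample_nearest(template: RSNTemplate, shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resampling of a binary template onto a target grid."""
    inv = np.linalg.inv(template.affine)
    ijk = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    src = world @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(
        template.mask.astype(np.float32), src.T, order=0, mode="constant", cval=0.0
    )
    return out.reshape(shape) > 0.5


def overlap_ratio(
    significance_mask_vol: np.ndarray,
    template: RSNTemplate,
    mask_affine: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """Overlap ratio R = N_overlap / N_RSN.

    R = 1 means the template lies fully within the corrected map; 0
    means no overlap.  Templates on a different grid are resampled to
    the map's grid by nearest neighbour (requires ``mask_affine``).

    Returns
    -------
    (R, N_overlap, N_RSN)
    """
    sig = np.asarray(significance_mask_vol, dtype=bool)
    tmask = template.mask
    if tmask.shape != sig.shape:
        if mask_affine is None:
            raise ValueError("template grid differs from map grid; pass mask_affine to resample")
        tmask = _resample_nearest(template, sig.shape, mask_affine)
    elif mask_affine is not None and not np.allclose(template.affine, mask_affine):
        tmask = _resample_nearest(template, sig.shape, mask_affine)
    n_rsn = int(tmask.sum())
    if n_rsn == 0:
        raise ValueError(f"template {template.name!r} is empty on the analysis grid")
    n_overlap = int((sig & tmask).sum())
    return n_overlap / n_rsn, n_overlap, n_rsn


def overlap_profile(
    significance_mask_vol: np.ndarray,
    templates: list[RSNTemplate],
    seed_label: str = "",
    labels: tuple[str, ...] = CANONICAL_RSN_LABELS,
    mask_affine: np.ndarray | None = None,
) -> OverlapProfile:
    """Overlap ratios of one corrected map against a fixed, ordered
    template set (the 14 canonical RSNs by default).

    Raises if any expected label is missing.
    """
    by_name = {t.name: t for t in templates}
    missing = [lab for lab in labels if lab not in by_name]
    if missing:
        raise ValueError(f"missing RSN template(s): {missing}")
    rows = []
    for lab in labels:
        r, n_ov, n_rsn = overlap_ratio(significance_mask_vol, by_name[lab], mask_affine)
        rows.append({"template": lab, "n_overlap": n_ov, "n_rsn": n_rsn, "ratio": r})
    return OverlapProfile(seed_label, pd.DataFrame(rows))
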
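"""Voxel-wise intrinsic connectivity contrast (ICC).

For an in-mask voxel i the (unstandardized) ICC is the mean of squared
Pearson correlations between its time series and those of the other
included voxels,

    ICC(i) = (1 / n_i) * sum_{j != i} r(i, j)^2 ,

a weighted hub-strength metric: voxels whose spontaneous fluctuations
are broadly coupled to the rest of gray matter score high.  Three
variants are produced by restricting the included voxels j:

* ``whole`` — every other in-mask voxel (n_i = n - 1);
* ``short`` — voxels whose world (Euclidean, mm) distance to i is
  within ``d_thr_mm`` (boundary inclusive);
* ``long``  — voxels strictly beyond ``d_thr_mm``.

The default distance threshold is 75 mm.  The pair matrix is never
materialized: correlations are accumulated over row chunks sized to a
memory cap, and the result is bit-identical for any chunk size because
each voxel's reduction runs over its full row at once.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import BoldSeries, GMMask, ICCMap

logger = logging.getLogger(__name__)

DEFAULT_GM_THRESHOLD = 0.2
DEFAULT_DTHR_MM = 75.0
MODES = ("whole", "short", "long")


def make_gm_mask(
    probability_map: np.ndarray,
    affine: np.ndarray,
    threshold: float = DEFAULT_GM_THRESHOLD,
) -> GMMask:
    """Gray-matter mask from a tissue-probability map.

    A voxel is included iff its probability strictly exceeds the
    threshold.
    """
    prob = np.asarray(probability_map, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob > threshold
    if mask.sum() < 2:
        raise ValueError(f"GM mask at threshold {threshold} has fewer than 2 voxels")
    return GMMask(mask, affine, source_threshold=threshold)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit L2 norm, so that the matrix
    product of rows gives Pearson correlations.  Zero-variance rows are
    set to zero (their correlations are defined as 0)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    # relative tolerance: a constant series leaves only round-off of the mean
    scale = np.abs(x).max(axis=1) + 1.0
    zero_var = norms <= 1e-12 * scale * np.sqrt(x.shape[1])
    norms[zero_var] = 1.0
    xs = xc / norms[:, None]
    xs[zero_var] = 0.0
    return xs, zero_var


def compute_icc(
    series: BoldSeries,
    mask: GMMask,
    mode: str = "whole",
    d_thr_mm: float = DEFAULT_DTHR_MM,
    denominator: str = "stratum",
    max_memory_mb: float = 256.0,
) -> ICCMap:
    """Unstandardized ICC map for one denoised subject.

    Parameters
    ----------
    mode
        ``whole``, ``short`` or ``long``.
    d_thr_mm
        Euclidean world-distance threshold separating short- from
        long-range pairs; pairs at exactly the threshold count as
        short.  Ignored for ``whole``.
    denominator
        ``stratum`` (default) divides each voxel's sum of r^2 by its own
        included-pair count n_i, keeping all three modes on the common
        [0, 1] scale.  ``global_n`` divides by the mask size n instead,
        the literal 1/n reading.
    max_memory_mb
        Cap on transient pair-block memory; results do not depend on it.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}; got {mode!r}")
    if denominator not in ("stratum", "global_n"):
        raise ValueError("denominator must be 'stratum' or 'global_n'")
    if series.spatial_shape != mask.mask.shape:
        raise ValueError("series and mask grids differ")
    t = series.n_volumes
    if t < 8:
        raise ValueError(f"need at least 8 timepoints; got {t}")
    n = mask.n_voxels

    x = series.data[mask.mask]  # V x T
    xs, zero_var = _standardize_rows(x)
    if zero_var.any():
        logger.warning("%d zero-variance voxel(s); their correlations set to 0", int(zero_var.sum()))

    need_dist = mode != "whole"
    coords = mask.world_coords() if need_dist else None
    d2_thr = d_thr_mm**2 if need_dist else None

    # per-chunk transient: chunk x V correlation block (+ distance block)
    bytes_per_row = n * 8 * (3 if need_dist else 2)
    chunk = max(1, int(max_memory_mb * 1e6 / bytes_per_row))

    sums = np.empty(n)
    counts = np.empty(n, dtype=np.int64)
    r2 = np.empty((chunk, n))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        # per-row matvec keeps each voxel's correlations (and hence the
        # result) bit-identical for every chunk size
        for k in range(i0, i1):
            r2[k - i0] = xs @ xs[k]
        blk = r2[: i1 - i0]
        np.square(blk, out=blk)
        rows = np.arange(i0, i1)
        blk[rows - i0, rows] = 0.0  # exclude self-pairs
        if need_dist:
            d2 = ((coords[i0:i1, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            included = d2 <= d2_thr if mode == "short" else d2 > d2_thr
            included[rows - i0, rows] = False
            blk[~included] = 0.0
            counts[i0:i1] = included.sum(axis=1)
        else:
            counts[i0:i1] = n - 1
        sums[i0:i1] = blk.sum(axis=1)

    if denominator == "global_n":
        values_flat = sums / n
    else:
        values_flat = np.zeros(n)
        nonempty = counts > 0
        values_flat[nonempty] = sums[nonempty] / counts[nonempty]
        if not nonempty.all():
            logger.warning(
                "%d voxel(s) with empty %s-range stratum; ICC set to 0", int((~nonempty).sum()), mode
            )

    values = np.zeros(mask.mask.shape)
    values[mask.mask] = values_flat
    count_map = np.zeros(mask.mask.shape, dtype=np.int64)
    count_map[mask.mask] = counts
    zv_map = np.zeros(mask.mask.shape, dtype=bool)
    zv_map[mask.mask] = zero_var
    return ICCMap(
        values,
        mask,
        mode=mode,
        standardized=False,
        d_thr_mm=None if mode == "whole" else d_thr_mm,
        per_voxel_counts=count_map,
        zero_variance=zv_map,
    )


def compute_all_icc(
    series: BoldSeries,
    mask: GMMask,
    d_thr_mm: float = DEFAULT_DTHR_MM,
    denominator: str = "stratum",
    max_memory_mb: float = 256.0,
) -> dict[str, ICCMap]:
    """Whole-brain, short-range and long-range ICC maps in one call."""
    return {
        mode: compute_icc(series, mask, mode, d_thr_mm, denominator, max_memory_mb)
        for mode in MODES
    }


def standardize_map(icc_map: ICCMap) -> ICCMap:
    """z-score an ICC map over its mask (population s.d.).

    Standardization makes maps comparable across subjects without
    altering each map's topography (voxel rank order is preserved).
    Standardizing an already-standardized map is a no-op up to floating
    point.
    """
    vals = icc_map.in_mask_values
    mu = vals.mean()
    sd = vals.std()  # population (divide-by-N) convention
    if sd == 0:
        raise ValueError("cannot standardize a constant ICC map (zero s.d. over the mask)")
    z = np.zeros_like(icc_map.values)
    z[icc_map.mask.mask] = (vals - mu) / sd
    return ICCMap(
        z,
        icc_map.mask,
        mode=icc_map.mode,
        standardized=True,
        d_thr_mm=icc_map.d_thr_mm,
        per_voxel_counts=icc_map.per_voxel_counts,
        zero_variance=icc_map.zero_variance,
    )
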
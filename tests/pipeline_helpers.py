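"""Shared helpers for the test suite: independent brute-force oracles
and the end-to-end cohort analysis used by the recovery/calibration
tests."""

from __future__ import annotations

import numpy as np

from iccmap.glm import DesignMatrix, VoxelwiseGLM
from iccmap.icc import compute_icc, make_gm_mask, standardize_map
from iccmap.preprocess import compute_fd, denoise
from iccmap.synthetic import SyntheticCohortSpec, generate_cohort
from iccmap.types import BoldSeries, GMMask


def naive_icc(series: BoldSeries, mask: GMMask, mode: str, d_thr_mm: float) -> np.ndarray:
    """All-pairs double-loop ICC oracle (per-pair np.corrcoef), flat
    over in-mask voxels.  Deliberately independent of the chunked
    engine."""
    x = series.data[mask.mask]
    coords = mask.world_coords()
    v = x.shape[0]
    out = np.zeros(v)
    for i in range(v):
        total, count = 0.0, 0
        for j in range(v):
            if i == j:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if mode == "short" and d > d_thr_mm:
                continue
            if mode == "long" and d <= d_thr_mm:
                continue
            sj = x[j] - x[j].mean()
            si = x[i] - x[i].mean()
            denom = np.linalg.norm(si) * np.linalg.norm(sj)
            r = float(si @ sj / denom) if denom > 0 else 0.0
            total += r * r
            count += 1
        out[i] = total / count if count else 0.0
    return out


def ols_t_oracle(y: np.ndarray, x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closed-form per-voxel OLS contrast t via explicit normal
    equations, columns of y are voxels."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
    return (c @ beta) / se


def analyze_cohort(seed: int, age_effect: float, n_perm: int = 500,
                   contrasts: tuple[str, ...] = ("age-",)):
    """Full pipeline on one synthetic cohort at the default study
    conditions (40 subjects, 16^3 grid, 120 timepoints): generate,
    denoise, whole-brain z-ICC, voxelwise GLM, permutation
    cluster-extent correction.

    Returns a dict with per-contrast cluster tables, the significant
    voxel mask of the first contrast, the planted hub mask and fitted
    results.
    """
    spec = SyntheticCohortSpec(rng_seed=seed, age_effect=age_effect)
    bold, motion, gm_prob, _templates, cov, truth = generate_cohort(spec)
    mask = make_gm_mask(gm_prob, spec.affine)
    maps, fds = [], []
    for b, m in zip(bold, motion):
        clean = denoise(b, m)
        maps.append(standardize_map(compute_icc(clean, mask, "whole")))
        fds.append(compute_fd(m)[5:].mean())
    design = DesignMatrix.from_covariates(cov.assign(mean_fd=fds))
    res = VoxelwiseGLM(maps, design).fit()
    tables = {
        con: res.cluster_correct(con, n_perm=n_perm, seed=seed * 7 + i + 1)
        for i, con in enumerate(contrasts)
    }
    out = {"tables": tables, "results": res, "hub_mask": truth.hub_mask, "gm_mask": mask}
    first = contrasts[0]
    out["sig_mask"] = (
        res.significant_voxels(first, tables[first]) if len(tables[first]) else
        np.zeros(mask.mask.shape, dtype=bool)
    )
    return out
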
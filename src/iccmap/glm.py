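"""Group-level voxel-wise inference on ICC maps.

Two model classes follow the Model/Results convention: build the model
from per-subject maps (plus a design matrix for the regression), call
``fit()``, and interrogate the Results object for t-maps, permutation
FWE-corrected cluster tables and a text summary.

* :class:`OneSampleTTest` — voxel-wise one-sample t of z-ICC maps
  against zero, characterizing where ICC is reliably high across
  subjects.
* :class:`VoxelwiseGLM` — per-voxel OLS of ICC on age and cognitive
  score with sex and mean FD as nuisance covariates; one-sided signed
  contrasts Age(+), Age(-), ACER(+), ACER(-).

Family-wise-error control is nonparametric: the null distribution of
the maximum statistic (peak voxel t, or supra-threshold cluster extent
at a cluster-defining threshold) is built by sign-flipping (one-sample)
or Freedman–Lane residual permutation (regression), which is exact
under exchangeability and needs no smoothness estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import GMMask, ICCMap

DEFAULT_CDT_P = 0.001
DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_EXTENT_MIN = 25
#: 3-D connectivity for cluster formation (count of neighbours): 6, 18 or 26.
DEFAULT_CONNECTIVITY = 26

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

CLUSTER_COLUMNS = ["x", "y", "z", "stat", "z_value", "k", "p_fwe"]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with named one-sided contrasts."""

    matrix: np.ndarray
    columns: list[str]
    contrasts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("design matrix shape does not match column labels")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            bad = self._collinear_columns()
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    def _collinear_columns(self) -> list[str]:
        from scipy.linalg import qr

        _, r, piv = qr(self.matrix, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > 1e-10 * diag[0]).sum())
        return [self.columns[i] for i in sorted(piv[rank:])]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_covariates(cls, covariates: pd.DataFrame) -> "DesignMatrix":
        """Standard design from a covariate table with columns
        ``age``, ``acer_total``, ``sex`` and ``mean_fd``.

        Age and ACE-R are the regressors of interest; sex and mean FD
        enter as regressors of no interest.  Signed contrasts
        ``age+ / age- / acer+ / acer-`` are attached.
        """
        cols = ["intercept", "age", "acer_total", "sex", "mean_fd"]
        n = len(covariates)
        x = np.column_stack(
            [
                np.ones(n),
                covariates["age"].to_numpy(float),
                covariates["acer_total"].to_numpy(float),
                covariates["sex"].to_numpy(float),
                covariates["mean_fd"].to_numpy(float),
            ]
        )
        e = np.eye(5)
        contrasts = {
            "age+": e[1],
            "age-": -e[1],
            "acer+": e[2],
            "acer-": -e[2],
        }
        return cls(x, cols, contrasts)


@dataclass
class StatMap:
    """3-D statistic map on the GM mask."""

    statistic: np.ndarray
    mask: GMMask
    dof: int
    kind: str  # t_one_sample | t_regression
    contrast: str = ""
    flagged: np.ndarray | None = field(default=None, repr=False)

    @property
    def in_mask(self) -> np.ndarray:
        return self.statistic[self.mask.mask]


# ---------------------------------------------------------------------------
# statistic engines (vectorized over voxels)
# ---------------------------------------------------------------------------

_T_CAP = 1e6  # stand-in for +/- infinity where the residual variance is 0


def _one_sample_t(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columns of y (N x V) tested against 0. Returns (t, zero_var_flag)."""
    n = y.shape[0]
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros(y.shape[1])
    ok = ~zero
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    # identical maps: infinite t where the mean is nonzero, flagged 0 where it is 0
    inf = zero & (mean != 0)
    t[inf] = np.sign(mean[inf]) * _T_CAP
    return t, zero & (mean == 0)


class _OLSEngine:
    """Precomputed pieces for repeated contrast t-tests of Y = X b + e."""

    def __init__(self, x: np.ndarray):
        self.x = x
        self.pinv = np.linalg.pinv(x)
        self.xtx_inv = np.linalg.inv(x.T @ x)
        self.dof = x.shape[0] - np.linalg.matrix_rank(x)

    def t_stat(self, y: np.ndarray, c: np.ndarray) -> np.ndarray:
        """t for contrast c, vectorized over columns of y (N x V)."""
        beta = self.pinv @ y
        resid = y - self.x @ beta
        sigma2 = (resid**2).sum(axis=0) / self.dof
        c = np.asarray(c, dtype=np.float64)
        var_c = c @ self.xtx_inv @ c
        cb = c @ beta
        se = np.sqrt(sigma2 * var_c)
        t = np.zeros(y.shape[1])
        ok = se > 0
        t[ok] = cb[ok] / se[ok]
        t[~ok] = np.sign(cb[~ok]) * _T_CAP
        return t


def _stack_maps(maps: list[ICCMap]) -> tuple[np.ndarray, GMMask]:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.mask.shape != mask.mask.shape or not np.allclose(m.mask.affine, mask.affine):
            raise ValueError("all subject maps must share the same mask grid and affine")
    y = np.stack([m.in_mask_values for m in maps])  # N x V
    return y, mask


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t to a standard-normal deviate by matching tail probability."""
    t = np.clip(t, -37.0, 37.0)  # beyond this both tails underflow identically
    return stats.norm.isf(stats.t.sf(t, dof))


def _label_clusters(
    t_flat: np.ndarray, mask: GMMask, threshold: float, connectivity: int
) -> tuple[np.ndarray, int]:
    """Label supra-threshold (t >= threshold) in-mask voxels."""
    vol = np.zeros(mask.mask.shape, dtype=bool)
    vol[mask.mask] = t_flat >= threshold
    return ndimage.label(vol, structure=_STRUCTURES[connectivity])


def _cluster_sizes(labels: np.ndarray, n_labels: int) -> np.ndarray:
    if n_labels == 0:
        return np.zeros(0, dtype=np.int64)
    return np.bincount(labels[labels > 0], minlength=n_labels + 1)[1:]


def _max_cluster_size(t_flat: np.ndarray, mask: GMMask, threshold: float, connectivity: int) -> int:
    labels, n = _label_clusters(t_flat, mask, threshold, connectivity)
    sizes = _cluster_sizes(labels, n)
    return int(sizes.max()) if sizes.size else 0


def _cluster_table(
    t_flat: np.ndarray,
    mask: GMMask,
    threshold: float,
    connectivity: int,
    null_max_sizes: np.ndarray,
    n_perm: int,
    dof: int,
    alpha: float,
    extent_min: int = 1,
) -> pd.DataFrame:
    """Observed supra-threshold clusters with permutation-corrected p."""
    labels, n = _label_clusters(t_flat, mask, threshold, connectivity)
    tvol = np.zeros(mask.mask.shape)
    tvol[mask.mask] = t_flat
    rows = []
    for lab in range(1, n + 1):
        inside = labels == lab
        size = int(inside.sum())
        if size < extent_min:
            continue
        idx = np.argwhere(inside)
        peak_local = np.argmax(tvol[inside])
        peak_ijk = idx[peak_local]
        peak_t = float(tvol[tuple(peak_ijk)])
        world = mask.affine[:3, :3] @ peak_ijk + mask.affine[:3, 3]
        p = (1 + int((null_max_sizes >= size).sum())) / (1 + n_perm)
        rows.append(
            {
                "x": world[0],
                "y": world[1],
                "z": world[2],
                "stat": peak_t,
                "z_value": float(_t_to_z(np.array([peak_t]), dof)[0]),
                "k": size,
                "p_fwe": p,
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    table = table[table["p_fwe"] < alpha]
    return table.sort_values("stat", ascending=False, ignore_index=True)


def significance_mask(table: pd.DataFrame, t_flat: np.ndarray, mask: GMMask,
                      threshold: float, connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """Binary volume of all voxels belonging to the table's significant
    clusters (identified by re-labelling at the same threshold)."""
    labels, n = _label_clusters(t_flat, mask, threshold, connectivity)
    out = np.zeros(mask.mask.shape, dtype=bool)
    if table.empty or n == 0:
        return out
    sig_sizes = set(int(k) for k in table["k"])
    tvol = np.zeros(mask.mask.shape)
    tvol[mask.mask] = t_flat
    for lab in range(1, n + 1):
        inside = labels == lab
        size = int(inside.sum())
        peak = float(tvol[inside].max())
        if any(
            abs(size - int(row.k)) == 0 and abs(peak - float(row.stat)) < 1e-9
            for row in table.itertuples()
        ):
            out |= inside
    return out


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class OneSampleTTest:
    """One-sample t-test of standardized ICC maps against zero.

    Parameters
    ----------
    maps
        Per-subject z-ICC maps on a common mask (>= 3 subjects).
    """

    def __init__(self, maps: list[ICCMap]):
        if len(maps) < 3:
            raise ValueError("one-sample test needs at least 3 subject maps")
        self.y, self.mask = _stack_maps(maps)
        self.n_subjects = self.y.shape[0]

    def fit(self) -> "OneSampleResults":
        t, flagged = _one_sample_t(self.y)
        return OneSampleResults(self, t, flagged)


class OneSampleResults:
    """Results of :class:`OneSampleTTest`."""

    def __init__(self, model: OneSampleTTest, t_flat: np.ndarray, flagged: np.ndarray):
        self.model = model
        self.t_flat = t_flat
        self.dof = model.n_subjects - 1
        flag_map = np.zeros(model.mask.mask.shape, dtype=bool)
        flag_map[model.mask.mask] = flagged
        self._flag_map = flag_map

    def t_map(self) -> StatMap:
        vol = np.zeros(self.model.mask.mask.shape)
        vol[self.model.mask.mask] = self.t_flat
        return StatMap(vol, self.model.mask, self.dof, "t_one_sample", flagged=self._flag_map)

    def _null_max(self, statistic, n_perm: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        y = self.model.y
        out = np.empty(n_perm)
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=y.shape[0])
            t_p, _ = _one_sample_t(signs[:, None] * y)
            out[p] = statistic(t_p)
        return out

    def cluster_correct(
        self,
        cdt_p: float = DEFAULT_CDT_P,
        n_perm: int = DEFAULT_N_PERM,
        seed: int = 0,
        alpha: float = DEFAULT_ALPHA,
        connectivity: int = DEFAULT_CONNECTIVITY,
    ) -> pd.DataFrame:
        """Cluster-extent FWE correction by sign-flip permutation.

        Clusters are formed at the analytic Student-t cluster-defining
        threshold for one-sided ``cdt_p``; the corrected p of an
        observed cluster is its extent's rank within the permutation
        null of the maximum extent.
        """
        if not 0 < cdt_p <= 0.05:
            raise ValueError("cdt_p must lie in (0, 0.05]")
        if n_perm < 100:
            raise ValueError("need at least 100 permutations")
        thr = stats.t.isf(cdt_p, self.dof)
        null = self._null_max(
            lambda t: _max_cluster_size(t, self.model.mask, thr, connectivity), n_perm, seed
        )
        return _cluster_table(
            self.t_flat, self.model.mask, thr, connectivity, null, n_perm, self.dof, alpha
        )

    def voxel_fwe(
        self,
        p_fwe: float = DEFAULT_ALPHA,
        extent_min: int = DEFAULT_EXTENT_MIN,
        n_perm: int = DEFAULT_N_PERM,
        seed: int = 0,
        connectivity: int = DEFAULT_CONNECTIVITY,
    ) -> pd.DataFrame:
        """Voxel-level FWE thresholding with a cluster-extent floor.

        The voxel threshold is the (1 - p_fwe) quantile of the
        permutation null of the maximum t; surviving clusters smaller
        than ``extent_min`` voxels (default 25) are discarded, clusters
        of at least ``extent_min`` are kept.
        """
        if extent_min < 1:
            raise ValueError("extent_min must be >= 1")
        null = self._null_max(lambda t: float(t.max()), n_perm, seed)
        thr = float(np.quantile(null, 1 - p_fwe, method="higher"))
        # cluster p here is voxel-level: peak t against the max-t null
        labels, n = _label_clusters(self.t_flat, self.model.mask, thr, connectivity)
        tvol = np.zeros(self.model.mask.mask.shape)
        tvol[self.model.mask.mask] = self.t_flat
        rows = []
        for lab in range(1, n + 1):
            inside = labels == lab
            size = int(inside.sum())
            if size < extent_min:
                continue
            idx = np.argwhere(inside)
            peak_ijk = idx[np.argmax(tvol[inside])]
            peak_t = float(tvol[tuple(peak_ijk)])
            world = self.model.mask.affine[:3, :3] @ peak_ijk + self.model.mask.affine[:3, 3]
            p = (1 + int((null >= peak_t).sum())) / (1 + n_perm)
            rows.append(
                {
                    "x": world[0], "y": world[1], "z": world[2],
                    "stat": peak_t,
                    "z_value": float(_t_to_z(np.array([peak_t]), self.dof)[0]),
                    "k": size, "p_fwe": p,
                }
            )
        return pd.DataFrame(rows, columns=CLUSTER_COLUMNS).sort_values(
            "stat", ascending=False, ignore_index=True
        )

    def summary(self) -> str:
        t = self.t_flat
        return (
            f"One-sample t-test | subjects: {self.model.n_subjects} | dof: {self.dof}\n"
            f"mask voxels: {self.model.mask.n_voxels}\n"
            f"t range: [{t.min():.3f}, {t.max():.3f}], mean {t.mean():.3f}\n"
            f"zero-variance voxels flagged: {int(self._flag_map.sum())}"
        )


class VoxelwiseGLM:
    """Mass-univariate OLS of ICC maps on subject covariates.

    Each in-mask voxel is regressed on the design (intercept, age,
    ACE-R, sex, mean FD by default); inference is on one-sided
    t-contrasts of single regressors, with permutation FWE correction.
    """

    def __init__(self, maps: list[ICCMap], design: DesignMatrix):
        self.y, self.mask = _stack_maps(maps)
        if design.n_subjects != self.y.shape[0]:
            raise ValueError(
                f"design has {design.n_subjects} rows but {self.y.shape[0]} maps were given"
            )
        self.design = design
        self._engine = _OLSEngine(design.matrix)

    def fit(self) -> "VoxelwiseGLMResults":
        beta = self._engine.pinv @ self.y
        return VoxelwiseGLMResults(self, beta)


class VoxelwiseGLMResults:
    """Results of :class:`VoxelwiseGLM`: per-voxel coefficients and
    contrast t-maps, with Freedman–Lane permutation cluster inference."""

    def __init__(self, model: VoxelwiseGLM, beta: np.ndarray):
        self.model = model
        self.beta = beta  # P x V
        self.dof = model._engine.dof

    def _contrast_vec(self, contrast: str | np.ndarray) -> np.ndarray:
        if isinstance(contrast, str):
            try:
                return self.model.design.contrasts[contrast]
            except KeyError:
                raise KeyError(
                    f"unknown contrast {contrast!r}; have {sorted(self.model.design.contrasts)}"
                ) from None
        return np.asarray(contrast, dtype=np.float64)

    def t_flat(self, contrast: str | np.ndarray) -> np.ndarray:
        c = self._contrast_vec(contrast)
        return self.model._engine.t_stat(self.model.y, c)

    def t_map(self, contrast: str | np.ndarray) -> StatMap:
        name = contrast if isinstance(contrast, str) else "custom"
        vol = np.zeros(self.model.mask.mask.shape)
        vol[self.model.mask.mask] = self.t_flat(contrast)
        return StatMap(vol, self.model.mask, self.dof, "t_regression", contrast=name)

    def coefficient_map(self, column: str) -> np.ndarray:
        i = self.model.design.columns.index(column)
        vol = np.zeros(self.model.mask.mask.shape)
        vol[self.model.mask.mask] = self.beta[i]
        return vol

    def _freedman_lane_null(
        self, contrast: str | np.ndarray, statistic, n_perm: int, seed: int
    ) -> np.ndarray:
        """Max-statistic null via Freedman–Lane: permute the rows of the
        reduced-model (nuisance-only) residuals, add back the nuisance
        fit, and recompute the full-model contrast t."""
        c = self._contrast_vec(contrast)
        x = self.model.design.matrix
        active = np.abs(c) > 0
        z = x[:, ~active]
        if z.size:
            pz = np.linalg.pinv(z)
            fit_z = z @ (pz @ self.model.y)
        else:
            fit_z = np.zeros_like(self.model.y)
        resid_z = self.model.y - fit_z
        rng = np.random.default_rng(seed)
        engine = self.model._engine
        out = np.empty(n_perm)
        n = x.shape[0]
        for p in range(n_perm):
            perm = rng.permutation(n)
            y_star = fit_z + resid_z[perm]
            out[p] = statistic(engine.t_stat(y_star, c))
        return out

    def cluster_correct(
        self,
        contrast: str | np.ndarray,
        cdt_p: float = DEFAULT_CDT_P,
        n_perm: int = DEFAULT_N_PERM,
        seed: int = 0,
        alpha: float = DEFAULT_ALPHA,
        connectivity: int = DEFAULT_CONNECTIVITY,
    ) -> pd.DataFrame:
        """Cluster-extent FWE-corrected table for a signed contrast.

        Clusters are defined at the analytic one-sided Student-t
        threshold for ``cdt_p`` (default 0.001); corrected p values come
        from the Freedman–Lane permutation null of the maximum cluster
        extent.  Deterministic given ``seed``.
        """
        if not 0 < cdt_p <= 0.05:
            raise ValueError("cdt_p must lie in (0, 0.05]")
        if n_perm < 100:
            raise ValueError("need at least 100 permutations")
        thr = stats.t.isf(cdt_p, self.dof)
        null = self._freedman_lane_null(
            contrast,
            lambda t: _max_cluster_size(t, self.model.mask, thr, connectivity),
            n_perm,
            seed,
        )
        return _cluster_table(
            self.t_flat(contrast), self.model.mask, thr, connectivity, null, n_perm,
            self.dof, alpha,
        )

    def significant_voxels(
        self, contrast: str | np.ndarray, table: pd.DataFrame,
        cdt_p: float = DEFAULT_CDT_P, connectivity: int = DEFAULT_CONNECTIVITY,
    ) -> np.ndarray:
        """Binary volume of the voxels in the table's clusters."""
        thr = stats.t.isf(cdt_p, self.dof)
        return significance_mask(table, self.t_flat(contrast), self.model.mask, thr, connectivity)

    def summary(self) -> str:
        d = self.model.design
        lines = [
            f"Voxel-wise OLS | subjects: {d.n_subjects} | dof: {self.dof}",
            f"mask voxels: {self.model.mask.n_voxels}",
            f"regressors: {', '.join(d.columns)}",
        ]
        for name in sorted(d.contrasts):
            t = self.t_flat(name)
            lines.append(f"contrast {name:6s}: t in [{t.min():.3f}, {t.max():.3f}]")
        return "\n".join(lines)
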
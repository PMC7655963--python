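"""Synthetic resting-state cohorts with known ground truth.

The generator emulates the data the pipeline expects — multi-subject
4-D BOLD in a common space, 6-parameter motion traces, a gray-matter
probability map, binary network templates and a covariate table — with
structure planted so every downstream stage is testable:

* latent-network covariance: each subject's gray-matter signal is
  ``loading_matrix @ latent_timecourses``, the latents being smoothed
  Gaussian processes whose spectrum lies mostly inside the 0.01–0.1 Hz
  passband at TR 2.5 s;
* connector-hub voxels: networks occupy spatially compact blocks and
  hub voxels sit on block borders, loading equally on the two abutting
  networks, so hubs have strictly higher whole-brain ICC than any
  non-hub voxel (exactly so at zero noise — latents are orthogonalized
  over the post-trim window);
* an age-modulated coupling effect: hub loadings are scaled by
  ``1 + age_effect * (age - mean age)``, so a negative slope lowers the
  hub signal-to-noise — and hence hub ICC — with age;
* head motion as a 6-parameter random walk, rotations scaled so their
  frame-wise-displacement contribution matches the translations.

Background (non-gray-matter) voxels carry pure noise and exercise the
GM masking; ACE-R scores are drawn independently of the BOLD model
unless ``acer_effect`` is set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .seeds import CANONICAL_RSN_LABELS, RSNTemplate
from .types import BoldSeries, MotionTrace

#: volumes prepended for the steady-state trim
N_DUMMY = 5
#: moving-average width (volumes) shaping the latent spectrum
SMOOTH_WIDTH = 5
#: FD rotation lever arm used to scale rotational motion steps
FD_RADIUS_MM = 50.0
#: GM probability inside / outside the gray-matter box
GM_PROB_IN, GM_PROB_OUT = 0.9, 0.02


@dataclass
class SyntheticCohortSpec:
    """Conditions of a synthetic resting-state study.

    Defaults describe a desk-scale cohort: 40 subjects on a 16^3 grid of
    3 mm voxels, 120 retained volumes at TR 2.5 s, four latent networks
    with unit-s.d. fluctuations in unit-s.d. white noise, 4% of
    gray-matter voxels planted as connector hubs, ages spanning 21–86
    years, and a hub-coupling slope of -0.012 per year of age (sized to
    a per-voxel Cohen's f^2 near 0.3 at this sample size).
    """

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 120  # post-trim target; N_DUMMY extra volumes are emitted
    tr_seconds: float = 2.5
    n_networks: int = 4
    network_amplitude: float = 1.0
    noise_sd: float = 1.0
    hub_voxel_fraction: float = 0.04
    age_range: tuple[float, float] = (21.0, 86.0)
    age_effect: float = -0.012  # hub-loading slope per year of age
    acer_effect: float = 0.0  # optional planted cognition slope per ACE-R point
    motion_sd_mm: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        n_vox = int(np.prod(self.grid_shape))
        if len(self.grid_shape) != 3 or any(g < 3 for g in self.grid_shape):
            raise ValueError("grid_shape must be three voxel counts, each >= 3")
        if not 27 <= n_vox <= 32768:
            raise ValueError(f"grid_shape voxel count {n_vox} outside desk scale [27, 32768]")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32 for a well-posed band-pass")
        if not 0 < self.hub_voxel_fraction < 1:
            raise ValueError("hub_voxel_fraction must lie in (0, 1)")
        if self.hub_voxel_fraction * n_vox < 1:
            raise ValueError("hub_voxel_fraction times total voxels must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 1 <= self.n_networks <= len(CANONICAL_RSN_LABELS):
            raise ValueError(f"n_networks must lie in [1, {len(CANONICAL_RSN_LABELS)}]")
        for name in ("voxel_size_mm", "tr_seconds", "network_amplitude"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd", "motion_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be [min, max] with min < max")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        a[:3, 3] = -self.voxel_size_mm * (np.array(self.grid_shape) - 1) / 2.0
        return a


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    network_assignment: np.ndarray  # 3-D int, -1 outside gray matter
    hub_mask: np.ndarray  # 3-D bool
    loading_matrix: np.ndarray  # (total voxels, n_networks); background rows zero
    subject_ages: np.ndarray
    subject_sex: np.ndarray
    true_acer: np.ndarray
    template_labels: tuple[str, ...] = field(default=())


def _split_dims(k: int) -> tuple[int, int, int]:
    """Factor k into a near-balanced 3-D block grid."""
    best, best_spread = (k, 1, 1), k
    for a in range(1, k + 1):
        if k % a:
            continue
        for b in range(1, k // a + 1):
            if (k // a) % b:
                continue
            c = k // (a * b)
            dims = tuple(sorted((a, b, c), reverse=True))
            spread = dims[0] - dims[2]
            if spread < best_spread:
                best, best_spread = dims, spread
    return best


def _plan_layout(spec: SyntheticCohortSpec):
    """Gray-matter box, per-voxel network labels, hub placement, loadings.

    The GM box is the grid center with a margin of ~1/5 per side; it is
    split into a near-cubic arrangement of network blocks.  Hub voxels
    are taken from the two voxel layers flanking each block-pair
    interface, nearest the interface centroid, with the hub quota split
    evenly over the borders; each hub loads 1 on both abutting networks.
    """
    g = np.array(spec.grid_shape)
    margin = np.maximum(1, g // 5)
    lo, hi = margin, g - margin
    dims = np.array(_split_dims(spec.n_networks))
    # assign the largest split count to the largest box axis
    box = hi - lo
    order = np.argsort(-box)
    dims_axis = np.empty(3, dtype=int)
    dims_axis[order] = np.sort(dims)[::-1]

    assignment = -np.ones(spec.grid_shape, dtype=int)
    edges = [np.linspace(lo[a], hi[a], dims_axis[a] + 1).astype(int) for a in range(3)]
    block_of = {}
    label = 0
    for bi in range(dims_axis[0]):
        for bj in range(dims_axis[1]):
            for bk in range(dims_axis[2]):
                sl = tuple(
                    slice(edges[a][b], edges[a][b + 1]) for a, b in zip(range(3), (bi, bj, bk))
                )
                assignment[sl] = label
                block_of[(bi, bj, bk)] = label
                label += 1

    gm = assignment >= 0
    n_gm = int(gm.sum())

    # face-adjacent block pairs
    borders = []
    for (bi, bj, bk), lab in block_of.items():
        for axis in range(3):
            nb = [bi, bj, bk]
            nb[axis] += 1
            lab2 = block_of.get(tuple(nb))
            if lab2 is not None:
                borders.append(((lab, lab2), axis, tuple(nb)))

    hub_mask = np.zeros(spec.grid_shape, dtype=bool)
    hub_nets: dict[tuple[int, int, int], tuple[int, int]] = {}
    if borders:
        per_border = max(1, int(round(spec.hub_voxel_fraction * n_gm / len(borders))))
        for (lab_a, lab_b), axis, _nb in borders:
            plane = int(np.argwhere(assignment == lab_b)[:, axis].min())
            # candidates: the two layers flanking the interface, in either block
            cand = np.argwhere(
                ((assignment == lab_a) | (assignment == lab_b))
                & _layer_mask(spec.grid_shape, axis, (plane - 1, plane))
            )
            centroid = cand.mean(axis=0)
            d2 = ((cand - centroid) ** 2).sum(axis=1)
            order_idx = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d2))
            for idx in order_idx[:per_border]:
                ijk = tuple(int(v) for v in cand[idx])
                hub_mask[ijk] = True
                hub_nets[ijk] = (lab_a, lab_b)

    loading = np.zeros((int(np.prod(spec.grid_shape)), spec.n_networks))
    flat_assignment = assignment.reshape(-1)
    in_gm = flat_assignment >= 0
    loading[np.nonzero(in_gm)[0], flat_assignment[in_gm]] = 1.0
    for ijk, (a, b) in hub_nets.items():
        row = np.ravel_multi_index(ijk, spec.grid_shape)
        loading[row] = 0.0
        loading[row, a] = 1.0
        loading[row, b] = 1.0
    return assignment, hub_mask, loading


def _layer_mask(shape, axis: int, layers: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for l in layers:
        sl = [slice(None)] * 3
        sl[axis] = l
        m[tuple(sl)] = True
    return m


def _make_latents(rng: np.random.Generator, n_total: int, k: int, amplitude: float) -> np.ndarray:
    """(n_total, k) latent network time-courses.

    Smoothed white noise (moving average of SMOOTH_WIDTH volumes)
    concentrates power below ~0.1 Hz at TR 2.5 s.  Over the post-trim
    window the columns are made exactly zero-mean and mutually
    orthogonal (QR against the intercept) and scaled to population s.d.
    ``amplitude`` — this makes noise-free correlation structure exact
    rather than asymptotic.
    """
    w = rng.standard_normal((n_total, k))
    sm = uniform_filter1d(w, size=SMOOTH_WIDTH, axis=0, mode="nearest")
    tail = sm[N_DUMMY:]
    t = tail.shape[0]
    if t < k + 2:
        raise ValueError("n_timepoints too small for the requested number of networks")
    m = np.column_stack([np.ones(t), tail])
    q, r = np.linalg.qr(m)
    cols = q[:, 1:] * np.sign(np.diag(r)[1:])  # keep orientation of the raw series
    cols = cols * (amplitude * np.sqrt(t))  # unit columns -> population s.d. amplitude
    head = sm[:N_DUMMY]
    head = head - tail.mean(axis=0)
    scale = amplitude / np.where(tail.std(axis=0) == 0, 1.0, tail.std(axis=0))
    out = np.vstack([head * scale, cols])
    return out


def generate_motion(spec: SyntheticCohortSpec, rng: np.random.Generator | None = None) -> MotionTrace:
    """Random-walk 6-parameter motion trace of ``n_timepoints + 5`` rows.

    Translation steps have s.d. ``motion_sd_mm``; rotation steps are
    scaled by 1/50 mm^-1 so their FD contribution (50 mm lever arm)
    matches the translations.  Zero ``motion_sd_mm`` gives an all-zero
    trace.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_timepoints + N_DUMMY
    steps = rng.normal(0.0, spec.motion_sd_mm, size=(n - 1, 6))
    steps[:, 3:] /= FD_RADIUS_MM
    params = np.zeros((n, 6))
    params[1:] = np.cumsum(steps, axis=0)
    return MotionTrace(params)


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate a full synthetic cohort.

    Returns
    -------
    (bold_list, motion_list, gm_probability_map, templates, covariates,
    ground_truth) — one :class:`BoldSeries` and :class:`MotionTrace` per
    subject, the GM probability volume, one binary
    :class:`RSNTemplate` per latent network (named with the canonical
    RSN labels), the covariate table (subject_id, age, sex, acer_total)
    and the planted :class:`GroundTruth`.  Identical spec and seed give
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    assignment, hub_mask, loading = _plan_layout(spec)
    affine = spec.affine
    n_total = spec.n_timepoints + N_DUMMY
    n_vox = int(np.prod(spec.grid_shape))

    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sex = rng.integers(0, 2, size=spec.n_subjects)
    acer = np.clip(np.round(rng.normal(96.3, 2.2, size=spec.n_subjects), 1), 80.0, 100.0)

    hub_rows = np.nonzero(hub_mask.reshape(-1))[0]
    mean_age = ages.mean()
    mean_acer = acer.mean()

    bold_list, motion_list = [], []
    for s in range(spec.n_subjects):
        latents = _make_latents(rng, n_total, spec.n_networks, spec.network_amplitude)
        l_s = loading.copy()
        gain = 1.0 + spec.age_effect * (ages[s] - mean_age) + spec.acer_effect * (
            acer[s] - mean_acer
        )
        l_s[hub_rows] *= max(gain, 0.05)
        signal = l_s @ latents.T  # n_vox x n_total
        noise = rng.normal(0.0, spec.noise_sd, size=(n_vox, n_total)) if spec.noise_sd > 0 else 0.0
        data = (signal + noise).reshape(*spec.grid_shape, n_total)
        bold_list.append(BoldSeries(data, affine, spec.tr_seconds))
        motion_list.append(generate_motion(spec, rng))

    gm_prob = np.where(assignment >= 0, GM_PROB_IN, GM_PROB_OUT)

    labels = CANONICAL_RSN_LABELS[: spec.n_networks]
    templates = [
        RSNTemplate(lab, (loading[:, k] > 0).reshape(spec.grid_shape), affine)
        for k, lab in enumerate(labels)
    ]

    covariates = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)],
            "age": ages,
            "sex": sex,
            "acer_total": acer,
        }
    )
    truth = GroundTruth(
        network_assignment=assignment,
        hub_mask=hub_mask,
        loading_matrix=loading,
        subject_ages=ages,
        subject_sex=sex,
        true_acer=acer,
        template_labels=labels,
    )
    return bold_list, motion_list, gm_prob, templates, covariates, truth


def write_cohort(out_dir: str | Path, spec: SyntheticCohortSpec) -> Path:
    """Generate a cohort and write it to disk in the on-disk layout the
    pipeline reads: per-subject BOLD NIfTI + motion text, GM probability
    NIfTI, one binary NIfTI per template, covariates CSV and a ground
    truth sidecar (.npz + JSON manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bold, motion, gm_prob, templates, covariates, truth = generate_cohort(spec)
    import nibabel as nib

    for sid, bs, mt in zip(covariates["subject_id"], bold, motion):
        bs.to_nifti(str(out / f"{sid}_bold.nii.gz"))
        mt.to_txt(str(out / f"rp_{sid}.txt"))
    nib.save(nib.Nifti1Image(gm_prob.astype(np.float32), spec.affine), str(out / "gm_prob.nii.gz"))
    tdir = out / "templates"
    tdir.mkdir(exist_ok=True)
    for t in templates:
        nib.save(
            nib.Nifti1Image(t.mask.astype(np.uint8), t.affine), str(tdir / f"{t.name}.nii.gz")
        )
    covariates.to_csv(out / "covariates.csv", index=False)
    np.savez_compressed(
        out / "ground_truth.npz",
        network_assignment=truth.network_assignment,
        hub_mask=truth.hub_mask,
        loading_matrix=truth.loading_matrix,
        subject_ages=truth.subject_ages,
        subject_sex=truth.subject_sex,
        true_acer=truth.true_acer,
    )
    (out / "manifest.json").write_text(
        json.dumps({"template_labels": list(truth.template_labels), "tr_seconds": spec.tr_seconds,
                    "n_timepoints_emitted": spec.n_timepoints + N_DUMMY}, indent=2)
    )
    return out
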
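"""Seed-based connectivity maps, spherical ROIs and RSN overlap
ratios/profiles."""

import numpy as np
import pytest

from iccmap.preprocess import denoise
from iccmap.seeds import (
    CANONICAL_RSN_LABELS,
    RoiSpec,
    RSNTemplate,
    group_seed_map,
    make_spherical_roi,
    overlap_profile,
    overlap_ratio,
    seed_connectivity_map,
)
from iccmap.types import BoldSeries, GMMask

AFF2 = np.diag([2.0, 2.0, 2.0, 1.0])


class TestSphericalRoi:
    def test_lattice_count_matches_brute_force_enumeration(self):
        shape = (11, 11, 11)
        center_ijk = np.array([5, 5, 5])
        center = AFF2[:3, :3] @ center_ijk + AFF2[:3, 3]
        roi = make_spherical_roi(RoiSpec(tuple(center), 4.0), shape, AFF2)
        # independent enumeration over the voxel lattice
        count = 0
        for i in range(11):
            for j in range(11):
                for k in range(11):
                    d2 = 4.0 * ((i - 5) ** 2 + (j - 5) ** 2 + (k - 5) ** 2)
                    count += d2 <= 16.0
        assert count == 33  # 1 + 6 + 12 + 8 + 6
        assert roi.sum() == count

    def test_tiny_radius_single_voxel(self):
        roi = make_spherical_roi(RoiSpec((4.0, 4.0, 4.0), 0.1), (5, 5, 5), AFF2)
        assert roi.sum() == 1
        assert roi[2, 2, 2]

    def test_between_centers_forces_nearest_voxel(self):
        roi = make_spherical_roi(RoiSpec((3.0, 3.0, 3.0), 0.2), (5, 5, 5), AFF2)
        assert roi.sum() == 1

    def test_translation_equivariance(self):
        shape = (12, 12, 12)
        r1 = make_spherical_roi(RoiSpec((8.0, 8.0, 8.0), 4.0), shape, AFF2)
        r2 = make_spherical_roi(RoiSpec((12.0, 10.0, 8.0), 4.0), shape, AFF2)
        np.testing.assert_array_equal(np.roll(r1, (2, 1, 0), axis=(0, 1, 2)), r2)

    def test_center_outside_volume_errors(self):
        with pytest.raises(ValueError):
            make_spherical_roi(RoiSpec((100.0, 0.0, 0.0), 4.0), (5, 5, 5), AFF2)


class TestSeedMap:
    def test_single_voxel_roi_self_correlation_one(self, rng):
        shape = (5, 5, 5)
        data = rng.standard_normal((*shape, 20))
        s = BoldSeries(data, AFF2, 2.5)
        mask = GMMask(np.ones(shape, bool), AFF2)
        roi = np.zeros(shape, bool)
        roi[2, 2, 2] = True
        out = seed_connectivity_map(s, roi, mask)
        np.testing.assert_allclose(out[2, 2, 2], 1.0, atol=1e-12)

    def test_negated_voxel_has_r_minus_one(self, rng):
        shape = (3, 3, 3)
        data = rng.standard_normal((*shape, 20))
        data[0, 0, 1] = -data[0, 0, 0]
        s = BoldSeries(data, AFF2, 2.5)
        mask = GMMask(np.ones(shape, bool), AFF2)
        roi = np.zeros(shape, bool)
        roi[0, 0, 0] = True
        out = seed_connectivity_map(s, roi, mask)
        np.testing.assert_allclose(out[0, 0, 1], -1.0, atol=1e-12)

    def test_matches_per_voxel_pearson_oracle(self, rng):
        shape = (5, 4, 1)
        data = rng.standard_normal((*shape, 15))
        s = BoldSeries(data, AFF2, 2.5)
        mask = GMMask(np.ones(shape, bool), AFF2)
        roi = np.zeros(shape, bool)
        roi[0, 0, 0] = roi[1, 0, 0] = True
        out = seed_connectivity_map(s, roi, mask)
        seed_ts = data[roi].mean(axis=0)
        for idx in np.ndindex(shape):
            expected = np.corrcoef(seed_ts, data[idx])[0, 1]
            np.testing.assert_allclose(out[idx], expected, atol=1e-12)

    def test_constant_roi_errors(self):
        shape = (3, 3, 3)
        s = BoldSeries(np.ones((*shape, 10)), AFF2, 2.5)
        mask = GMMask(np.ones(shape, bool), AFF2)
        roi = np.zeros(shape, bool)
        roi[0, 0, 0] = True
        with pytest.raises(ValueError):
            seed_connectivity_map(s, roi, mask)


class TestOverlapRatio:
    def _template(self, mask):
        return RSNTemplate("dDMN", mask, AFF2)

    def test_full_containment_gives_one(self):
        tmpl = np.zeros((6, 6, 6), bool)
        tmpl[1:4, 1:4, 1:4] = True
        sig = np.zeros((6, 6, 6), bool)
        sig[0:5, 0:5, 0:5] = True
        r, n_ov, n_rsn = overlap_ratio(sig, self._template(tmpl))
        assert r == 1.0 and n_ov == n_rsn == 27

    def test_disjoint_masks_give_zero(self):
        tmpl = np.zeros((6, 6, 6), bool)
        tmpl[0:2] = True
        sig = np.zeros((6, 6, 6), bool)
        sig[4:6] = True
        r, n_ov, _ = overlap_ratio(sig, self._template(tmpl))
        assert r == 0.0 and n_ov == 0

    def test_partial_overlap_fraction(self):
        tmpl = np.zeros((10, 1, 1), bool)
        tmpl[0:10] = True
        sig = np.zeros((10, 1, 1), bool)
        sig[0:4] = True
        r, n_ov, n_rsn = overlap_ratio(sig, self._template(tmpl))
        assert (r, n_ov, n_rsn) == (0.4, 4, 10)

    def test_monotone_under_mask_growth(self, rng):
        shape = (8, 8, 8)
        tmpl = rng.random(shape) > 0.6
        small = rng.random(shape) > 0.7
        big = small | (rng.random(shape) > 0.7)
        r_small, *_ = overlap_ratio(small, self._template(tmpl))
        r_big, *_ = overlap_ratio(big, self._template(tmpl))
        assert r_big >= r_small

    def test_rigid_translation_invariance(self, rng):
        shape = (8, 8, 8)
        tmpl = np.zeros(shape, bool)
        tmpl[2:5, 2:5, 2:5] = True
        sig = rng.random(shape) > 0.5
        r0, *_ = overlap_ratio(sig, self._template(tmpl))
        shift = (1, 2, 0)
        r1, *_ = overlap_ratio(
            np.roll(sig, shift, axis=(0, 1, 2)),
            self._template(np.roll(tmpl, shift, axis=(0, 1, 2))),
        )
        assert r0 == r1

    def test_nearest_neighbour_resampling_identity_grid(self):
        # same world grid expressed with a shifted affine: template is
        # resampled onto the map grid without change of counts
        tmpl = np.zeros((6, 6, 6), bool)
        tmpl[2:4, 2:4, 2:4] = True
        aff_shift = AFF2.copy()
        aff_shift[:3, 3] += 2.0  # one-voxel world shift
        template = RSNTemplate("Aud", tmpl, aff_shift)
        sig = np.zeros((6, 6, 6), bool)
        sig[3:5, 3:5, 3:5] = True  # the template's voxels on the map grid
        r, n_ov, n_rsn = overlap_ratio(sig, template, mask_affine=AFF2)
        assert r == 1.0 and n_rsn == 8


class TestOverlapProfile:
    def _templates(self, shape=(6, 6, 6)):
        out = []
        for i, lab in enumerate(CANONICAL_RSN_LABELS):
            m = np.zeros(shape, bool)
            m.reshape(-1)[i * 6 : (i + 1) * 6] = True
            out.append(RSNTemplate(lab, m, AFF2))
        return out

    def test_empty_mask_all_zero(self):
        templates = self._templates()
        prof = overlap_profile(np.zeros((6, 6, 6), bool), templates)
        assert (prof.ratios["ratio"] == 0.0).all()
        assert list(prof.ratios["template"]) == list(CANONICAL_RSN_LABELS)

    def test_union_of_templates_all_one(self):
        templates = self._templates()
        union = np.zeros((6, 6, 6), bool)
        for t in templates:
            union |= t.mask
        prof = overlap_profile(union, templates)
        assert (prof.ratios["ratio"] == 1.0).all()

    def test_missing_template_errors(self):
        templates = self._templates()[:-1]
        with pytest.raises(ValueError, match="SMN"):
            overlap_profile(np.zeros((6, 6, 6), bool), templates)


@pytest.fixture(scope="module")
def seeded_analysis():
    from iccmap.icc import make_gm_mask
    from iccmap.synthetic import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(n_subjects=12, noise_sd=0.5, rng_seed=11)
    bold, motion, gm_prob, templates, cov, truth = generate_cohort(spec)
    mask = make_gm_mask(gm_prob, spec.affine)
    cleaned = [denoise(b, m) for b, m in zip(bold, motion)]
    return spec, cleaned, mask, templates, truth


class TestConnectorHubDetection:
    def _profile_at(self, seeded_analysis, world):
        spec, cleaned, mask, templates, truth = seeded_analysis
        roi = make_spherical_roi(RoiSpec(tuple(world), 4.0), spec.grid_shape, spec.affine)
        rmaps = [seed_connectivity_map(c, roi, mask) for c in cleaned]
        sig = group_seed_map(rmaps, mask, n_perm=300, seed=5)
        return overlap_profile(
            sig, templates, labels=truth.template_labels
        ).ratios["ratio"].to_numpy()

    def test_hub_seed_connects_to_multiple_networks(self, seeded_analysis):
        spec, _, _, _, truth = seeded_analysis
        hub_ijk = np.argwhere(truth.hub_mask)[0]
        world = spec.affine[:3, :3] @ hub_ijk + spec.affine[:3, 3]
        ratios = self._profile_at(seeded_analysis, world)
        assert (ratios > 0.5).sum() >= 2

    def test_nonhub_seed_connects_to_single_network(self, seeded_analysis):
        spec, _, _, _, truth = seeded_analysis
        cand = np.argwhere((truth.network_assignment == 0) & ~truth.hub_mask)
        ijk = cand[len(cand) // 2]
        world = spec.affine[:3, :3] @ ijk + spec.affine[:3, 3]
        ratios = self._profile_at(seeded_analysis, world)
        assert (ratios > 0.5).sum() == 1

    def test_pure_noise_subjects_give_empty_map(self):
        from iccmap.icc import make_gm_mask
        from iccmap.synthetic import SyntheticCohortSpec, generate_cohort

        hits = 0
        for seed in range(5):
            spec = SyntheticCohortSpec(
                n_subjects=10, network_amplitude=1e-6, noise_sd=1.0,
                grid_shape=(10, 10, 10), n_timepoints=60, rng_seed=40 + seed,
            )
            bold, motion, gm_prob, templates, cov, truth = generate_cohort(spec)
            mask = make_gm_mask(gm_prob, spec.affine)
            cleaned = [denoise(b, m) for b, m in zip(bold, motion)]
            roi = make_spherical_roi(
                RoiSpec((0.0, 0.0, 0.0), 4.0), spec.grid_shape, spec.affine
            )
            rmaps = [seed_connectivity_map(c, roi, mask) for c in cleaned]
            sig = group_seed_map(rmaps, mask, n_perm=200, seed=seed)
            # the seed's own sphere can survive; any cluster beyond it counts
            outside = sig & ~roi
            hits += int(outside.any())
        assert hits <= 1

    def test_group_map_deterministic_given_seed(self, seeded_analysis):
        spec, cleaned, mask, templates, truth = seeded_analysis
        roi = make_spherical_roi(RoiSpec((0.0, 0.0, 0.0), 4.0), spec.grid_shape, spec.affine)
        rmaps = [seed_connectivity_map(c, roi, mask) for c in cleaned[:6]]
        s1 = group_seed_map(rmaps, mask, n_perm=150, seed=9)
        s2 = group_seed_map(rmaps, mask, n_perm=150, seed=9)
        np.testing.assert_array_equal(s1, s2)
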
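"""Curation operators: interpolation, registration, propagation, consistency."""

import numpy as np
import pytest
from scipy import ndimage

from cardioloop.curation import (
    Contour,
    DeformationField,
    apply_correction,
    contour_to_region,
    enforce_consistency,
    estimate_deformation,
    interpolate_slices,
    propagate_contour,
    region_to_contour,
)
from cardioloop.datamodel import CohortError, LABEL_IDS, LabelMask, iter_cases
from tests.conftest import make_ring_slice


def _disc_stack(radii, grid=96, centers=None):
    labels = np.zeros((1, len(radii), grid, grid), np.int16)
    yy, xx = np.mgrid[0:grid, 0:grid]
    for s, r in enumerate(radii):
        cy, cx = (grid / 2, grid / 2) if centers is None else centers[s]
        if r > 0:
            labels[0, s][np.hypot(yy - cy, xx - cx) <= r] = LABEL_IDS["lv_bloodpool"]
    return LabelMask(labels, (8.0, 1.0, 1.0))


def _dice(a, b):
    return 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)


class TestInterpolateSlices:
    def test_concentric_circles_interpolate_radius_linearly(self):
        mask = interpolate_slices(_disc_stack([10, 0, 20]), "lv_bloodpool", 0, [0, 2])
        yy, xx = np.mgrid[0:96, 0:96]
        disc15 = np.hypot(yy - 48, xx - 48) <= 15
        assert _dice(mask.labels[0, 1] == 3, disc15) >= 0.95
        # annotated slices unchanged
        assert np.array_equal(mask.labels[0, 0], _disc_stack([10, 0, 20]).labels[0, 0])

    def test_identical_bounding_slices_copy_through(self):
        mask = interpolate_slices(_disc_stack([14, 0, 14]), "lv_bloodpool", 0, [0, 2])
        assert np.array_equal(mask.labels[0, 1], mask.labels[0, 0])

    def test_translated_discs_give_midpoint_centroid(self):
        src = _disc_stack([12, 0, 12], centers=[(48, 38), (0, 0), (48, 58)])
        mask = interpolate_slices(src, "lv_bloodpool", 0, [0, 2])
        cy, cx = ndimage.center_of_mass(mask.labels[0, 1] == 3)
        assert cy == pytest.approx(48, abs=1.0)
        assert cx == pytest.approx(48, abs=1.0)

    def test_symmetric_in_bounding_slices(self):
        fwd = interpolate_slices(_disc_stack([10, 0, 20]), "lv_bloodpool", 0, [0, 2])
        rev = interpolate_slices(_disc_stack([20, 0, 10]), "lv_bloodpool", 0, [0, 2])
        assert np.array_equal(fwd.labels[0, 1], rev.labels[0, 1])

    def test_fewer_than_two_annotated_slices_rejected(self):
        with pytest.raises(CohortError, match=">= 2"):
            interpolate_slices(_disc_stack([10, 0, 20]), "lv_bloodpool", 0, [0])


class TestEstimateDeformation:
    @pytest.fixture(scope="class")
    def textured(self):
        rng = np.random.default_rng(0)
        return ndimage.gaussian_filter(rng.normal(size=(96, 96)), 3.0) * 100.0

    def test_identity_field_below_tenth_voxel(self, textured):
        field = estimate_deformation(textured[None], textured[None])
        assert field.magnitude.max() <= 0.1

    def test_known_translation_recovered(self, textured):
        moved = np.roll(textured, (3, 0), axis=(0, 1))
        field = estimate_deformation(textured[None], moved[None])
        inner = field.vectors[0, 20:76, 20:76]
        assert np.median(inner[..., 0]) == pytest.approx(3.0, abs=0.5)
        assert np.median(inner[..., 1]) == pytest.approx(0.0, abs=0.5)

    def test_smooth_synthetic_deformation_endpoint_error(self, textured):
        # smooth displacement of <= 5 voxel magnitude; pulling intensities
        # at grid + d means the forward point transport is -d
        yy, xx = np.mgrid[0:96, 0:96]
        dy = 4.0 * np.sin(np.pi * yy / 96) * np.sin(np.pi * xx / 96)
        dx = 3.0 * np.sin(np.pi * xx / 96) * np.sin(np.pi * yy / 96)
        warped = ndimage.map_coordinates(textured, [yy + dy, xx + dx], order=1)
        field = estimate_deformation(textured[None], warped[None])
        band = (np.hypot(yy - 48, xx - 48) > 15) & (np.hypot(yy - 48, xx - 48) < 40)
        err = np.hypot(field.vectors[0, ..., 0] + dy, field.vectors[0, ..., 1] + dx)
        assert err[band].mean() <= 1.5

    def test_grid_mismatch_rejected(self, textured):
        with pytest.raises(CohortError, match="grids differ"):
            estimate_deformation(textured[None], textured[None, :, :48])

    def test_identity_field_invariant(self):
        field = DeformationField(np.zeros((2, 8, 8, 2)), (8.0, 1.0, 1.0))
        assert field.magnitude.max() == 0.0
        with pytest.raises(CohortError):
            DeformationField(np.full((1, 4, 4, 2), np.nan), (8.0, 1.0, 1.0))


class TestPropagateContour:
    @staticmethod
    def _contour(grid=96, radius=16):
        region = np.hypot(*(np.mgrid[0:grid, 0:grid] - grid / 2)) <= radius
        return Contour("lv_endo", 0, 0, region_to_contour(region)), region

    def test_identity_fields_preserve_contour(self):
        contour, region = self._contour()
        fields = [DeformationField(np.zeros((1, 96, 96, 2)), (8, 1, 1))] * 3
        out = propagate_contour(contour, fields, range(1, 4))
        assert [c.phase for c in out] == [1, 2, 3]
        assert all(c.source == "propagated" and not c.corrected for c in out)
        for c in out:
            assert _dice(contour_to_region(c.points, (96, 96)), region) >= 0.99

    def test_uniform_translation_is_shape_preserving(self):
        contour, region = self._contour()
        vec = np.zeros((1, 96, 96, 2))
        vec[..., 0] = 2.0  # two rows per phase
        fields = [DeformationField(vec, (8, 1, 1))] * 2
        out = propagate_contour(contour, fields, range(1, 3))
        shifted = np.roll(region, 4, axis=0)
        assert _dice(contour_to_region(out[-1].points, (96, 96)), shifted) >= 0.97

    def test_phantom_contraction_tracked(self):
        from cardioloop.phantom import PhantomConfig, generate_cohort
        cfg = PhantomConfig(n_cases=1, phases=10, slices=6, grid=(96, 96), seed=3,
                            class_mix={"NOR": 1.0})
        cohort, _ = generate_cohort(cfg)
        case = next(iter_cases(cohort))
        img = case.image.voxels
        mask = case.latest_session().mask
        sl = 2
        fields = [estimate_deformation(img[t], img[t + 1], spacing=mask.spacing)
                  for t in range(3)]
        pool0 = mask.structure("lv_bloodpool", 0)[sl]
        contour = Contour("lv_endo", 0, sl, region_to_contour(pool0))
        for phase, prop in zip(range(1, 4), propagate_contour(contour, fields, range(1, 4))):
            region = contour_to_region(prop.points, pool0.shape)
            truth = mask.structure("lv_bloodpool", phase)[sl]
            assert _dice(region, truth) >= 0.9

    def test_non_adjacent_targets_rejected(self):
        contour, _ = self._contour()
        fields = [DeformationField(np.zeros((1, 96, 96, 2)), (8, 1, 1))]
        with pytest.raises(CohortError, match="contiguous"):
            propagate_contour(contour, fields, range(2, 3))


class TestEnforceConsistency:
    def test_protruding_endo_clipped(self):
        sl = make_ring_slice(rv_radius=0)
        yy, xx = np.mgrid[0:96, 0:96]
        sl[np.hypot(yy - 48, xx - 83) <= 8] = LABEL_IDS["lv_bloodpool"]
        fixed = enforce_consistency(LabelMask(sl[None, None], (8, 1, 1)), 0, 0)
        out = fixed.labels[0, 0]
        pool = out == LABEL_IDS["lv_bloodpool"]
        d = np.hypot(yy - 48, xx - 48)
        assert not (pool & (d > 31)).any()

    def test_rv_drawn_into_septum_reassigned_to_myocardium(self):
        sl = make_ring_slice()
        yy, xx = np.mgrid[0:96, 0:96]
        d = np.hypot(yy - 48, xx - 48)
        bite = (d > 24) & (d <= 30) & (np.abs(yy - 48) < 6) & (xx < 48)
        sl[bite] = LABEL_IDS["rv_bloodpool"]
        fixed = enforce_consistency(LabelMask(sl[None, None], (8, 1, 1)), 0, 0)
        out = fixed.labels[0, 0]
        assert (out[bite] == LABEL_IDS["lv_myocardium"]).mean() > 0.9
        rv = out == LABEL_IDS["rv_bloodpool"]
        epi = (out == LABEL_IDS["lv_myocardium"]) | (out == LABEL_IDS["lv_bloodpool"])
        assert not (rv & epi).any()

    def test_consistent_mask_unchanged(self):
        mask = LabelMask(make_ring_slice()[None, None], (8, 1, 1))
        fixed = enforce_consistency(mask, 0, 0)
        assert np.array_equal(fixed.labels, mask.labels)

    @pytest.mark.parametrize("trial", range(25))
    def test_random_perturbed_masks_idempotent_and_consistent(self, trial):
        rng = np.random.default_rng(1000 + trial)
        yy, xx = np.mgrid[0:96, 0:96]
        s = np.zeros((96, 96), np.int16)
        r_epi = rng.uniform(22, 34)
        r_endo = rng.uniform(10, r_epi - 5)
        cy, cx = 48 + rng.uniform(-5, 5, 2)
        dd = np.hypot(yy - cy, xx - cx)
        s[dd <= r_epi] = LABEL_IDS["lv_myocardium"]
        de = np.hypot(yy - cy - rng.uniform(-6, 6), xx - cx - rng.uniform(-6, 6))
        s[de <= r_endo] = LABEL_IDS["lv_bloodpool"]
        dr = np.hypot(yy - cy, xx - cx + r_epi + rng.uniform(-8, 6))
        s[(dr <= rng.uniform(8, 16)) & (dd > r_epi - rng.uniform(0, 8))] = \
            LABEL_IDS["rv_bloodpool"]
        mask = LabelMask(s[None, None], (8, 1, 1))
        once = enforce_consistency(mask, 0, 0)
        twice = enforce_consistency(once, 0, 0)
        assert np.array_equal(once.labels, twice.labels)
        out = once.labels[0, 0]
        rv = out == LABEL_IDS["rv_bloodpool"]
        myo = out == LABEL_IDS["lv_myocardium"]
        pool = out == LABEL_IDS["lv_bloodpool"]
        assert not (rv & (myo | pool)).any()
        assert (out > 0).sum() <= (s > 0).sum()  # never increases labelled volume


class TestApplyCorrection:
    def _session(self, small_cohort):
        cohort, _ = small_cohort
        case = next(iter_cases(cohort))
        return case, case.sessions[0]

    def test_single_edit_sets_exactly_one_flag(self, small_cohort):
        case, session = self._session(small_cohort)
        pool = session.mask.structure("lv_bloodpool", 0)[2]
        contour = Contour("lv_endo", 0, 2, region_to_contour(pool), corrected=True)
        new = apply_correction(session, [contour])
        assert new.origin == "corrected"
        flags = [k for k, v in new.per_contour_corrected.items() if v]
        assert flags == [(0, 2, "lv_bloodpool")]

    def test_original_session_untouched(self, small_cohort):
        case, session = self._session(small_cohort)
        before = session.mask.labels.copy()
        pool = session.mask.structure("lv_bloodpool", 0)[2]
        apply_correction(session, [Contour("lv_endo", 0, 2, region_to_contour(pool))])
        assert np.array_equal(session.mask.labels, before)
        assert session.origin == "automatic"

    def test_replacing_corrupted_slice_removes_area_jump(self, small_cohort):
        from cardioloop.phantom import inject_corruption
        case, session = self._session(small_cohort)
        bad, _ = inject_corruption(session, "slice_shift",
                                   {"slice": 2, "shift": (12, 0)}, seed=1)

        def max_area_jump(mask):
            areas = mask.structure("lv_bloodpool", 0).sum(axis=(1, 2)).astype(float)
            return np.abs(np.diff(areas)).max() if len(areas) > 1 else 0.0

        def max_centroid_jump(mask):
            pool = mask.structure("lv_bloodpool", 0)
            cs = [ndimage.center_of_mass(pool[s]) for s in range(pool.shape[0])
                  if pool[s].any()]
            return max(np.hypot(a[0] - b[0], a[1] - b[1])
                       for a, b in zip(cs, cs[1:]))

        truth_pool = session.mask.structure("lv_bloodpool", 0)[2]
        edits = [Contour("lv_endo", 0, 2, region_to_contour(truth_pool))]
        fixed = apply_correction(bad, edits)
        assert max_centroid_jump(fixed.mask) < max_centroid_jump(bad.mask)
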
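from dataclasses import replace

import numpy as np
import pytest

from carti3d.model import Compartment, ConfigError, Group
from carti3d.phantom import (
    LesionSpec,
    PhantomSpec,
    default_cohort_lesion,
    generate_cohort,
    generate_phantom,
    small_spec,
)
from oracles import local_thickness_brute_force


class TestFlatPlateauConstruction:
    def test_cartilage_is_exact_slab(self, flat_spec):
        res = generate_phantom(flat_spec)
        cart = res.cartilage_truth.voxels
        cols = cart.sum(axis=0)
        footprint = cols > 0
        # 50 µm at 5 µm voxels: every cartilage column is exactly 10 voxels
        assert footprint.any()
        assert (cols[footprint] == 10).all()
        assert res.true_mean_thickness[Compartment.MEDIAL] == pytest.approx(50.0)
        assert res.true_mean_thickness[Compartment.LATERAL] == pytest.approx(50.0)

    def test_truth_masks_disjoint(self, flat_spec):
        res = generate_phantom(flat_spec)
        assert not (res.bone_truth.voxels & res.cartilage_truth.voxels).any()

    def test_noise_free_levels_single_threshold_separable(self, flat_spec):
        res = generate_phantom(flat_spec)
        for stack in (res.uv, res.cy5):
            assert len(np.unique(stack.voxels)) == 3

    def test_truth_matches_brute_force_thickness_oracle(self):
        # tiny flat phantom so the exhaustive sphere oracle stays tractable
        spec = small_spec(
            grid_shape=(24, 24, 40),
            noise_sd=0.0,
            dome_height=0.0,
            thickness_ramp=0.0,
            plateau_height=20.0,
            cartilage_thickness_medial=30.0,
            cartilage_thickness_lateral=30.0,
        )
        res = generate_phantom(spec)
        oracle = local_thickness_brute_force(res.cartilage_truth.voxels, 5.0)
        interior = oracle[res.cartilage_truth.voxels]
        # the slab interior thickness equals the nominal value; allow the
        # lateral rim (one voxel) to deviate
        assert abs(np.median(interior) - 30.0) <= 5.0
        for comp in (Compartment.MEDIAL, Compartment.LATERAL):
            assert abs(res.true_mean_thickness[comp] - 30.0) <= 5.0


class TestLesionAndOsteophyte:
    def test_full_plateau_erosion_empties_medial(self, flat_spec):
        huge = LesionSpec(radius_x=1e6, radius_y=1e6, residual_thickness=0.0)
        res = generate_phantom(replace(flat_spec, lesion=huge))
        nx = flat_spec.grid_shape[2]
        medial_half = res.cartilage_truth.voxels[:, :, : nx // 2]
        assert medial_half.sum() == 0
        assert res.cartilage_truth.voxels[:, :, nx // 2 :].sum() > 0

    def test_residual_exceeding_thickness_rejected(self, flat_spec):
        bad = LesionSpec(radius_x=100, radius_y=100, residual_thickness=80.0)
        with pytest.raises(ConfigError):
            replace(flat_spec, lesion=bad)

    def test_osteophyte_adds_marginal_bone(self, small_phantom_spec):
        from carti3d.phantom import OsteophyteSpec

        base = generate_phantom(replace(small_phantom_spec, noise_sd=0.0))
        with_ost = generate_phantom(
            replace(small_phantom_spec, noise_sd=0.0,
                    osteophyte=OsteophyteSpec(radius=40.0))
        )
        extra = with_ost.bone_truth.voxels & ~base.bone_truth.voxels
        assert extra.sum() > 0
        # the bump sits at the medial (low-x) margin
        assert np.argwhere(extra)[:, 2].max() < base.bone_truth.shape[2] // 2


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_phantom_spec):
        a = generate_phantom(small_phantom_spec)
        b = generate_phantom(small_phantom_spec)
        np.testing.assert_array_equal(a.uv.voxels, b.uv.voxels)
        np.testing.assert_array_equal(a.cy5.voxels, b.cy5.voxels)

    def test_different_seed_different_noise(self, small_phantom_spec):
        a = generate_phantom(small_phantom_spec)
        b = generate_phantom(replace(small_phantom_spec, seed=99))
        assert (a.uv.voxels != b.uv.voxels).any()


class TestContrastValidation:
    def test_rejects_inverted_cy5_ordering(self):
        bad = {
            "uv": {"bone": 200.0, "cartilage": 30.0, "background": 20.0},
            "cy5": {"bone": 10.0, "cartilage": 25.0, "background": 90.0},
        }
        with pytest.raises(ConfigError):
            PhantomSpec(intensities=bad)


class TestCohort:
    def test_paired_design_and_effect_direction(self, small_phantom_spec):
        lesion = default_cohort_lesion(small_phantom_spec)
        samples, expected = generate_cohort(
            1, base_spec=small_phantom_spec, dmm_effect=lesion,
            thickness_jitter_sd=0.0, seed=0,
        )
        assert len(samples) == 2
        assert {s.group for s in samples} == {Group.CONTRALATERAL, Group.DMM}
        by = {
            (r.group, r.compartment): r.mean_thickness_um for r in expected
        }
        assert by[(Group.DMM, Compartment.MEDIAL)] < by[
            (Group.CONTRALATERAL, Compartment.MEDIAL)
        ]
        # the lateral compartment is spared; the lesion only nudges the VOI
        # split line, so lateral truth agrees to a small sub-voxel tolerance
        assert by[(Group.DMM, Compartment.LATERAL)] == pytest.approx(
            by[(Group.CONTRALATERAL, Compartment.LATERAL)], abs=0.5
        )

    def test_group_size_matches_study_design(self, small_phantom_spec):
        samples, expected = generate_cohort(
            4, base_spec=small_phantom_spec, dmm_effect=None, seed=1
        )
        assert len(samples) == 8
        assert len(expected) == 16

    def test_fixed_seed_reproducible(self, small_phantom_spec):
        a, _ = generate_cohort(2, base_spec=small_phantom_spec, seed=7)
        b, _ = generate_cohort(2, base_spec=small_phantom_spec, seed=7)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            np.testing.assert_array_equal(sa.cy5.voxels, sb.cy5.voxels)

    def test_n_pairs_must_be_positive(self, small_phantom_spec):
        with pytest.raises(ConfigError):
            generate_cohort(0, base_spec=small_phantom_spec)
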
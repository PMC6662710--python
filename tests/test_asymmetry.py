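"""Mirroring, overlap statistics, Dice/NOV, segments, deviation side."""

import numpy as np
import pytest

from mandisym import (
    EmptyOverlapError,
    GridMismatchError,
    LandmarkSet,
    Plane,
    VoxelMask,
    assess_deviation,
    box_pair_dice,
    make_box_pair,
    make_mandible_phantom,
    mirror_mask,
    mirrored_similarity,
    nonoverlap_mask,
    overlap_stats,
    segment_distribution,
)
from mandisym.phantom import PhantomSpec
from mandisym.pipeline import RunConfig, analyze_case, preprocess_mask
from mandisym.voxel_ops import BONE_HU_BAND, binarize
from conftest import brute_overlap_counts, random_mask

X0 = Plane(np.array([1.0, 0.0, 0.0]), 0.0)


def mask_on_midplane_grid(data, spacing=1.0):
    """Grid whose x = 0 plane is the mid-plane between voxel columns."""
    nx = data.shape[0]
    origin = np.array([-spacing * (nx - 1) / 2.0, 0.0, 0.0])
    return VoxelMask(data, spacing, origin)


class TestOverlapStats:
    def test_identical_masks(self, rng):
        m = random_mask(rng, (10, 10, 10))
        res = overlap_stats(m, m)
        assert res.dice == 1.0
        assert res.count_nonoverlap == 0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2], b[2:] = True, True
        ra = VoxelMask(a, 1.0, np.zeros(3))
        rb = VoxelMask(b, 1.0, np.zeros(3))
        res = overlap_stats(ra, rb)
        assert res.dice == 0.0
        assert res.count_nonoverlap == ra.count + rb.count

    def test_nested_boxes_hand_arithmetic(self):
        """|A| = 1000, |B| = 800 nested: dice = 1600/1800, NOV = 200."""
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[:10, :10, :10] = True
        b[:10, :10, :8] = True
        res = overlap_stats(
            VoxelMask(a, 1.0, np.zeros(3)), VoxelMask(b, 1.0, np.zeros(3))
        )
        assert res.count_intersection == 800
        assert res.dice == pytest.approx(1600 / 1800)
        assert res.count_nonoverlap == 200

    def test_symmetry_in_arguments(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (8, 8, 8))
        assert overlap_stats(a, b).dice == overlap_stats(b, a).dice

    def test_grid_mismatch_rejected(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (8, 8, 8), spacing=0.5)
        with pytest.raises(GridMismatchError):
            overlap_stats(a, b)

    def test_both_empty_rejected(self):
        e = VoxelMask(np.zeros((3, 3, 3), bool), 1.0, np.zeros(3))
        with pytest.raises(EmptyOverlapError):
            overlap_stats(e, e)

    def test_matches_brute_force_triple_count(self, rng):
        for _ in range(10):
            a = random_mask(rng, (16, 16, 16), p=0.4)
            b = random_mask(rng, (16, 16, 16), p=0.4)
            ca, cb, ci, cn = brute_overlap_counts(a.data, b.data)
            res = overlap_stats(a, b)
            assert (res.count_a, res.count_b) == (ca, cb)
            assert res.count_intersection == ci
            assert res.count_nonoverlap == cn

    def test_dice_nov_identity(self, rng):
        """dice = 1 - NOV/(|A|+|B|) holds exactly."""
        for _ in range(50):
            a = random_mask(rng, (10, 10, 10), p=rng.uniform(0.1, 0.6))
            b = random_mask(rng, (10, 10, 10), p=rng.uniform(0.1, 0.6))
            if a.count + b.count == 0:
                continue
            res = overlap_stats(a, b)
            total = res.count_a + res.count_b
            assert res.count_nonoverlap == total - 2 * res.count_intersection
            assert res.dice == pytest.approx(
                1.0 - res.count_nonoverlap / total, abs=1e-15
            )


class TestMirrorMask:
    def test_midplane_mirror_is_index_flip(self, rng):
        m = mask_on_midplane_grid(rng.random((10, 6, 6)) < 0.4)
        mirrored = mirror_mask(m, X0)
        np.testing.assert_array_equal(mirrored.data, m.data[::-1])

    def test_involution_for_grid_aligned_plane(self, rng):
        m = mask_on_midplane_grid(rng.random((8, 5, 5)) < 0.4)
        np.testing.assert_array_equal(mirror_mask(mirror_mask(m, X0), X0).data, m.data)

    def test_oblique_plane_nearly_preserves_volume(self):
        """Nearest-neighbour resampling across an oblique plane changes a
        40-voxel sphere's volume by < 2%."""
        n = 40
        idx = np.arange(n)
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        sphere = (X - 19.5) ** 2 + (Y - 19.5) ** 2 + (Z - 19.5) ** 2 <= 14**2
        m = VoxelMask(sphere, 1.0, np.array([-19.5, -19.5, -19.5]))
        normal = np.array([1.0, 0.7, 0.3])
        plane = Plane(normal / np.linalg.norm(normal), 0.0)
        mirrored = mirror_mask(m, plane)
        assert abs(mirrored.count - m.count) / m.count < 0.02

    def test_linear_resampling_close_to_nearest(self):
        n = 24
        idx = np.arange(n)
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        sphere = (X - 11.5) ** 2 + (Y - 11.5) ** 2 + (Z - 11.5) ** 2 <= 8**2
        m = VoxelMask(sphere, 1.0, np.array([-11.5, -11.5, -11.5]))
        normal = np.array([1.0, 0.4, 0.0])
        plane = Plane(normal / np.linalg.norm(normal), 0.0)
        a = mirror_mask(m, plane, method="nearest")
        b = mirror_mask(m, plane, method="linear")
        assert abs(a.count - b.count) / m.count < 0.05


class TestMirroredSimilarity:
    def test_symmetric_structure_dice_one(self, rng):
        half = rng.random((5, 6, 6)) < 0.5
        data = np.concatenate([half[::-1], half], axis=0)
        m = mask_on_midplane_grid(data)
        assert mirrored_similarity(m, X0).dice == 1.0

    def test_one_sided_structure_dice_zero_with_warning(self):
        data = np.zeros((8, 4, 4), bool)
        data[5:7] = True  # entirely on the positive-x side
        m = mask_on_midplane_grid(data)
        with pytest.warns(UserWarning, match="empty"):
            assert mirrored_similarity(m, X0).dice == 0.0

    def test_box_pair_phantom_closed_form(self):
        left_mask, right_mask, plane = make_box_pair((10, 10, 10), (10, 10, 8))
        combined = left_mask.with_data(left_mask.data | right_mask.data)
        res = mirrored_similarity(combined, plane)
        assert res.dice == pytest.approx(1600 / 1800)
        assert res.dice == pytest.approx(box_pair_dice((10, 10, 10), (10, 10, 8)))

    def test_hemi_equals_whole_structure_dice(self):
        """For a clean grid-aligned split, comparing mirrored-left vs right
        equals comparing the whole structure against its whole mirror."""
        vol, lm, _ = make_mandible_phantom(
            PhantomSpec(shape=(96, 96, 72), spacing=1.0,
                        right_scale=(1, 1, 0.9), lateral_shift_mm=5.0)
        )
        bone = preprocess_mask(vol, BONE_HU_BAND, 3)
        msp = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
        hemi = mirrored_similarity(bone, msp)
        whole_mirror = mirror_mask(bone, msp)
        whole = overlap_stats(bone, whole_mirror)
        assert hemi.dice == pytest.approx(whole.dice, abs=1e-12)

    def test_monotone_in_right_box_size(self):
        """Dice strictly decreases as the right box shrinks along one axis."""
        last = 1.1
        for rz in (10, 9, 8, 6, 4, 2):
            l_mask, r_mask, plane = make_box_pair((10, 10, 10), (10, 10, rz))
            combined = l_mask.with_data(l_mask.data | r_mask.data)
            d = mirrored_similarity(combined, plane).dice
            assert d < last
            assert d == pytest.approx(box_pair_dice((10, 10, 10), (10, 10, rz)))
            last = d


class TestSegmentDistribution:
    def test_fraction_split(self):
        data = np.zeros((10, 2, 2), bool)
        data[:5, 0, 0] = True  # 5 voxels, 2 on the positive side of x = 2.5
        data[6:11, 1, 1] = True
        m = VoxelMask(data, 1.0, np.zeros(3))
        plane = Plane(np.array([1.0, 0.0, 0.0]), 2.5)
        dist = segment_distribution(m, plane, ramus_side="positive")
        total = m.count
        pos = int((m.signed_distance_field(plane) >= 0)[data].sum())
        assert dist.ramus_fraction == pytest.approx(100 * pos / total)
        assert dist.ramus_fraction + dist.body_fraction == pytest.approx(100.0)

    def test_all_on_body_side(self):
        data = np.zeros((4, 2, 2), bool)
        data[:2] = True
        m = VoxelMask(data, 1.0, np.zeros(3))
        plane = Plane(np.array([1.0, 0.0, 0.0]), 10.0)
        dist = segment_distribution(m, plane)
        assert dist.ramus_fraction == 0.0
        assert dist.body_fraction == 100.0
        assert dist.body_mm3 == pytest.approx(8.0)

    def test_empty_nov_warns(self):
        m = VoxelMask(np.zeros((3, 3, 3), bool), 1.0, np.zeros(3))
        with pytest.warns(UserWarning, match="empty"):
            dist = segment_distribution(m, X0)
        assert dist.ramus_fraction == dist.body_fraction == 0.0


class TestAssessDeviation:
    @pytest.mark.parametrize(
        "me_x, expected_side, expected_dev, expected_included",
        [
            (5.0, "left", 5.0, True),
            (-4.0, "right", 4.0, False),  # strictly-greater-than-4 rule
            (0.0, "midline", 0.0, False),
        ],
    )
    def test_side_and_inclusion(self, me_x, expected_side, expected_dev,
                                expected_included):
        lm = LandmarkSet({"Me": (me_x, 30.0, 10.0)})
        res = assess_deviation(lm, X0)
        assert res.dev_side == expected_side
        assert res.deviation_mm == pytest.approx(expected_dev)
        assert res.included is expected_included

    def test_missing_menton_rejected(self):
        from mandisym import MissingLandmarkError

        with pytest.raises(MissingLandmarkError):
            assess_deviation(LandmarkSet({"N": (0, 0, 0)}), X0)


class TestNonoverlapMask:
    def test_symmetric_difference(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (8, 8, 8))
        nov = nonoverlap_mask(a, b)
        assert nov.count == overlap_stats(a, b).count_nonoverlap
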
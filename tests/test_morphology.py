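"""Morphology: line-decomposition exactness, duality, top-hat semantics,
geodesic opening component bookkeeping, and the radius-independent runtime
contract of the 1-D min/max filters."""

import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otomorph import (
    BinaryMask,
    IntensityVolume,
    StructuringElement,
    apply_mask,
    binarize,
    closing,
    connected_components,
    dilate,
    erode,
    geodesic_opening,
    opening,
    white_tophat,
)
from otomorph.exceptions import DimensionalityError, ParameterError

from oracles import dilate_enum, erode_enum, random_blob_mask


class TestStructuringElement:
    def test_cross_offsets(self):
        se = StructuringElement("cross", 1)
        offs = {tuple(o) for o in se.offsets()}
        assert offs == {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                        (0, -1, 0), (0, 0, 1), (0, 0, -1)}
        assert len(StructuringElement("cross", 3).offsets()) == 19

    def test_radius_zero_is_origin(self):
        for shape in ("cross", "box", "ball"):
            offs = StructuringElement(shape, 0).offsets()
            assert offs.shape == (1, 3) and tuple(offs[0]) == (0, 0, 0)

    def test_box_is_full_cube(self):
        assert StructuringElement("box", 2).footprint().sum() == 125

    def test_validation(self):
        with pytest.raises(ParameterError):
            StructuringElement("diamond", 1)
        with pytest.raises(ParameterError):
            StructuringElement("box", -1)


class TestErodeDilate:
    def test_constant_grayscale_unchanged(self, constant_volume):
        vol = constant_volume(0.5, (8, 8, 8))
        for se in [StructuringElement("cross", 2), StructuringElement("box", 1)]:
            np.testing.assert_array_equal(erode(vol, se).data, vol.data)
            np.testing.assert_array_equal(dilate(vol, se).data, vol.data)

    @pytest.mark.parametrize("shape,radius", [
        ("cross", 1), ("cross", 2), ("cross", 3), ("cross", 64),
        ("box", 1), ("box", 2),
    ])
    def test_grayscale_bitidentical_to_enumeration(self, random_volume, shape, radius):
        vol = random_volume((16, 16, 16), seed=radius)
        se = StructuringElement(shape, radius)
        with pytest.warns(UserWarning) if radius >= 16 else _noop():
            got_e = erode(vol, se).data
            got_d = dilate(vol, se).data
        np.testing.assert_array_equal(got_e, erode_enum(vol.data, se.offsets(), binary=False))
        np.testing.assert_array_equal(got_d, dilate_enum(vol.data, se.offsets(), binary=False))

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_binary_bitidentical_to_enumeration(self, random_mask, radius):
        mask = random_mask((16, 16, 16), seed=radius + 100)
        se = StructuringElement("cross", radius)
        np.testing.assert_array_equal(
            erode(mask, se).data, erode_enum(mask.data, se.offsets(), binary=True))
        np.testing.assert_array_equal(
            dilate(mask, se).data, dilate_enum(mask.data, se.offsets(), binary=True))

    def test_single_voxel_cross_dilation_has_7_voxels(self):
        mask = BinaryMask(np.zeros((9, 9, 9), dtype=bool))
        mask.data[4, 4, 4] = True
        out = dilate(mask, StructuringElement("cross", 1))
        assert out.voxel_count() == 7
        assert out.data[4, 4, 4] and out.data[3, 4, 4] and out.data[4, 4, 5]
        assert not out.data[3, 3, 4]  # no edge neighbours

    def test_single_voxel_cross_erosion_empty(self):
        mask = BinaryMask(np.zeros((9, 9, 9), dtype=bool))
        mask.data[4, 4, 4] = True
        assert erode(mask, StructuringElement("cross", 1)).voxel_count() == 0

    def test_binary_duality(self, random_mask):
        # erode(v) == 1 - dilate(1 - v) with complementary border values
        mask = random_mask((12, 12, 12), seed=77)
        se = StructuringElement("cross", 2)
        comp = BinaryMask(~mask.data)
        lhs = erode(mask, se, border_value=0).data
        rhs = ~dilate(comp, se, border_value=1).data
        np.testing.assert_array_equal(lhs, rhs)

    def test_half_space_closing_identity_away_from_borders(self):
        mask = BinaryMask(np.zeros((12, 12, 12), dtype=bool))
        mask.data[:, :, :6] = True
        se = StructuringElement("box", 2)
        closed = erode(dilate(mask, se), se)
        core = (slice(2, -2),) * 3
        np.testing.assert_array_equal(closed.data[core], mask.data[core])

    def test_ball_erosion_matches_enumeration(self, random_volume):
        vol = random_volume((10, 10, 10), seed=31)
        se = StructuringElement("ball", 2)
        np.testing.assert_array_equal(
            erode(vol, se).data, erode_enum(vol.data, se.offsets(), binary=False))

    def test_runtime_independent_of_radius(self):
        # van Herk / Gil-Werman contract: line filters cost the same for
        # r = 64 as for r = 8
        rng = np.random.default_rng(0)
        vol = IntensityVolume(rng.uniform(0, 1, (128, 128, 128)))

        def best_of(se, n=3):
            times = []
            for _ in range(n):
                t0 = time.perf_counter()
                erode(vol, se)
                times.append(time.perf_counter() - t0)
            return min(times)

        t8 = best_of(StructuringElement("cross", 8))
        t64 = best_of(StructuringElement("cross", 64))
        assert t64 <= 2.0 * t8


class _noop:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestOpeningClosing:
    def test_opening_of_fitting_box_unchanged(self):
        mask = BinaryMask(np.zeros((12, 12, 12), dtype=bool))
        mask.data[3:8, 3:8, 3:8] = True  # (2r+1)^3 with r = 2
        out = opening(mask, StructuringElement("box", 2))
        np.testing.assert_array_equal(out.data, mask.data)

    def test_opening_antiextensive_closing_extensive(self, random_mask):
        mask = random_mask((14, 14, 14), seed=3)
        se = StructuringElement("box", 1)
        o = opening(mask, se).data
        c = closing(mask, se).data
        assert np.all(o <= mask.data)
        assert np.all(mask.data <= c)

    def test_closing_idempotent_binary(self):
        se = StructuringElement("box", 2)
        for seed in range(6):
            mask = BinaryMask(random_blob_mask((20, 20, 20), seed, density=0.4))
            once = closing(mask, se)
            twice = closing(once, se)
            np.testing.assert_array_equal(once.data, twice.data)

    def test_opening_idempotent_grayscale(self, random_volume):
        vol = random_volume((12, 12, 12), seed=41)
        se = StructuringElement("box", 1)
        once = opening(vol, se)
        np.testing.assert_array_equal(opening(once, se).data, once.data)

    def test_single_voxel_opened_away_by_large_cross(self):
        data = np.full((20, 20, 20), 0.1)
        data[10, 10, 10] = 0.8
        with pytest.warns(UserWarning):
            out = opening(IntensityVolume(data), StructuringElement("cross", 64))
        assert out.data[10, 10, 10] == pytest.approx(0.1)


class TestWhiteTophat:
    def test_constant_is_zero(self, constant_volume):
        out = white_tophat(constant_volume(0.7, (10, 10, 10)),
                           StructuringElement("cross", 2))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_bright_spike_contrast(self):
        data = np.full((15, 15, 15), 0.1)
        data[7, 7, 7] = 0.8
        out = white_tophat(IntensityVolume(data), StructuringElement("cross", 2))
        assert out.data[7, 7, 7] == pytest.approx(0.7)

    def test_nonnegative_and_zero_on_opened(self, random_volume):
        vol = random_volume((12, 12, 12), seed=19)
        se = StructuringElement("cross", 2)
        th = white_tophat(vol, se)
        assert np.all(th.data >= 0.0)
        opened = opening(vol, se)
        np.testing.assert_array_equal(white_tophat(opened, se).data, 0.0)

    def test_broad_slab_suppressed(self):
        # a bright slab thicker than the SE along every axis is reproduced
        # by its opening, so the top-hat vanishes in the slab interior
        data = np.full((24, 24, 24), 0.1)
        data[4:20, 4:20, 4:20] = 0.8
        out = white_tophat(IntensityVolume(data), StructuringElement("cross", 3))
        assert np.all(out.data[8:16, 8:16, 8:16] == 0.0)


class TestBinarize:
    def test_threshold_tie_is_foreground(self):
        vol = IntensityVolume(np.array([0.034, 0.035, 0.036]).reshape(1, 1, 3))
        mask = binarize(vol, 0.035)
        np.testing.assert_array_equal(mask.data[0, 0], [False, True, True])

    def test_all_zero_gives_empty_mask(self):
        assert binarize(IntensityVolume(np.zeros((4, 4, 4))), 0.035).voxel_count() == 0

    def test_monotone_in_threshold(self, random_volume):
        vol = random_volume((12, 12, 12), seed=8)
        counts = [binarize(vol, t).voxel_count() for t in np.linspace(0.05, 0.95, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_validation(self, constant_volume):
        vol = constant_volume()
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                binarize(vol, bad)


class TestGeodesicOpening:
    def test_large_cube_kept_small_cube_removed(self):
        mask = BinaryMask(np.zeros((64, 64, 64), dtype=bool))
        mask.data[5:40, 5:40, 5:40] = True   # 35^3: contains a 31^3 box
        mask.data[50:55, 50:55, 50:55] = True  # 5^3: too small
        out = geodesic_opening(mask, 15)
        expected = np.zeros_like(mask.data)
        expected[5:40, 5:40, 5:40] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_mask(self):
        mask = BinaryMask(np.zeros((8, 8, 8), dtype=bool))
        assert geodesic_opening(mask, 2).voxel_count() == 0

    def test_matches_reconstruction_oracle(self):
        # independent oracle: erosion marker + grayscale reconstruction by
        # dilation (skimage), binarised
        from skimage.morphology import reconstruction

        for seed in range(5):
            mask = BinaryMask(random_blob_mask((28, 28, 28), seed + 40, density=0.45))
            size = 3
            marker = erode(mask, StructuringElement("box", size)).data
            expected = reconstruction(
                marker.astype(np.uint8), mask.data.astype(np.uint8),
                method="dilation",
                footprint=np.ones((3, 3, 3)),
            ).astype(bool)
            out = geodesic_opening(mask, size, connectivity=26)
            np.testing.assert_array_equal(out.data, expected)

    def test_output_is_union_of_input_components(self, random_mask):
        mask = BinaryMask(random_blob_mask((24, 24, 24), 7, density=0.4))
        out = geodesic_opening(mask, 2)
        labels, _ = connected_components(mask)
        kept = np.unique(labels[out.data])
        kept = kept[kept > 0]
        np.testing.assert_array_equal(out.data, np.isin(labels, kept))
        assert np.all(out.data <= mask.data)

    def test_idempotent(self):
        for seed in range(5):
            mask = BinaryMask(random_blob_mask((24, 24, 24), seed, density=0.4))
            once = geodesic_opening(mask, 2)
            np.testing.assert_array_equal(geodesic_opening(once, 2).data, once.data)


class TestConnectedComponents:
    def test_diagonal_voxels_connectivity(self):
        mask = BinaryMask(np.zeros((4, 4, 4), dtype=bool))
        mask.data[1, 1, 1] = True
        mask.data[2, 2, 2] = True
        _, sizes26 = connected_components(mask, 26)
        _, sizes6 = connected_components(mask, 6)
        assert len(sizes26) == 1
        assert len(sizes6) == 2

    def test_empty_mask(self):
        _, sizes = connected_components(BinaryMask(np.zeros((4, 4, 4), dtype=bool)))
        assert len(sizes) == 0

    def test_sizes_conserve_foreground(self, random_mask):
        mask = random_mask((16, 16, 16), seed=13)
        _, sizes = connected_components(mask)
        assert sizes.sum() == mask.voxel_count()


class TestApplyMask:
    def test_ones_mask_identity(self, random_volume):
        vol = random_volume((6, 6, 6))
        mask = BinaryMask(np.ones((6, 6, 6), dtype=bool))
        np.testing.assert_array_equal(apply_mask(vol, mask).data, vol.data)

    def test_zero_mask_zeroes(self, random_volume):
        vol = random_volume((6, 6, 6))
        mask = BinaryMask(np.zeros((6, 6, 6), dtype=bool))
        np.testing.assert_array_equal(apply_mask(vol, mask).data, 0.0)

    def test_elementwise_product(self, random_volume, random_mask):
        vol = random_volume((8, 8, 8), seed=1)
        mask = random_mask((8, 8, 8), seed=2)
        np.testing.assert_array_equal(
            apply_mask(vol, mask).data, vol.data * mask.data.astype(float))

    def test_shape_mismatch(self, random_volume):
        vol = random_volume((6, 6, 6))
        mask = BinaryMask(np.ones((5, 6, 6), dtype=bool))
        with pytest.raises(DimensionalityError):
            apply_mask(vol, mask)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), radius=st.integers(1, 3),
       shape=st.sampled_from(["cross", "box"]))
def test_erosion_dilation_enumeration_property(seed, radius, shape):
    """Line-decomposed min/max equals direct offset enumeration on random
    grayscale volumes, bit-identically."""
    rng = np.random.default_rng(seed)
    vol = IntensityVolume(rng.uniform(0, 1, (10, 10, 10)))
    se = StructuringElement(shape, radius)
    np.testing.assert_array_equal(
        erode(vol, se).data, erode_enum(vol.data, se.offsets(), binary=False))
    np.testing.assert_array_equal(
        dilate(vol, se).data, dilate_enum(vol.data, se.offsets(), binary=False))
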
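"""NSCT transform properties: shapes, invertibility, shift invariance,
linearity, boundary modes."""

import numpy as np
import pytest

from nsctfuse import (SubbandPyramid, nsct_decompose, nsct_reconstruct,
                      nsdfb_merge, nsdfb_split, nspfb_merge, nspfb_split)


def all_bands(p):
    return [p.low] + [b for level in p.highs for b in level]


class TestPyramidStage:
    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_constant_image_splits_into_constant_and_zero(self, pyr_bank,
                                                          level):
        c = np.full((32, 32), 0.7)
        low, high = nspfb_split(c, pyr_bank, level=level)
        assert np.max(np.abs(low - 0.7)) < 1e-10
        assert np.max(np.abs(high)) < 1e-10

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_split_merge_round_trip(self, pyr_bank, random_image, level):
        low, high = nspfb_split(random_image, pyr_bank, level=level)
        rec = nspfb_merge(low, high, pyr_bank, level=level)
        assert np.max(np.abs(rec - random_image)) < 1e-8

    def test_periodic_split_commutes_with_circular_shift(self, pyr_bank,
                                                         random_image):
        shift = (5, 11)
        low0, high0 = nspfb_split(random_image, pyr_bank, level=1)
        low1, high1 = nspfb_split(np.roll(random_image, shift, (0, 1)),
                                  pyr_bank, level=1)
        assert np.max(np.abs(np.roll(low0, shift, (0, 1)) - low1)) < 1e-10
        assert np.max(np.abs(np.roll(high0, shift, (0, 1)) - high1)) < 1e-10


class TestDirectionalStage:
    def test_zero_levels_is_identity(self, fan_bank, random_image):
        out = nsdfb_split(random_image, fan_bank, 0)
        assert len(out) == 1
        assert np.array_equal(out[0], random_image)

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_band_count_shape_and_round_trip(self, fan_bank, random_image,
                                             depth):
        bands = nsdfb_split(random_image, fan_bank, depth)
        assert len(bands) == 2 ** depth
        assert all(b.shape == random_image.shape for b in bands)
        rec = nsdfb_merge(bands, fan_bank, depth)
        assert np.max(np.abs(rec - random_image)) < 1e-6

    def test_negative_depth_rejected(self, fan_bank, random_image):
        with pytest.raises(ValueError):
            nsdfb_split(random_image, fan_bank, -1)

    def test_bands_are_directional_not_duplicates(self, fan_bank, rng):
        # the two fan channels must respond differently to an oriented
        # pattern (a horizontal-frequency grating)
        x = np.tile(np.cos(np.arange(64) * 2.5), (64, 1))
        b0, b1 = nsdfb_split(x, fan_bank, 1)
        e0, e1 = np.sum(b0 ** 2), np.sum(b1 ** 2)
        assert max(e0, e1) > 5 * min(e0, e1)


class TestFullTransform:
    def test_band_count_and_nonsubsampled_shapes(self, pyr_bank, fan_bank,
                                                 rng):
        x = rng.random((64, 64))
        p = nsct_decompose(x, 4, (3, 3, 2, 2), pyr_bank, fan_bank)
        assert p.band_count() == 1 + 8 + 8 + 4 + 4
        assert all(b.shape == (64, 64) for b in all_bands(p))

    def test_constant_image_energy_stays_in_lowpass(self, pyr_bank,
                                                    fan_bank):
        c = np.full((32, 32), 0.4)
        p = nsct_decompose(c, 3, (2, 1, 1), pyr_bank, fan_bank)
        assert np.max(np.abs(p.low - 0.4)) < 1e-9
        for level in p.highs:
            for b in level:
                assert np.max(np.abs(b)) < 1e-9

    @pytest.mark.parametrize("levels,dirs", [(1, (2,)), (2, (2, 1)),
                                             (3, (3, 2, 2))])
    def test_round_trip_is_exact(self, pyr_bank, fan_bank, rng, levels,
                                 dirs):
        x = rng.random((64, 64))
        p = nsct_decompose(x, levels, dirs, pyr_bank, fan_bank)
        r = nsct_reconstruct(p, pyr_bank, fan_bank)
        assert np.max(np.abs(r - x)) < 1e-6

    def test_lowpass_only_reconstruction_of_constant(self, pyr_bank,
                                                     fan_bank):
        c = np.full((32, 32), 0.6)
        p = nsct_decompose(c, 2, (1, 1), pyr_bank, fan_bank)
        zeroed = SubbandPyramid(
            low=p.low,
            highs=[[np.zeros_like(b) for b in lvl] for lvl in p.highs],
            levels=p.levels, dirs_per_level=p.dirs_per_level)
        r = nsct_reconstruct(zeroed, pyr_bank, fan_bank)
        assert np.max(np.abs(r - 0.6)) < 1e-9

    def test_decompose_and_reconstruct_are_linear(self, pyr_bank, fan_bank,
                                                  rng):
        x, y = rng.random((2, 32, 32))
        a, b = 1.7, -0.6
        px = nsct_decompose(x, 2, (2, 1), pyr_bank, fan_bank)
        py = nsct_decompose(y, 2, (2, 1), pyr_bank, fan_bank)
        pz = nsct_decompose(a * x + b * y, 2, (2, 1), pyr_bank, fan_bank)
        for bx, by, bz in zip(all_bands(px), all_bands(py), all_bands(pz)):
            assert np.max(np.abs(a * bx + b * by - bz)) < 1e-8
        combo = SubbandPyramid(
            low=a * px.low + b * py.low,
            highs=[[a * u + b * v for u, v in zip(lu, lv)]
                   for lu, lv in zip(px.highs, py.highs)],
            levels=2, dirs_per_level=(2, 1))
        rc = nsct_reconstruct(combo, pyr_bank, fan_bank)
        rx = nsct_reconstruct(px, pyr_bank, fan_bank)
        ry = nsct_reconstruct(py, pyr_bank, fan_bank)
        assert np.max(np.abs(rc - (a * rx + b * ry))) < 1e-8

    def test_subbands_shift_with_the_image(self, pyr_bank, fan_bank, rng):
        x = rng.random((32, 32))
        shift = (7, 3)
        p0 = nsct_decompose(x, 2, (2, 1), pyr_bank, fan_bank)
        p1 = nsct_decompose(np.roll(x, shift, (0, 1)), 2, (2, 1),
                            pyr_bank, fan_bank)
        for b0, b1 in zip(all_bands(p0), all_bands(p1)):
            assert np.max(np.abs(np.roll(b0, shift, (0, 1)) - b1)) < 1e-8


class TestValidation:
    def test_dirs_length_must_match_levels(self, pyr_bank, fan_bank,
                                           random_image):
        with pytest.raises(ValueError, match="one entry per level"):
            nsct_decompose(random_image, 3, (2, 1), pyr_bank, fan_bank)

    def test_nonfinite_image_rejected(self, pyr_bank, fan_bank):
        x = np.ones((8, 8))
        x[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nsct_decompose(x, 1, (1,), pyr_bank, fan_bank)

    def test_inconsistent_pyramid_rejected(self, pyr_bank, fan_bank, rng):
        x = rng.random((16, 16))
        p = nsct_decompose(x, 2, (1, 1), pyr_bank, fan_bank)
        p.highs[0] = p.highs[0][:1]  # drop a directional band
        with pytest.raises(ValueError, match="directional bands"):
            nsct_reconstruct(p, pyr_bank, fan_bank)

    def test_unknown_boundary_mode_rejected(self, pyr_bank, random_image):
        with pytest.raises(ValueError, match="boundary"):
            nspfb_split(random_image, pyr_bank, boundary="toroidal")


class TestSymmetricBoundary:
    """Mirror extension trades exact global invertibility for artifact-free
    borders; reconstruction stays exact away from the margins."""

    def test_interior_reconstruction_is_exact(self, pyr_bank, fan_bank,
                                              rng):
        x = rng.random((64, 64))
        p = nsct_decompose(x, 3, (2, 2, 1), pyr_bank, fan_bank,
                           boundary="symmetric")
        r = nsct_reconstruct(p, pyr_bank, fan_bank, boundary="symmetric")
        err = np.abs(r - x)
        assert err[16:-16, 16:-16].max() < 1e-6

    def test_pyramid_only_tree_is_globally_exact(self, pyr_bank, fan_bank,
                                                 rng):
        # with axis-symmetric kernels (depth-1 fans) mirror extension
        # commutes with the tree and the inverse is exact everywhere
        x = rng.random((48, 48))
        p = nsct_decompose(x, 2, (1, 1), pyr_bank, fan_bank,
                           boundary="symmetric")
        r = nsct_reconstruct(p, pyr_bank, fan_bank, boundary="symmetric")
        assert np.max(np.abs(r - x)) < 1e-10
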
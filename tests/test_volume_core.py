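import numpy as np
import nibabel as nib
import pytest

from pdacdetect.volume_core import (CropRegion, Volume, extract_crop, load_volume,
                                    map_index_between_spacings, normalize_hu,
                                    paste_crop, resample, save_volume)


def _brute_force_crop(data, start, size, fill):
    """Per-voxel gather oracle for extract_crop/paste_crop."""
    out = np.full(size, fill, dtype=float)
    for idx in np.ndindex(*size):
        src = tuple(start[a] + idx[a] for a in range(3))
        if all(0 <= src[a] < data.shape[a] for a in range(3)):
            out[idx] = data[src]
    return out


class TestNiftiIO:
    def test_round_trip_preserves_grid_and_spacing(self, tmp_path):
        data = np.full((4, 4, 4), 42.0)
        v = Volume(data, spacing=(0.68, 0.68, 1.0))
        path = tmp_path / "x.nii.gz"
        save_volume(v, path)
        v2 = load_volume(path)
        np.testing.assert_array_equal(v2.data, data)
        assert np.allclose(v2.spacing, (0.68, 0.68, 1.0), atol=1e-6)

    def test_non_3d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4)), np.eye(4))
        path = tmp_path / "flat.nii.gz"
        nib.save(img, str(path))
        with pytest.raises(ValueError, match="3D"):
            load_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii.gz")


class TestResample:
    def test_factor_two_shape(self):
        v = Volume(np.zeros((64, 64, 64)), spacing=(1, 1, 1))
        out = resample(v, (0.5, 0.5, 0.5))
        assert out.shape == (128, 128, 128)

    def test_constant_stays_constant(self):
        v = Volume(np.full((10, 12, 8), 7.0), spacing=(1, 1, 1))
        out = resample(v, (0.73, 1.9, 0.4))
        np.testing.assert_allclose(out.data, 7.0)

    def test_nearest_preserves_label_set(self):
        rng = np.random.default_rng(3)
        v = Volume((rng.random((16, 16, 16)) < 0.4).astype(np.uint8), spacing=(1, 1, 1))
        out = resample(v, (2, 2, 2), mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_linear_ramp_matches_analytic(self):
        # f(i) = i along axis 0; downsample x2 samples positions 2j exactly
        n = 32
        ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n)).copy()
        v = Volume(ramp, spacing=(1, 1, 1))
        out = resample(v, (2, 2, 2))
        interior = out.data[: n // 2 - 1]
        expect = np.broadcast_to(
            2.0 * np.arange(n // 2 - 1, dtype=float)[:, None, None], interior.shape
        )
        np.testing.assert_allclose(interior, expect, atol=1e-6)

    def test_nonpositive_spacing_rejected(self):
        v = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample(v, (1, 0, 1))


class TestNormalizeHU:
    @pytest.mark.parametrize("hu,expected", [(-87, 0.0), (199, 1.0), (56, 0.5),
                                             (-500, 0.0), (3000, 1.0)])
    def test_window_mapping(self, hu, expected):
        v = Volume(np.full((2, 2, 2), float(hu)))
        assert normalize_hu(v).data.flat[0] == pytest.approx(expected, abs=1e-12)

    def test_idempotent_with_unit_window(self, rng):
        v = normalize_hu(Volume(rng.normal(50, 100, (6, 6, 6))))
        again = normalize_hu(v, window=(0.0, 1.0))
        np.testing.assert_allclose(again.data, v.data)

    def test_output_in_unit_interval_and_monotone(self, rng):
        x = np.sort(rng.normal(50, 300, 100))
        v = Volume(x.reshape(4, 5, 5))
        out = normalize_hu(v).data.ravel()
        assert out.min() >= 0 and out.max() <= 1
        assert (np.diff(out) >= -1e-15).all()

    def test_bad_window(self):
        with pytest.raises(ValueError):
            normalize_hu(Volume(np.zeros((2, 2, 2))), window=(5, 5))


class TestCropPaste:
    def test_interior_crop_start(self, rng):
        v = Volume(rng.random((100, 100, 100)))
        crop, region = extract_crop(v, (50, 50, 50), (64, 64, 64))
        assert region.start == (18, 18, 18)
        np.testing.assert_array_equal(crop.data, v.data[18:82, 18:82, 18:82])

    def test_padded_crop_matches_brute_force(self, rng):
        v = Volume(rng.random((100, 60, 60)))
        crop, region = extract_crop(v, (5, 30, 30), (64, 64, 64), fill=-1.0)
        assert region.start == (-27, -2, -2)
        np.testing.assert_array_equal(crop.data[:27], -1.0)
        oracle = _brute_force_crop(v.data, region.start, region.size, -1.0)
        np.testing.assert_array_equal(crop.data, oracle)

    def test_center_outside_rejected(self):
        v = Volume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError):
            extract_crop(v, (10, 5, 5), (4, 4, 4))

    def test_round_trip_identity_on_in_bounds_region(self, rng):
        for _ in range(25):
            shape = tuple(int(rng.integers(6, 14)) for _ in range(3))
            size = tuple(int(rng.integers(2, 10)) for _ in range(3))
            v = Volume(rng.random(shape))
            center = tuple(int(rng.integers(s)) for s in shape)
            crop, region = extract_crop(v, center, size, fill=0.0)
            pasted = paste_crop(shape, crop, region, background=np.nan)
            inb = ~np.isnan(pasted)
            np.testing.assert_array_equal(pasted[inb], v.data[inb])

    def test_full_coverage_paste_equals_crop(self, rng):
        v = Volume(rng.random((8, 8, 8)))
        crop, region = extract_crop(v, (4, 4, 4), (8, 8, 8))
        np.testing.assert_array_equal(paste_crop((8, 8, 8), crop, region), v.data)

    def test_paste_conservation(self, rng):
        v = Volume(rng.random((20, 20, 20)))
        crop, region = extract_crop(v, (10, 10, 10), (6, 6, 6))
        out = paste_crop((20, 20, 20), crop, region, background=0.0)
        assert out.sum() == pytest.approx(crop.data.sum())

    def test_paste_shape_mismatch(self, rng):
        v = Volume(rng.random((8, 8, 8)))
        crop, region = extract_crop(v, (4, 4, 4), (4, 4, 4))
        with pytest.raises(ValueError):
            paste_crop((9, 8, 8), crop, region)


class TestIndexMapping:
    def test_identity(self):
        assert map_index_between_spacings((3, 4, 5), (1, 1, 1), (1, 1, 1)) == (3, 4, 5)

    def test_factor_two(self):
        got = map_index_between_spacings((10, 10, 10), (1.37, 1.37, 2.0), (0.685, 0.685, 1.0))
        assert got == (20, 20, 20)

    def test_round_trip_within_one_coarse_voxel(self, rng):
        # each hop rounds to half a voxel, so the round trip stays within
        # one voxel of the coarser of the two grids
        for _ in range(50):
            sp1 = tuple(rng.uniform(0.5, 3.0, 3))
            sp2 = tuple(rng.uniform(0.5, 3.0, 3))
            idx = tuple(int(rng.integers(0, 40)) for _ in range(3))
            there = map_index_between_spacings(idx, sp1, sp2)
            back = map_index_between_spacings(there, sp2, sp1)
            for a in range(3):
                assert abs(back[a] - idx[a]) * sp1[a] <= max(sp1[a], sp2[a]) + 1e-9


def test_crop_region_must_intersect_source():
    with pytest.raises(ValueError):
        CropRegion(start=(-5, 0, 0), size=(4, 4, 4), source_shape=(10, 10, 10))
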
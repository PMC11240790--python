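from types import SimpleNamespace

import numpy as np
import pytest
from scipy import ndimage as ndi

from pdacdetect.patch_engine import (TilingSpec, binarize, largest_component,
                                     sliding_window_predict, tile_positions)


class ConstModel:
    """Predicts a constant probability everywhere."""

    def __init__(self, c: float, out_channels: int = 1):
        self.c = c
        self.config = SimpleNamespace(in_channels=1, out_channels=out_channels)

    def predict_proba(self, x):
        return np.full((self.config.out_channels,) + x.shape[1:], self.c)


class SmoothModel:
    """Deterministic input-dependent predictor (no learned state)."""

    config = SimpleNamespace(in_channels=1, out_channels=1)

    def predict_proba(self, x):
        return 1.0 / (1.0 + np.exp(-ndi.gaussian_filter(x[0], 1.0)))[None]


def flood_fill_components(mask, connectivity=26):
    """Independent BFS flood-fill oracle for 3D connected components."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = sum(abs(d) for d in (dx, dy, dz))
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for seed in sorted(map(tuple, np.argwhere(mask))):
        if seen[seed]:
            continue
        comp, stack = [], [seed]
        seen[seed] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


class TestTilePositions:
    def test_exact_division(self):
        spec = TilingSpec((128, 128, 128), (32, 32, 32))
        starts = sorted({p[0] for p in tile_positions((192, 192, 192), spec)})
        assert starts == [0, 32, 64]

    def test_final_start_clamped_and_covering(self):
        spec = TilingSpec((128, 128, 128), (32, 32, 32))
        starts = sorted({p[0] for p in tile_positions((190, 190, 190), spec)})
        assert starts == [0, 32, 62]
        covered = np.zeros(190, dtype=bool)
        for s in starts:
            covered[s:s + 128] = True
        assert covered.all()

    def test_volume_equals_patch(self):
        spec = TilingSpec((16, 16, 16), (8, 8, 8))
        assert tile_positions((16, 16, 16), spec) == [(0, 0, 0)]

    def test_too_small_volume_names_axis(self):
        spec = TilingSpec((16, 16, 16), (8, 8, 8))
        with pytest.raises(ValueError, match="axis 2"):
            tile_positions((16, 16, 8), spec)

    def test_coverage_over_random_geometries(self, rng):
        for _ in range(200):
            patch = tuple(int(rng.integers(2, 9)) for _ in range(3))
            stride = tuple(int(rng.integers(1, patch[a] + 1)) for a in range(3))
            shape = tuple(int(rng.integers(patch[a], 25)) for a in range(3))
            covered = np.zeros(shape, dtype=bool)
            for p in tile_positions(shape, TilingSpec(patch, stride)):
                covered[p[0]:p[0] + patch[0], p[1]:p[1] + patch[1], p[2]:p[2] + patch[2]] = True
            assert covered.all()

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            TilingSpec((16, 16, 16), (0, 8, 8))


class TestSlidingWindow:
    def test_constant_predictor_unaffected_by_tiling(self, rng):
        spec = TilingSpec((8, 8, 8), (3, 3, 3))
        out = sliding_window_predict(ConstModel(0.37), rng.random((1, 19, 17, 13)), spec)
        np.testing.assert_allclose(out, 0.37)

    def test_matches_per_voxel_oracle(self, rng):
        """Brute-force per-voxel mean over covering patches."""
        vol = rng.normal(size=(1, 24, 20, 16))
        spec = TilingSpec((16, 16, 16), (8, 8, 8))
        model = SmoothModel()
        got = sliding_window_predict(model, vol, spec)
        positions = tile_positions(vol.shape[1:], spec)
        preds = {p: model.predict_proba(
            vol[:, p[0]:p[0] + 16, p[1]:p[1] + 16, p[2]:p[2] + 16]) for p in positions}
        for v in [(0, 0, 0), (23, 19, 15), (12, 10, 8), (8, 0, 15), (7, 19, 3)]:
            vals = [preds[p][0, v[0] - p[0], v[1] - p[1], v[2] - p[2]]
                    for p in positions
                    if all(p[a] <= v[a] < p[a] + 16 for a in range(3))]
            assert got[0][v] == pytest.approx(np.mean(vals), abs=1e-6)

    def test_single_patch_equals_direct_call(self, rng):
        vol = rng.normal(size=(1, 16, 16, 16))
        spec = TilingSpec((16, 16, 16), (8, 8, 8))
        model = SmoothModel()
        np.testing.assert_allclose(
            sliding_window_predict(model, vol, spec), model.predict_proba(vol))


class TestBinarize:
    def test_boundary_inclusive(self):
        out = binarize(np.array([[[0.4, 0.5, 0.6]]]), 0.5)
        np.testing.assert_array_equal(out, [[[False, True, True]]])

    def test_extremes(self):
        p = np.array([[[0.0, 0.3, 0.99]]])
        assert binarize(p, 0.0).all()
        assert not binarize(p, 1.0).any()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2, 2)), 1.5)


class TestLargestComponent:
    def test_keeps_biggest_blob(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:3, 1:3, 1:3] = True          # 8 voxels
        mask[8:10, 8:10, 8] = True          # 4 voxels
        out = largest_component(mask)
        assert out.sum() == 8 and out[1, 1, 1] and not out[8, 8, 8]

    def test_empty_in_empty_out(self):
        assert largest_component(np.zeros((5, 5, 5), dtype=bool)).sum() == 0

    def test_agrees_with_flood_fill_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((12, 12, 12)) < 0.25
            got = largest_component(mask, connectivity=26)
            comps = flood_fill_components(mask, connectivity=26)
            if not comps:
                assert got.sum() == 0
                continue
            # max size; ties broken by smallest lexicographic seed voxel
            best = max(comps, key=lambda c: (len(c), [-x for x in min(c)]))
            expect = np.zeros_like(mask)
            for v in best:
                expect[v] = True
            np.testing.assert_array_equal(got, expect)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_connectivity_variants(self, connectivity):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # diagonal neighbour: one component only at 26
        out = largest_component(mask, connectivity=connectivity)
        assert out.sum() == (2 if connectivity == 26 else 1)
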
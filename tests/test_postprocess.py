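"""Morphology, distance-transform and fusion against brute-force oracles."""

import numpy as np
import pytest
from skimage.morphology import disk

from octfluid.phantom import PhantomConfig, generate_cube
from octfluid.postprocess import fuse, smooth_mask, thickness_map


# -- brute-force oracles -------------------------------------------------------

def brute_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """OR over footprint shifts; outside the image counts as background."""
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask)
    h, w = mask.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not footprint[dy + r, dx + r]:
                continue
            shifted = np.zeros_like(mask)
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            ys_src = slice(max(0, -dy), min(h, h - dy))
            xs_src = slice(max(0, -dx), min(w, w - dx))
            shifted[ys, xs] = mask[ys_src, xs_src]
            out |= shifted
    return out


def brute_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """AND over footprint offsets; outside the image counts as background."""
    r = footprint.shape[0] // 2
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not footprint[dy + r, dx + r]:
                        continue
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                        ok = False
                        break
                if not ok:
                    break
            out[y, x] = ok
    return out


def brute_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs nearest-background Euclidean search on one slice."""
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    for y, x in np.argwhere(mask):
        d2 = ((bg - [y, x]) ** 2).sum(axis=1)
        out[y, x] = np.sqrt(d2.min())
    return out


# -- smooth_mask ---------------------------------------------------------------

def brute_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """dilate∘erode composed on the (padded) plane, cropped back."""
    r = footprint.shape[0] // 2
    pad = 2 * r + 2
    mp = np.pad(mask, pad)
    out = brute_erode(brute_dilate(mp, footprint), footprint)
    return out[pad:-pad, pad:-pad]


def brute_open(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    pad = 2 * r + 2
    mp = np.pad(mask, pad)
    out = brute_dilate(brute_erode(mp, footprint), footprint)
    return out[pad:-pad, pad:-pad]


class TestSmoothMask:
    def test_matches_brute_force(self, rng):
        fp = disk(2)
        for _ in range(60):
            m = rng.random((1, 12, 12)) < rng.uniform(0.2, 0.6)
            close = smooth_mask(m, "closing", 2)[0]
            opn = smooth_mask(m, "opening", 2)[0]
            assert np.array_equal(close, brute_close(m[0], fp))
            assert np.array_equal(opn, brute_open(m[0], fp))

    def test_closing_idempotent_opening_antiextensive(self, rng):
        for _ in range(30):
            m = rng.random((1, 12, 12)) < 0.4
            close = smooth_mask(m, "closing", 2)
            opn = smooth_mask(m, "opening", 2)
            assert np.array_equal(close, smooth_mask(close, "closing", 2))
            assert np.array_equal(opn, smooth_mask(opn, "opening", 2))
            assert np.all(opn <= m) and np.all(m <= close)

    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((1, 9, 9), dtype=bool)
        m[0, 4, 4] = True
        assert not smooth_mask(m, "opening", 2).any()

    def test_closing_fills_one_pixel_hole(self):
        m = np.zeros((1, 9, 9), dtype=bool)
        m[0, 1:8, 1:8] = True
        m[0, 4, 4] = False
        closed = smooth_mask(m, "closing", 2)
        assert closed[0, 4, 4]

    def test_unknown_op_raises(self):
        with pytest.raises(ValueError):
            smooth_mask(np.zeros((1, 4, 4), bool), "median", 2)

    def test_slices_processed_independently(self, rng):
        m = rng.random((4, 12, 12)) < 0.4
        full = smooth_mask(m, "closing", 2)
        per_slice = np.stack([smooth_mask(m[i:i + 1], "closing", 2)[0]
                              for i in range(4)])
        assert np.array_equal(full, per_slice)


# -- thickness_map -------------------------------------------------------------

class TestThicknessMap:
    def test_empty_mask_all_zero(self):
        assert not thickness_map(np.zeros((3, 8, 8), bool)).any()

    def test_single_pixel_distance_one(self):
        m = np.zeros((1, 16, 16), dtype=bool)
        m[0, 8, 8] = True
        t = thickness_map(m)
        assert t[0, 8, 8] == pytest.approx(1.0)

    def test_filled_square_centre(self):
        m = np.zeros((1, 16, 16), dtype=bool)
        m[0, 5:10, 5:10] = True  # 5x5 square away from borders
        t = thickness_map(m)
        assert t[0, 7, 7] == pytest.approx(3.0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            m = rng.random((1, 16, 16)) < rng.uniform(0.1, 0.9)
            if m.all():
                continue
            t = thickness_map(m)
            assert np.allclose(t[0], brute_distance(m[0]))

    def test_zero_exactly_off_mask_positive_on_mask(self, rng):
        m = rng.random((2, 16, 16)) < 0.3
        t = thickness_map(m)
        assert np.all((t > 0) == m)


# -- fuse ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def phantom_fused():
    cfg = PhantomConfig(n_slices=12, height=64, width=64,
                        blob_radius_range=(3, 5), seed=3)
    volume, mask = generate_cube(cfg)
    thickness = thickness_map(mask)
    return volume, mask, thickness, fuse(volume, mask, thickness)


class TestFuse:
    def test_split_histogram(self, phantom_fused):
        volume, mask, _, fused = phantom_fused
        assert fused.dtype == np.uint16
        assert np.all(fused[~mask] <= 255)
        assert np.all(fused[mask] >= 256)
        assert np.all(fused <= 510)
        assert int((fused > 255).sum()) == int(mask.sum())

    def test_background_passthrough(self, phantom_fused):
        volume, mask, _, fused = phantom_fused
        assert np.array_equal(fused[~mask], volume[~mask].astype(np.uint16))

    def test_max_thickness_maps_to_510(self, phantom_fused):
        _, mask, thickness, fused = phantom_fused
        dmax_voxels = thickness == thickness[mask].max()
        assert np.all(fused[dmax_voxels & mask] == 510)

    def test_midpoint_mapping(self):
        cube = np.zeros((1, 8, 8), dtype=np.uint8)
        mask = np.zeros((1, 8, 8), dtype=bool)
        mask[0, 2, 2] = mask[0, 2, 3] = True
        thickness = np.zeros((1, 8, 8))
        thickness[0, 2, 2] = 4.0      # d_max
        thickness[0, 2, 3] = 2.0      # d_max / 2
        fused = fuse(cube, mask, thickness)
        assert fused[0, 2, 2] == 510
        assert fused[0, 2, 3] == 256 + 127

    def test_empty_mask_returns_cube(self):
        cube = np.arange(64, dtype=np.uint8).reshape(1, 8, 8)
        fused = fuse(cube, np.zeros_like(cube, bool), np.zeros(cube.shape))
        assert np.array_equal(fused, cube)

    def test_clamp_mode_is_absolute(self):
        cube = np.zeros((1, 8, 8), dtype=np.uint8)
        mask = np.zeros((1, 8, 8), dtype=bool)
        mask[0, 1, 1] = True
        thickness = np.zeros((1, 8, 8)); thickness[0, 1, 1] = 3.0
        assert fuse(cube, mask, thickness, mode="clamp")[0, 1, 1] == 259

    def test_inconsistent_thickness_raises(self):
        cube = np.zeros((1, 4, 4), dtype=np.uint8)
        mask = np.zeros((1, 4, 4), dtype=bool)
        bad = np.ones((1, 4, 4))
        with pytest.raises(ValueError):
            fuse(cube, mask, bad)

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((1, 4, 4), np.uint8), np.zeros((1, 5, 5), bool),
                 np.zeros((1, 4, 4)))
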
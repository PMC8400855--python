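"""Distance fields, class balancing and the composed weight map."""

import numpy as np
import pytest
from scipy import ndimage

from dermcad import weightmap as wmod
from dermcad.weightmap import class_balance_map, object_distance_fields, \
    sentinel_distance, weight_map


def brute_force_component_distances(mask):
    """O(pixels x component-pixels) exhaustive scan, independent of the
    distance-transform implementation."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    H, W = mask.shape
    sent = sentinel_distance(mask.shape)
    comp_pix = [np.argwhere(labels == i) for i in range(1, n + 1)]
    d1 = np.full((H, W), sent)
    d2 = np.full((H, W), sent)
    for y in range(H):
        for x in range(W):
            per_comp = sorted(
                np.sqrt(((pix - (y, x)) ** 2).sum(axis=1)).min()
                for pix in comp_pix
            )
            if len(per_comp) >= 1:
                d1[y, x] = per_comp[0]
            if len(per_comp) >= 2:
                d2[y, x] = per_comp[1]
    return d1, d2, n


def random_multiblob_mask(rng, side):
    mask = np.zeros((side, side), dtype=np.uint8)
    for _ in range(rng.integers(1, 5)):
        cy, cx = rng.integers(0, side, 2)
        r = rng.integers(1, max(2, side // 6))
        yy, xx = np.mgrid[0:side, 0:side]
        mask[np.hypot(yy - cy, xx - cx) <= r] = 1
    if mask.sum() == 0:
        mask[side // 2, side // 2] = 1
    return mask


class TestDistanceFields:
    def test_matches_exhaustive_scan_on_random_masks(self, rng):
        for _ in range(12):
            side = int(rng.integers(8, 33))
            mask = random_multiblob_mask(rng, side)
            fields = object_distance_fields(mask)
            d1, d2, n = brute_force_component_distances(mask)
            assert fields.n_objects == n
            np.testing.assert_allclose(fields.d1, d1, atol=1e-9)
            np.testing.assert_allclose(fields.d2, d2, atol=1e-9)

    def test_two_point_objects_hand_computed(self):
        mask = np.zeros((3, 12), dtype=np.uint8)
        mask[0, 0] = 1
        mask[0, 10] = 1
        fields = object_distance_fields(mask)
        assert fields.d1[0, 5] == 5 and fields.d2[0, 5] == 5
        assert fields.d1[0, 2] == 2 and fields.d2[0, 2] == 8

    def test_foreground_pixels_have_zero_d1(self, rng):
        mask = random_multiblob_mask(rng, 24)
        fields = object_distance_fields(mask)
        assert np.all(fields.d1[mask == 1] == 0)
        assert np.all(fields.d2 >= fields.d1)

    def test_single_component_sentinel(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[4:6, 4:6] = 1
        fields = object_distance_fields(mask)
        assert fields.n_objects == 1
        assert np.all(fields.d2 == sentinel_distance(mask.shape))

    def test_empty_mask_warns_and_returns_sentinel(self):
        with pytest.warns(UserWarning):
            fields = object_distance_fields(np.zeros((5, 5), dtype=np.uint8))
        assert fields.n_objects == 0
        assert np.all(fields.d1 == sentinel_distance((5, 5)))


class TestClassBalance:
    def test_half_foreground_gives_unit_weight(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[:2] = 1
        assert np.allclose(class_balance_map(mask), 1.0)

    def test_quarter_foreground_weights(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0] = 1  # 25% foreground
        wc = class_balance_map(mask)
        assert np.allclose(wc[mask == 1], 2.0)
        assert np.allclose(wc[mask == 0], 2.0 / 3.0)

    def test_count_weighted_mean_recovers_half_area_per_class(self, rng):
        mask = (rng.random((8, 8)) > 0.7).astype(np.uint8)
        if mask.sum() in (0, mask.size):
            mask[0, 0] = 1 - mask[0, 0]
        wc = class_balance_map(mask)
        n = mask.size
        assert np.isclose(wc[mask == 1].sum(), n / 2)
        assert np.isclose(wc[mask == 0].sum(), n / 2)

    def test_absent_class_capped_with_warning(self):
        with pytest.warns(UserWarning):
            class_balance_map(np.ones((4, 4), dtype=np.uint8))


class TestWeightMap:
    def test_touching_pixel_gets_full_boundary_bonus(self):
        # two adjacent point objects: the pixel between them has d1=d2=small
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 0] = 1
        mask[2, 4] = 1
        wm = weight_map(mask, omega0=10, sigma=5)
        wc = class_balance_map(mask)
        # scalar oracle: d1=d2=2 at the midpoint -> 10*exp(-16/50)
        expected = wc[2, 2] + 10 * np.exp(-16 / 50)
        assert np.isclose(wm.weights[2, 2], expected)

    def test_scalar_formula_value(self):
        # direct evaluation of the additive term at d1=d2=1
        assert np.isclose(10 * np.exp(-4 / 50), 9.231163463866358)
        mask = np.zeros((3, 4), dtype=np.uint8)
        mask[1, 0] = 1
        mask[1, 3] = 1
        wm = weight_map(mask, omega0=10.0, sigma=5.0)
        wc = class_balance_map(mask)
        d = object_distance_fields(mask)
        x = (1, 1)  # d1=1, d2=2
        expected = wc[x] + 10 * np.exp(-((d.d1[x] + d.d2[x]) ** 2) / 50)
        assert np.isclose(wm.weights[x], expected)

    def test_far_pixels_decay_to_class_balance(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[0, 0] = 1
        mask[0, 2] = 1
        wm = weight_map(mask, omega0=10, sigma=2)
        wc = class_balance_map(mask)
        assert np.isclose(wm.weights[39, 39], wc[39, 39], atol=1e-12)

    def test_single_object_reduces_to_class_balance(self):
        # the diagonal sentinel drives the exponential term to numerical zero
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 20:40] = 1
        wm = weight_map(mask)
        np.testing.assert_allclose(wm.weights, class_balance_map(mask), atol=1e-12)

    def test_commutes_with_flips(self, rng):
        mask = random_multiblob_mask(rng, 20)
        w = weight_map(mask).weights
        for flip in (np.flipud, np.fliplr):
            wf = weight_map(flip(mask).copy()).weights
            np.testing.assert_allclose(wf, flip(w), atol=1e-9)

    def test_weights_bounded_below_by_class_balance(self, rng):
        mask = random_multiblob_mask(rng, 20)
        wm = weight_map(mask)
        assert np.all(wm.weights >= class_balance_map(mask) - 1e-12)
        assert np.all(np.isfinite(wm.weights))

    def test_invalid_parameters_rejected(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = 1
        with pytest.raises(ValueError):
            weight_map(mask, omega0=-1)
        with pytest.raises(ValueError):
            weight_map(mask, sigma=0)


def test_weight_map_round_trip_via_lossless_dump(tmp_path, rng):
    mask = random_multiblob_mask(rng, 16)
    wm = weight_map(mask)
    png = tmp_path / "wm.png"
    wmod.save_weight_map(wm, png)
    reloaded = np.load(png.with_suffix(".npy"))
    np.testing.assert_array_equal(reloaded, wm.weights)
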
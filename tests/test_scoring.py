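"""IPI parameter computations, weight lookups, and score invariants."""

import numpy as np
import pytest
from scipy import ndimage

from woundipi.errors import DegenerateInputError, UsageError
from woundipi.imaging import BinaryMask, ImagePair, ThermalImage, VisualImage
from woundipi.scoring import (
    ScoringConfig,
    compute_ipi,
    concentration_flag,
    detect_cold_spots,
    inhomogeneity_flag,
    intact_skin_region,
    margin_crossing_flag,
    margin_superpixels,
    score_cold_spots,
    score_temp_difference,
    temperature_difference,
    thermal_wound_margin,
    wound_stats,
)


def reachability_oracle(wound, margin, skin, connectivity=8):
    """Independent margin-crossing check via exhaustive component labelling.

    The margin fails to guard the wound iff some connected component of
    skin & ~margin contains both an outer-rim pixel of the margin and a
    wound pixel.
    """
    structure = (
        np.ones((3, 3), bool)
        if connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    )
    if not margin.any():
        return 1
    free = skin & ~margin
    labels, _ = ndimage.label(free, structure=structure)
    rim = ndimage.binary_dilation(margin, structure=structure) & free & ~wound
    rim_labels = set(np.unique(labels[rim])) - {0}
    wound_labels = set(np.unique(labels[wound & free])) - {0}
    return int(bool(rim_labels & wound_labels))


def _square_wound(size=40, w0=10, w1=30, temp=35.0, base=33.0):
    t = np.full((size, size), base)
    wound = np.zeros((size, size), dtype=np.uint8)
    wound[w0:w1, w0:w1] = 1
    t[wound.astype(bool)] = temp
    return t, wound


class TestWoundStats:
    def test_mean_and_max(self):
        t = np.full((8, 8), 20.0)
        t[0, :3] = [34.0, 35.0, 36.0]
        wound = np.zeros((8, 8), dtype=np.uint8)
        wound[0, :3] = 1
        assert wound_stats(ThermalImage(t), BinaryMask(wound)) == (35.0, 36.0)

    def test_single_pixel(self):
        t = np.full((8, 8), 20.0)
        t[4, 4] = 33.0
        wound = np.zeros((8, 8), dtype=np.uint8)
        wound[4, 4] = 1
        assert wound_stats(ThermalImage(t), BinaryMask(wound)) == (33.0, 33.0)

    def test_weighted_mean(self):
        t = np.full((16, 16), 20.0)
        wound = np.zeros((16, 16), dtype=np.uint8)
        wound[0:10, 0:10] = 1  # 100 px at 35
        t[0:10, 0:10] = 35.0
        wound[12, 0:10] = 1  # 10 px at 32
        t[12, 0:10] = 32.0
        mean, mx = wound_stats(ThermalImage(t), BinaryMask(wound))
        assert mean == pytest.approx(34.7272727, abs=1e-6)
        assert mx == 35.0

    def test_empty_mask_rejected(self):
        with pytest.raises(UsageError):
            wound_stats(ThermalImage(np.full((8, 8), 30.0)), BinaryMask(np.zeros((8, 8), np.uint8)))


class TestColdSpots:
    def _scene(self, spot_specs, size=40):
        """Uniform 35 °C square wound with given (row, col, h, w, temp) spots."""
        t, wound = _square_wound(size=size)
        for r, c, hh, ww, temp in spot_specs:
            t[r : r + hh, c : c + ww] = temp
        return ThermalImage(t), BinaryMask(wound)

    def test_two_valid_spots_counted(self):
        thermal, wound = self._scene(
            [(12, 12, 4, 5, 31.0), (22, 22, 4, 5, 31.0)]
        )
        count, labels = detect_cold_spots(thermal, wound)
        assert count == 2
        assert labels.max() == 2

    def test_below_min_size_ignored(self):
        thermal, wound = self._scene([(15, 15, 1, 5, 31.0)])  # 5 px
        assert detect_cold_spots(thermal, wound)[0] == 0

    def test_above_max_size_ignored(self):
        thermal, wound = self._scene([(12, 12, 10, 15, 31.0)])  # 150 px
        assert detect_cold_spots(thermal, wound)[0] == 0

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(4)
        t, wound = _square_wound()
        t += rng.normal(0, 1.0, t.shape)
        thermal = ThermalImage(t)
        counts = [
            detect_cold_spots(thermal, BinaryMask(wound), ScoringConfig(cold_spot_delta=d))[0]
            for d in (0.5, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nearby_region_included_via_dilation(self):
        t, wound = _square_wound()
        t[32:36, 12:17] = 31.0  # 20 px just outside the wound, within 10 px
        count, _ = detect_cold_spots(ThermalImage(t), BinaryMask(wound))
        assert count == 1

    @pytest.mark.parametrize("count, expected", [(0, 0), (1, 2), (2, 2), (3, 2), (4, 4), (5, 4)])
    def test_case_distinction(self, count, expected):
        assert score_cold_spots(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(UsageError):
            score_cold_spots(-1)


class TestTemperatureDifference:
    def test_signed_subtraction(self):
        t = np.full((10, 10), 33.5)
        wound = np.zeros((10, 10), dtype=np.uint8)
        wound[2:4, 2:4] = 1
        t[2:4, 2:4] = 35.0
        t[2, 2] = 36.0
        intact = np.zeros((10, 10), dtype=np.uint8)
        intact[6:9, 6:9] = 1
        dt = temperature_difference(ThermalImage(t), BinaryMask(wound), BinaryMask(intact))
        assert dt == pytest.approx(2.5)

    def test_necrotic_wound_negative_difference(self):
        t = np.full((10, 10), 33.0)
        wound = np.zeros((10, 10), dtype=np.uint8)
        wound[2:4, 2:4] = 1
        t[2:4, 2:4] = 32.0
        intact = np.zeros((10, 10), dtype=np.uint8)
        intact[6:9, 6:9] = 1
        dt = temperature_difference(ThermalImage(t), BinaryMask(wound), BinaryMask(intact))
        assert dt == pytest.approx(-1.0)
        assert score_temp_difference(dt) == 1

    @pytest.mark.parametrize(
        "dt, expected",
        [(1.5, 0), (0.5, 1), (2.5, 2), (1.0, 0), (2.0, 0), (0.999, 1), (2.001, 2), (-1.0, 1)],
    )
    def test_case_distinction_with_closed_benign_band(self, dt, expected):
        assert score_temp_difference(dt) == expected


class TestSuperpixels:
    def test_uniform_boundary_splits_only_at_size_cap(self):
        _, wound = _square_wound()
        t = np.full((40, 40), 34.0)
        sps = margin_superpixels(BinaryMask(wound), ThermalImage(t))
        boundary_px = sum(sp.size for sp in sps)
        cfg = ScoringConfig()
        assert all(sp.size <= cfg.superpixel_max_px for sp in sps)
        full, partial = divmod(boundary_px, cfg.superpixel_max_px)
        assert len(sps) == full + (1 if partial else 0)

    def test_alternating_temperatures_single_pixel_groups(self):
        _, wound = _square_wound()
        t = np.full((40, 40), 30.0)
        t[:, ::2] = 33.0  # alternating columns: consecutive deltas ≥ 3 °C
        sps = margin_superpixels(BinaryMask(wound), ThermalImage(t))
        # grouping tolerance is 0.5 °C: nearly every group collapses to 1-2 px
        assert np.median([sp.size for sp in sps]) <= 2

    def test_single_pixel_wound(self):
        wound = np.zeros((10, 10), dtype=np.uint8)
        wound[5, 5] = 1
        sps = margin_superpixels(BinaryMask(wound), ThermalImage(np.full((10, 10), 33.0)))
        assert len(sps) == 1 and sps[0].size == 1

    def test_mean_equals_member_mean(self):
        rng = np.random.default_rng(9)
        _, wound = _square_wound()
        t = np.full((40, 40), 34.0) + rng.normal(0, 0.3, (40, 40))
        for sp in margin_superpixels(BinaryMask(wound), ThermalImage(t)):
            member = t[sp.pixels[:, 0], sp.pixels[:, 1]]
            assert sp.mean_temperature == pytest.approx(member.mean())


class TestThermalMargin:
    def test_radial_gradient_isotherm_radius(self):
        """Margin extends to the 1.5 °C isotherm of a 0.1 °C/px gradient."""
        size = 120
        rr, cc = np.mgrid[0:size, 0:size]
        wound = (((rr - 60) / 15) ** 2 + ((cc - 60) / 15) ** 2 <= 1).astype(np.uint8)
        d = ndimage.distance_transform_edt(~wound.astype(bool))
        t = np.where(wound.astype(bool), 35.0, 35.0 - 0.1 * d)
        skin = np.ones((size, size), dtype=np.uint8)
        margin = thermal_wound_margin(
            ThermalImage(t), BinaryMask(wound), BinaryMask(skin)
        )
        dist_in_margin = d[margin.as_bool()]
        assert abs(dist_in_margin.max() - 15.0) <= 2.0
        assert not np.any(margin.as_bool() & wound.astype(bool))

    def test_flat_skin_margin_reaches_skin_boundary(self):
        t, wound = _square_wound(temp=35.0, base=35.0)
        skin = np.zeros((40, 40), dtype=np.uint8)
        skin[2:38, 2:38] = 1
        margin = thermal_wound_margin(ThermalImage(t), BinaryMask(wound), BinaryMask(skin))
        outside_skin_ring = skin.astype(bool) & ~wound.astype(bool)
        assert margin.area == outside_skin_ring.sum()

    def test_cold_surroundings_confine_margin(self):
        t, wound = _square_wound(temp=35.0, base=30.0)  # 5 °C drop outside
        skin = np.ones((40, 40), dtype=np.uint8)
        margin = thermal_wound_margin(ThermalImage(t), BinaryMask(wound), BinaryMask(skin))
        assert margin.area == 0


class TestIntactSkin:
    def test_disjoint_from_wound_and_margin(self):
        skin = np.ones((40, 40), dtype=np.uint8)
        _, wound = _square_wound()
        margin = np.zeros((40, 40), dtype=np.uint8)
        margin[8:10, 8:32] = 1
        intact = intact_skin_region(BinaryMask(skin), BinaryMask(wound), BinaryMask(margin))
        assert intact.area > 0
        assert not np.any(intact.as_bool() & (wound.astype(bool) | margin.astype(bool)))

    def test_full_coverage_degenerate(self):
        skin = np.ones((20, 20), dtype=np.uint8)
        wound = np.ones((20, 20), dtype=np.uint8)
        margin = np.zeros((20, 20), dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            intact_skin_region(BinaryMask(skin), BinaryMask(wound), BinaryMask(margin))

    def test_zero_dilation_exact_set_algebra(self):
        skin = np.ones((30, 30), dtype=np.uint8)
        _, wound = _square_wound(size=30, w0=8, w1=20)
        margin = np.zeros((30, 30), dtype=np.uint8)
        margin[5:8, 8:20] = 1
        cfg = ScoringConfig(margin_dilation_px=0)
        intact = intact_skin_region(
            BinaryMask(skin), BinaryMask(wound), BinaryMask(margin), cfg
        )
        expected = skin.astype(bool) & ~wound.astype(bool) & ~margin.astype(bool)
        np.testing.assert_array_equal(intact.as_bool(), expected)


class TestDistributionFlags:
    def test_homogeneous_wound(self):
        rng = np.random.default_rng(1)
        t, wound = _square_wound()
        t += rng.uniform(-0.5, 0.5, t.shape)
        assert inhomogeneity_flag(ThermalImage(t), BinaryMask(wound)) == 0

    def test_sixty_percent_large_deviation(self):
        t, wound = _square_wound()
        idx = np.argwhere(wound.astype(bool))
        n = len(idx)
        k = int(0.6 * n) // 2 * 2
        chosen = idx[:k]
        t[chosen[: k // 2, 0], chosen[: k // 2, 1]] += 2.0
        t[chosen[k // 2 :, 0], chosen[k // 2 :, 1]] -= 2.0
        assert inhomogeneity_flag(ThermalImage(t), BinaryMask(wound)) == 1

    def test_exactly_half_is_not_a_majority(self):
        t, wound = _square_wound()
        idx = np.argwhere(wound.astype(bool))
        k = len(idx) // 2  # exactly 50 %, balanced +/-
        t[idx[: k // 2, 0], idx[: k // 2, 1]] += 2.0
        t[idx[k // 2 : k, 0], idx[k // 2 : k, 1]] -= 2.0
        frac = np.mean(
            np.abs(t[wound.astype(bool)] - t[wound.astype(bool)].mean()) > 1.2
        )
        assert frac == pytest.approx(0.5)
        assert inhomogeneity_flag(ThermalImage(t), BinaryMask(wound)) == 0

    def test_uniform_wound_not_concentrated(self):
        t, wound = _square_wound(size=60, w0=5, w1=55)
        assert concentration_flag(ThermalImage(t), BinaryMask(wound)) == 0

    def test_two_hot_patches_concentrated(self):
        t, wound = _square_wound(size=60, w0=5, w1=55)
        t[10:24, 10:24] += 3.0
        t[35:49, 35:49] += 3.0
        assert concentration_flag(ThermalImage(t), BinaryMask(wound)) == 1

    def test_many_scattered_patches_not_concentrated(self):
        t, wound = _square_wound(size=80, w0=2, w1=78)
        for r in (7, 28, 49):
            for c in (7, 49):
                t[r : r + 14, c : c + 14] += 3.0
        assert concentration_flag(ThermalImage(t), BinaryMask(wound)) == 0


class TestMarginCrossing:
    def _ring_scene(self, gap=0):
        size = 48
        rr, cc = np.mgrid[0:size, 0:size]
        r = np.hypot(rr - 24, cc - 24)
        wound = (r <= 8).astype(np.uint8)
        margin = ((r > 8) & (r <= 12)).astype(np.uint8)
        if gap:
            margin[22 : 22 + gap, 32:] = 0
        skin = np.ones((size, size), dtype=np.uint8)
        return wound, margin, skin

    def test_closed_ring_guards(self):
        wound, margin, skin = self._ring_scene()
        assert margin_crossing_flag(BinaryMask(wound), BinaryMask(margin), BinaryMask(skin)) == 0

    def test_three_pixel_gap_crosses(self):
        wound, margin, skin = self._ring_scene(gap=3)
        assert margin_crossing_flag(BinaryMask(wound), BinaryMask(margin), BinaryMask(skin)) == 1

    def test_empty_margin_unguarded(self):
        wound, _, skin = self._ring_scene()
        empty = BinaryMask(np.zeros_like(skin))
        assert margin_crossing_flag(BinaryMask(wound), empty, BinaryMask(skin)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reachability_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        wound, margin, skin = self._ring_scene()
        noise = rng.random(margin.shape) < 0.25
        margin = (margin.astype(bool) & ~noise).astype(np.uint8)
        skin = (rng.random(skin.shape) < 0.95).astype(np.uint8)
        got = margin_crossing_flag(BinaryMask(wound), BinaryMask(margin), BinaryMask(skin))
        exp = reachability_oracle(wound.astype(bool), margin.astype(bool), skin.astype(bool))
        assert got == exp


class TestComputeIPI:
    def test_benign_phantom_total_zero(self, benign_phantom):
        r = compute_ipi(
            benign_phantom.pair, benign_phantom.wound_mask, benign_phantom.skin_mask
        )
        assert r.total == 0

    def test_worst_phantom_total_nine(self, worst_phantom):
        r = compute_ipi(
            worst_phantom.pair, worst_phantom.wound_mask, worst_phantom.skin_mask
        )
        assert r.total == 9
        assert (
            r.cold_spot_score,
            r.temp_diff_score,
            r.inhomogeneous_flag,
            r.concentrated_flag,
            r.margin_crossing_flag,
        ) == (4, 2, 1, 1, 1)

    def test_mixed_phantom_sums_weights(self, iou_fn):
        from woundipi.phantom import PhantomSpec, generate

        res = generate(PhantomSpec.from_features(n_cold_spots=2, delta_t=2.5))
        r = compute_ipi(res.pair, res.wound_mask, res.skin_mask)
        assert (r.cold_spot_score, r.temp_diff_score) == (2, 2)
        assert r.total == 4

    def test_total_is_sum_of_subscores(self, worst_phantom):
        r = compute_ipi(
            worst_phantom.pair, worst_phantom.wound_mask, worst_phantom.skin_mask
        )
        assert r.total == (
            r.cold_spot_score
            + r.temp_diff_score
            + r.inhomogeneous_flag
            + r.concentrated_flag
            + r.margin_crossing_flag
        )

    def test_shift_invariance_of_all_subscores(self, worst_phantom):
        """All criteria are relative: a +1 °C offset changes nothing."""
        base = compute_ipi(
            worst_phantom.pair, worst_phantom.wound_mask, worst_phantom.skin_mask
        )
        shifted_pair = ImagePair(
            ThermalImage(worst_phantom.pair.thermal.temperatures + 1.0),
            worst_phantom.pair.visual,
        )
        shifted = compute_ipi(
            shifted_pair, worst_phantom.wound_mask, worst_phantom.skin_mask
        )
        assert base.to_dict() == shifted.to_dict()
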
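import numpy as np
import pytest

from obcacount.containers import ChannelImage
from obcacount.exceptions import BoundsError, ParameterError
from obcacount.maxima import (
    MaximaConfig,
    edit_points,
    find_maxima,
    maxima_with_prominence,
    pre_blur,
)
from oracles import gaussian_blur_oracle, maxima_oracle


def chan(arr, bit_depth=8):
    return ChannelImage(np.asarray(arr), bit_depth=bit_depth)


def two_peak_ridge():
    """Peaks 200 and 100 joined by a bridge of height 40 (the saddle)."""
    img = np.zeros((20, 20), dtype=np.uint8)
    img[5, 5] = 200
    img[5, 15] = 100
    img[5, 6:15] = 40
    return chan(img)


class TestPreBlur:
    def test_radius_zero_is_identity(self, rng):
        img = chan(rng.integers(0, 255, (16, 16), dtype=np.uint8))
        out = pre_blur(img, 0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            pre_blur(chan(np.zeros((4, 4), dtype=np.uint8)), -1.0)

    def test_impulse_mass_conserved(self):
        img = np.zeros((21, 21))
        img[10, 10] = 100.0
        out = pre_blur(chan(img), 1.0)
        assert abs(out.pixels.sum() - 100.0) < 1e-6
        # unimodal: global max at the impulse position
        assert np.unravel_index(np.argmax(out.pixels), (21, 21)) == (10, 10)

    def test_edge_impulse_mass_conserved_by_reflection(self):
        img = np.zeros((15, 15))
        img[0, 3] = 50.0
        out = pre_blur(chan(img), 1.5)
        assert abs(out.pixels.sum() - 50.0) < 1e-6

    def test_two_impulses_match_direct_convolution(self):
        img = np.zeros((11, 11))
        img[3, 2] = 80.0
        img[7, 8] = 120.0
        out = pre_blur(chan(img), 1.0)
        np.testing.assert_allclose(out.pixels, gaussian_blur_oracle(img, 1.0), atol=1e-9)


class TestFindMaxima:
    def test_single_gaussian_spot(self):
        yy, xx = np.mgrid[0:32, 0:32]
        img = 200.0 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / (2 * 3.0**2))
        ps = find_maxima(chan(img), MaximaConfig(noise_tolerance=50))
        assert len(ps) == 1
        np.testing.assert_allclose(ps.points[0], [16, 16])

    def test_two_peaks_prominence_gates_lower_peak(self):
        # lower peak prominence = 100 - 40 = 60
        assert len(find_maxima(two_peak_ridge(), MaximaConfig(noise_tolerance=50))) == 2
        assert len(find_maxima(two_peak_ridge(), MaximaConfig(noise_tolerance=70))) == 1

    def test_plateau_reported_once_at_center(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[3:6, 3:6] = 10
        ps = find_maxima(chan(img), MaximaConfig(noise_tolerance=5))
        assert len(ps) == 1
        np.testing.assert_allclose(ps.points[0], [4.0, 4.0])

    def test_flat_image_conventions(self):
        flat = chan(np.full((8, 8), 7, dtype=np.uint8))
        assert len(find_maxima(flat, MaximaConfig(noise_tolerance=1))) == 0
        ps = find_maxima(flat, MaximaConfig(noise_tolerance=0))
        assert len(ps) == 1
        np.testing.assert_allclose(ps.points[0], [3.5, 3.5])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_floodfill_oracle_integer_images(self, seed):
        r = np.random.default_rng(seed)
        img = r.integers(0, 60, (32, 32)).astype(np.float64)
        for tol in (0.0, 5.0, 15.0):
            pts, peaks, proms = maxima_with_prominence(chan(img, bit_depth=16))
            keep = proms > tol if tol > 0 else np.ones(len(proms), bool)
            got_pts = pts[keep]
            exp_pts, exp_peaks = maxima_oracle(img, tol)
            assert len(got_pts) == len(exp_pts), (seed, tol)
            np.testing.assert_allclose(got_pts, exp_pts, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floodfill_oracle_float_images(self, seed):
        r = np.random.default_rng(100 + seed)
        img = r.uniform(0, 100, (24, 24))
        tol = 20.0
        ps = find_maxima(chan(img, bit_depth=16), MaximaConfig(noise_tolerance=tol))
        exp_pts, _ = maxima_oracle(img, tol)
        assert len(ps) == len(exp_pts)
        np.testing.assert_allclose(ps.points, exp_pts, atol=1e-9)

    def test_monotone_in_tolerance(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            img = chan(r.integers(0, 200, (24, 24)).astype(np.uint8))
            prev = None
            for tol in (5.0, 20.0, 50.0, 90.0):
                pts = {tuple(p) for p in find_maxima(img, MaximaConfig(noise_tolerance=tol)).points}
                if prev is not None:
                    assert pts <= prev, seed
                prev = pts

    def test_translation_invariance(self, rng):
        img = rng.integers(0, 100, (24, 24)).astype(np.float64)
        cfg = MaximaConfig(noise_tolerance=10)
        a = find_maxima(chan(img, bit_depth=16), cfg).points
        b = find_maxima(chan(img + 500.0, bit_depth=16), cfg).points
        np.testing.assert_allclose(a, b)

    def test_well_separated_spots_counted_for_any_tolerance_in_window(self):
        yy, xx = np.mgrid[0:96, 0:96]
        img = np.zeros((96, 96))
        centers = [(20, 20), (20, 70), (70, 20), (70, 70), (48, 48)]
        for r, c in centers:
            img += 150.0 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 3.0**2))
        ch = chan(img, bit_depth=16)
        _, _, proms = maxima_with_prominence(ch)
        p = np.sort(proms)[-len(centers)]  # smallest true-peak prominence
        for tol in (0.1 * p, 0.5 * p, 0.99 * p):
            assert len(find_maxima(ch, MaximaConfig(noise_tolerance=tol))) == len(centers)

    def test_equal_peaks_with_deep_valley_both_reported(self):
        img = np.zeros((11, 11), dtype=np.uint8)
        img[5, 2] = 100
        img[5, 8] = 100
        img[5, 3:8] = 30
        ps = find_maxima(chan(img), MaximaConfig(noise_tolerance=50))
        assert len(ps) == 2

    def test_exclude_border_drops_edge_maxima(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[0, 4] = 200
        img[8, 8] = 200
        cfg = MaximaConfig(noise_tolerance=50, exclude_border=True)
        ps = find_maxima(chan(img), cfg)
        np.testing.assert_allclose(ps.points, [[8, 8]])

    def test_output_sorted_by_intensity_then_position(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[12, 3] = 150
        img[2, 10] = 250
        img[7, 7] = 200
        ps = find_maxima(chan(img), MaximaConfig(noise_tolerance=10))
        np.testing.assert_allclose(ps.points, [[2, 10], [7, 7], [12, 3]])


class TestEditPoints:
    def make_ps(self):
        from obcacount.containers import PointSet

        return PointSet(
            np.array([[5.0, 5.0], [10.0, 10.0], [20.0, 20.0]]),
            category=2,
            source_shape=(32, 32),
        )

    def test_remove_exact_point(self):
        out = edit_points(self.make_ps(), remove=[(10.0, 10.0)], snap_radius=1.0)
        assert len(out) == 2
        assert [10.0, 10.0] not in out.points.tolist()

    def test_remove_snaps_to_nearest_within_radius(self):
        out = edit_points(self.make_ps(), remove=[(11.0, 11.0)], snap_radius=3.0)
        assert len(out) == 2

    def test_remove_outside_snap_radius_is_noop(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="obcacount.maxima"):
            out = edit_points(self.make_ps(), remove=[(30.0, 30.0)], snap_radius=2.0)
        assert len(out) == 3
        assert "snap radius" in caplog.text

    def test_add_then_remove_restores_original(self):
        ps = self.make_ps()
        added = edit_points(ps, add=[(15.0, 15.0)])
        restored = edit_points(added, remove=[(15.0, 15.0)], snap_radius=0.5)
        np.testing.assert_allclose(np.sort(restored.points, axis=0), np.sort(ps.points, axis=0))

    def test_add_outside_bounds_rejected(self):
        with pytest.raises(BoundsError):
            edit_points(self.make_ps(), add=[(40.0, 5.0)])

    def test_duplicate_add_rejected(self):
        out = edit_points(self.make_ps(), add=[(5.2, 5.2)])
        assert len(out) == 3
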
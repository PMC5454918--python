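"""Spot detection and moment-based localization."""

import numpy as np
import pytest

from comboloc.localizer import (
    Frame, Roi, detect_spots, estimate_background, localize_roi,
    localize_stack, localization_precision, weighted_moments,
)
from reference import brute_moments, brute_precision


def frame_of(pixels, px=100.0, idx=0):
    return Frame(pixels=np.asarray(pixels, float), pixel_size_nm=px, frame_index=idx)


class TestBackground:
    def test_constant_field(self):
        assert estimate_background(frame_of(np.full((20, 20), 7.0))) == 7.0

    def test_median_ignores_single_outlier(self):
        img = np.full((100, 100), 5.0)
        img[50, 50] = 500.0
        assert estimate_background(frame_of(img)) == 5.0

    def test_poisson_field_near_rate(self, rng):
        img = rng.poisson(10.0, (200, 200)).astype(float)
        assert abs(estimate_background(frame_of(img)) - 10.0) <= 1.0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            Frame(pixels=np.empty((0, 0)), pixel_size_nm=100.0)


class TestDetectSpots:
    def test_constant_frame_yields_nothing(self):
        assert detect_spots(frame_of(np.full((30, 30), 10.0)), 10.0) == []

    def test_single_peak_threshold_and_subtraction(self):
        img = np.full((21, 21), 10.0)
        img[10, 10] = 50.0
        rois = detect_spots(frame_of(img), background=10.0, roi_side=7)
        assert len(rois) == 1
        roi = rois[0]
        assert roi.origin == (7, 7)
        # double background subtracted, clamped: center 50-20=30, rest 0
        assert roi.qi[3, 3] == 30.0
        assert roi.qi.sum() == 30.0

    def test_below_threshold_peak_ignored(self):
        img = np.full((21, 21), 10.0)
        img[10, 10] = 39.0  # < 4x background
        assert detect_spots(frame_of(img), 10.0) == []

    def test_two_separated_peaks(self):
        img = np.full((40, 40), 10.0)
        img[10, 10] = 50.0
        img[30, 30] = 50.0
        rois = detect_spots(frame_of(img), 10.0, roi_side=7)
        assert len(rois) == 2

    def test_overlapping_peaks_keep_brighter(self):
        img = np.full((40, 40), 10.0)
        img[20, 20] = 60.0
        img[20, 23] = 50.0  # within roi_side of the brighter peak
        rois = detect_spots(frame_of(img), 10.0, roi_side=7)
        assert len(rois) == 1
        assert rois[0].qi.max() == 60.0 - 20.0

    def test_peak_too_close_to_edge_dropped(self):
        img = np.full((20, 20), 10.0)
        img[1, 1] = 100.0
        assert detect_spots(frame_of(img), 10.0, roi_side=7) == []


class TestLocalizeRoi:
    def test_point_mass_at_central_pixel(self):
        qi = np.zeros((3, 3))
        qi[1, 1] = 50.0
        loc = localize_roi(Roi(origin=(0, 0), qi=qi, nb=0.0), pixel_size_nm=100.0)
        assert loc.x == pytest.approx(150.0)  # center of pixel col 1
        assert loc.y == pytest.approx(150.0)
        assert loc.sigma_x == 0.0 and loc.sigma_y == 0.0

    def test_symmetric_roi_centered(self):
        qi = np.array([[1, 2, 1], [2, 8, 2], [1, 2, 1]], float)
        loc = localize_roi(Roi(origin=(4, 6), qi=qi, nb=0.0), pixel_size_nm=10.0)
        assert loc.x == pytest.approx((6 + 1.5) * 10.0)
        assert loc.y == pytest.approx((4 + 1.5) * 10.0)

    def test_worked_1d_example(self):
        """q(x=0)=1, q(x=1)=3, N_B=0: Q=4, mu=0.75, var=0.1875, dmu~0.2602."""
        q = np.array([1.0, 3.0])
        x = np.array([0.0, 1.0])
        Q, mu, var = weighted_moments(q, x)
        assert Q == 4.0
        assert mu == pytest.approx(0.75, abs=0)
        assert var == pytest.approx(0.1875, abs=0)
        dmu = localization_precision(q, x, mu, nb=0.0)
        assert dmu == pytest.approx(np.sqrt(1 / 48 + 0.046875), rel=1e-12)
        assert dmu == pytest.approx(0.2602, abs=5e-5)

    def test_matches_double_loop_oracle(self, rng):
        """Vectorized moments equal the literal double-loop sums (1e-9 rel)."""
        px = 100.0
        for _ in range(50):
            side = int(rng.choice([3, 5, 7, 9]))
            qi = rng.uniform(0, 100, (side, side))
            origin = (int(rng.integers(0, 50)), int(rng.integers(0, 50)))
            nb = float(rng.uniform(0, 20))
            loc = localize_roi(Roi(origin=origin, qi=qi, nb=nb), px)
            Q, mx, my, vx, vy = brute_moments(qi, origin)
            px_x, px_y = brute_precision(qi, origin, nb, mx, my)
            assert loc.q_total == pytest.approx(Q, rel=1e-9)
            assert loc.x == pytest.approx(mx * px, rel=1e-9)
            assert loc.y == pytest.approx(my * px, rel=1e-9)
            assert loc.sigma_x == pytest.approx(np.sqrt(vx) * px, rel=1e-9)
            assert loc.sigma_y == pytest.approx(np.sqrt(vy) * px, rel=1e-9)
            assert loc.precision_x == pytest.approx(px_x * px, rel=1e-9)
            assert loc.precision_y == pytest.approx(px_y * px, rel=1e-9)

    def test_translation_equivariance(self, rng):
        qi = rng.uniform(0, 50, (5, 5))
        a = localize_roi(Roi(origin=(0, 0), qi=qi, nb=1.0), 100.0)
        b = localize_roi(Roi(origin=(3, 8), qi=qi, nb=1.0), 100.0)
        assert b.x - a.x == pytest.approx(8 * 100.0, abs=1e-9)
        assert b.y - a.y == pytest.approx(3 * 100.0, abs=1e-9)
        assert b.precision_x == pytest.approx(a.precision_x, rel=1e-12)

    def test_precision_shrinks_with_photons(self):
        """Scaling a fixed shape by k photons shrinks dmu; sum term ~ 1/k."""
        base = np.array([[1, 2, 1], [2, 8, 2], [1, 2, 1]], float)
        x = np.arange(3) + 0.5
        xs = np.tile(x, (3, 1))
        prev = np.inf
        sum_terms = []
        for k in (1, 4, 16, 64):
            q = base * k
            Q, mu, _ = weighted_moments(q, xs)
            dmu = localization_precision(q, xs, mu, nb=0.0)
            assert dmu < prev
            prev = dmu
            sum_terms.append(float((((xs - mu) / Q) ** 2 * q).sum()))
        ratios = np.array(sum_terms[:-1]) / np.array(sum_terms[1:])
        assert np.allclose(ratios, 4.0, rtol=1e-9)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            Roi(origin=(0, 0), qi=np.zeros((3, 3)), nb=0.0)


class TestLocalizeStack:
    def test_blank_stack_empty(self):
        frames = [frame_of(np.zeros((32, 32)), idx=i) for i in range(10)]
        assert len(localize_stack(frames)) == 0

    def test_determinism(self, rng):
        img = rng.poisson(10, (32, 32)).astype(float)
        img[16, 16] += 300
        frames = [frame_of(img, idx=i) for i in range(3)]
        a = localize_stack(frames, channel="c")
        b = localize_stack(frames, channel="c")
        assert a.df.equals(b.df)

    def test_frame_metadata_carried(self, rng):
        img = np.full((32, 32), 5.0)
        img[16, 16] = 400.0
        frames = [frame_of(img, idx=i) for i in range(4)]
        locs = localize_stack(frames, channel="alu")
        assert list(locs.df["frame"]) == [0, 1, 2, 3]
        assert set(locs.df["channel"]) == {"alu"}

    def test_inconsistent_shapes_rejected(self):
        frames = [frame_of(np.zeros((16, 16))), frame_of(np.zeros((16, 18)))]
        with pytest.raises(ValueError):
            localize_stack(frames)
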
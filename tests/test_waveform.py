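"""Line-scan, turning-point, waveform-normalization and difference-map tests."""

import numpy as np
import pytest

import myoturnover as mt
from myoturnover.errors import BoundaryError, InvalidConfigurationError
from myoturnover.simulate import LABEL_GREEN, profile_to_image
from myoturnover.waveform import (
    LineScan,
    extract_from_scan,
    find_turning_points,
    fit_polynomial,
)


class TestLineScan:
    def test_straight_polyline_round_trip(self, geometry, clean_render):
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, clean_render, seed=None)
        image = profile_to_image(scan, height_px=9)
        n = image.shape[2]
        ls = mt.line_scan(image, [(0, 4), (n - 1, 4)], width_px=1)
        np.testing.assert_allclose(ls.green, scan.green, atol=1e-9)
        np.testing.assert_allclose(ls.red, scan.red, atol=1e-9)

    def test_width_averaging_matches_width1_on_uniform_stripe(self, geometry, clean_render):
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, clean_render, seed=None)
        image = profile_to_image(scan, height_px=9)
        n = image.shape[2]
        w1 = mt.line_scan(image, [(0, 4), (n - 1, 4)], width_px=1)
        w5 = mt.line_scan(image, [(0, 4), (n - 1, 4)], width_px=5)
        np.testing.assert_allclose(w5.green, w1.green, atol=1e-9)

    def test_diagonal_polyline_matches_bilinear_oracle(self):
        # smooth axis-aligned pattern; sample a diagonal and compare with a
        # brute-force bilinear interpolation oracle
        yy, xx = np.mgrid[0:40, 0:60].astype(float)
        img = np.stack([np.sin(xx / 7) + yy / 40, np.cos(xx / 9)])
        ls = mt.line_scan(img, [(5, 5), (50, 30)], width_px=1)

        pts = np.array([(5, 5), (50, 30)], float)
        seg = pts[1] - pts[0]
        length = np.hypot(*seg)
        s = np.arange(0.0, length + 1e-9, 1.0)
        sx = pts[0][0] + seg[0] * s / length
        sy = pts[0][1] + seg[1] * s / length

        def bilinear(channel, x, y):
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            return (
                channel[y0, x0] * (1 - fx) * (1 - fy)
                + channel[y0, x0 + 1] * fx * (1 - fy)
                + channel[y0 + 1, x0] * (1 - fx) * fy
                + channel[y0 + 1, x0 + 1] * fx * fy
            )

        oracle = np.array([bilinear(img[0], x, y) for x, y in zip(sx, sy)])
        np.testing.assert_allclose(ls.green, oracle, atol=1e-6)

    def test_polyline_outside_bounds_rejected(self):
        img = np.zeros((2, 10, 10))
        with pytest.raises(BoundaryError):
            mt.line_scan(img, [(0, 0), (20, 5)])


class TestFitPolynomial:
    def test_exact_degree4_data(self):
        x = np.linspace(0, 2, 30)
        coeffs = [0.3, -1.0, 2.0, 0.5, -0.2]
        y = np.polynomial.polynomial.polyval(x, coeffs)
        scan = LineScan(positions_um=x, green=y, red=np.ones_like(x))
        fit = fit_polynomial(scan, degree=4)
        np.testing.assert_allclose(fit.green(x), y, atol=1e-9)

    def test_degree0_on_constant(self):
        x = np.linspace(0, 1, 10)
        scan = LineScan(positions_um=x, green=np.full(10, 3.3), red=np.zeros(10))
        fit = fit_polynomial(scan, degree=0)
        np.testing.assert_allclose(fit.green(x), 3.3)

    def test_too_few_samples_rejected(self):
        x = np.linspace(0, 1, 5)
        scan = LineScan(positions_um=x, green=x, red=x)
        with pytest.raises(InvalidConfigurationError):
            fit_polynomial(scan, degree=6)

    def test_peak_location_near_m_line(self, geometry):
        # a dome-shaped single-sarcomere profile (wide PSF, no neighbours):
        # the degree-6 smooth puts the peak at the M-line within one pixel
        render = mt.RenderConfig(noise_sd=0.0, background=0.0, psf_sigma=0.3)
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, render, seed=None, tile=False)
        fit = fit_polynomial(scan, degree=6)
        dense = np.linspace(scan.positions_um[0], scan.positions_um[-1], 2000)
        peak = dense[np.argmax(fit.green(dense))]
        center = scan.positions_um[-1] / 2
        assert abs(peak - center) <= render.pixel_size  # within one pixel


class TestFindTurningPoints:
    def test_cosine_has_analytic_minima(self):
        # green(x) = 1 - cos(2 pi x / 20 px) over 0-40 px: minima at 0/20/40
        x = np.arange(41.0)
        y = 1 - np.cos(2 * np.pi * x / 20)
        scan = LineScan(positions_um=x, green=y, red=np.zeros_like(x))
        fit = fit_polynomial(scan, degree=10)
        left, right = find_turning_points(fit.green)
        assert right - left == pytest.approx(20.0, abs=0.3)
        assert (left, right) == pytest.approx((0.0, 20.0), abs=0.3) or (
            left, right
        ) == pytest.approx((20.0, 40.0), abs=0.3)

    def test_monotone_ramp_is_boundary_error(self):
        x = np.linspace(0, 1, 30)
        scan = LineScan(positions_um=x, green=x.copy(), red=np.zeros_like(x))
        with pytest.raises(BoundaryError):
            find_turning_points(fit_polynomial(scan, degree=3).green)

    def test_zband_spacing_within_2pct_of_sarcomere_length(self, geometry, clean_render):
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, clean_render, seed=None)
        fit = fit_polynomial(scan, degree=6)
        left, right = find_turning_points(fit.green, scan=scan)
        assert right - left == pytest.approx(geometry.sarcomere_length, rel=0.02)


class TestExtractSarcomere:
    def test_baseline_arithmetic_and_coordinate_map(self):
        # quadratic channel through (10, 0.2), (50, 0.4) with value 1.3 at 30
        px = np.arange(0.0, 61.0)
        A = np.array([[10**2, 10, 1], [50**2, 50, 1], [30**2, 30, 1]], float)
        a, b, c = np.linalg.solve(A, [0.2, 0.4, 1.3])
        green = a * px**2 + b * px + c
        scan = LineScan(positions_um=px, green=green, red=green.copy())
        fit = fit_polynomial(scan, degree=2)
        w = mt.extract_sarcomere(fit, (10.0, 50.0))
        # baseline at 30 px is 0.3, so the pre-normalization value is 1.0
        i_mid = np.argmin(np.abs(w.x - 0.0))
        assert w.green[i_mid] * w.green_range == pytest.approx(1.3 - 0.3, abs=1e-9)
        # pixel 40 maps to normalized x = +0.5
        i40 = np.argmin(np.abs(w.x - 0.5))
        baseline_at_40 = 0.3 + (0.4 - 0.2) * (40 - 30) / (50 - 10)
        value_40 = a * 40**2 + b * 40 + c - baseline_at_40
        assert w.green[i40] * w.green_range == pytest.approx(value_40, abs=1e-9)

    def test_endpoints_zero_and_max_one(self, geometry):
        render = mt.RenderConfig(noise_sd=0.01)
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, render, seed=8)
        w = extract_from_scan(scan)
        assert w.green[0] == pytest.approx(0.0, abs=1e-12)
        assert w.green[-1] == pytest.approx(0.0, abs=1e-12)
        assert w.green.max() == pytest.approx(1.0)
        assert w.x[0] == -1.0 and w.x[-1] == 1.0 and w.x[len(w.x) // 2] == 0.0

    def test_symmetric_profile_gives_symmetric_waveform(self):
        px = np.arange(0.0, 81.0)
        green = np.exp(-0.5 * ((px - 40) / 12) ** 2) + 0.01
        scan = LineScan(positions_um=px, green=green, red=green.copy())
        fit = fit_polynomial(scan, degree=6)
        w = mt.extract_sarcomere(fit, (10.0, 70.0))
        np.testing.assert_allclose(w.green, w.green[::-1], atol=1e-12)

    def test_green_support_ends_near_normalized_tips(self, geometry, clean_render):
        """Rendered default geometry: green half-max support ends map to
        roughly +-0.8, the thick-filament tips."""
        labels = np.full(geometry.n_myosins, LABEL_GREEN, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, clean_render, seed=None)
        w = extract_from_scan(scan)
        above = w.x[w.green >= 0.5]
        assert above[-1] == pytest.approx(geometry.tip_coordinate, abs=0.06)
        assert above[0] == pytest.approx(-geometry.tip_coordinate, abs=0.06)

    def test_empty_red_channel_flagged(self, geometry):
        render = mt.RenderConfig(noise_sd=0.0, background=0.0)
        labels = np.zeros(geometry.n_myosins, dtype=np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, render, seed=None)
        w = extract_from_scan(scan)
        assert w.red_empty
        assert w.red_range == 0.0


class TestDifferenceMaps:
    @staticmethod
    def waveform_from_arrays(x, green, red, time_min=0.0):
        return mt.SarcomereWaveform(
            x=x, green=green, red=red, green_range=1.0, red_range=1.0,
            turning_points_um=(0.0, 1.0), baseline_green=(0, 0), baseline_red=(0, 0),
            degree=6, time_min=time_min,
        )

    def test_identical_channels_difference_zero(self):
        x = np.linspace(-1, 1, 201)
        g = 1 - x**2
        w = self.waveform_from_arrays(x, g, g.copy())
        np.testing.assert_allclose(mt.subtract_waveforms(w), 0.0, atol=1e-15)

    def test_gaussian_pair_difference_value(self):
        # green 1 - x^2, red = Gaussians at +-0.7 (sigma 0.15, height 1):
        # d(0.7) = 1 - 0.51 = +0.49
        x = np.linspace(-1, 1, 201)
        green = 1 - x**2
        red = np.exp(-0.5 * ((x - 0.7) / 0.15) ** 2) + np.exp(-0.5 * ((x + 0.7) / 0.15) ** 2)
        d = mt.subtract_waveforms(self.waveform_from_arrays(x, green, red))
        i = np.argmin(np.abs(x - 0.7))
        assert d[i] == pytest.approx(0.49, abs=0.01)

    def test_map_bounded_and_time_ordered(self):
        x = np.linspace(-1, 1, 201)
        rng = np.random.default_rng(1)
        ws = [
            self.waveform_from_arrays(
                x, rng.random(201), rng.random(201), time_min=t
            )
            for t in (30.0, 10.0, 20.0)
        ]
        dmap = mt.build_difference_map(ws)
        np.testing.assert_array_equal(dmap.times_min, [10.0, 20.0, 30.0])
        assert dmap.values.min() >= -1.0 and dmap.values.max() <= 1.0

    def test_grid_mismatch_resampled_with_warning(self):
        w1 = self.waveform_from_arrays(np.linspace(-1, 1, 201), np.ones(201), np.ones(201))
        w2 = self.waveform_from_arrays(np.linspace(-1, 1, 101), np.ones(101), np.ones(101))
        with pytest.warns(UserWarning, match="resampling"):
            dmap = mt.build_difference_map([w1, w2])
        assert dmap.values.shape == (1, 201)

    def test_mirror_equivariance_end_to_end(self, geometry, clean_render):
        rng = np.random.default_rng(3)
        labels = (rng.random(geometry.n_myosins) < 0.25).astype(np.int8)
        scan = mt.render_sarcomere_profile(labels, geometry, clean_render, seed=None)
        mirrored = mt.render_sarcomere_profile(labels[::-1], geometry, clean_render, seed=None)
        w = extract_from_scan(scan)
        wm = extract_from_scan(mirrored)
        np.testing.assert_allclose(w.red, wm.red[::-1], atol=1e-6)
        np.testing.assert_allclose(
            mt.subtract_waveforms(w), mt.subtract_waveforms(wm)[::-1], atol=1e-6
        )

    def test_photoconversion_map_sign_pattern(self, geometry):
        """Tip-biased photoconversion: after 60 min the difference map is
        positive (old/red label) in the middle and negative near the tips."""
        kin = mt.preset("tip_biased_paper")
        prot = mt.LabelProtocol(mode="photoconversion", conversion_efficiency=0.9)
        rec = np.arange(0, 201, 20) / 60.0
        render = mt.RenderConfig(noise_sd=0.0)
        ws = []
        for f in range(2):
            sim = mt.simulate_exchange(geometry, kin, prot, 200 / 60, seed=50 + f,
                                       record_times=rec)
            for j, t in enumerate(rec):
                scan = mt.render_sarcomere_profile(sim.labels[j], geometry, render,
                                                   seed=None, time_min=t * 60)
                ws.append(extract_from_scan(scan))
        dmap = mt.build_difference_map(ws)
        for i, t in enumerate(dmap.times_min):
            if t < 60:
                continue
            row = dmap.values[i]
            center = row[np.abs(dmap.x) < 0.2].mean()
            tips = row[(np.abs(dmap.x) > 0.65) & (np.abs(dmap.x) < 0.85)].mean()
            assert center > 0, f"t={t}: center difference should favour red"
            assert tips < 0, f"t={t}: tip difference should favour green"
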
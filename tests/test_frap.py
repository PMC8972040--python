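"""Normalization and exponential-recovery fitting tests."""

import numpy as np
import pytest

import myoturnover as mt
from myoturnover.errors import (
    CorrectionWindowError,
    DegenerateTraceError,
    InsufficientDataError,
)
from myoturnover.frap import FitResult, FrapTrace


def make_trace(times_h, green_conv, green_ref=None, red_conv=None, red_base=None):
    n = len(times_h)
    ones = np.ones(n)
    return FrapTrace(
        times_h=np.asarray(times_h, float),
        green_converted=np.asarray(green_conv, float),
        green_reference=np.asarray(green_ref if green_ref is not None else 100 * ones, float),
        red_converted=np.asarray(red_conv if red_conv is not None else 50 * ones, float),
        red_nonconverted=np.asarray(red_base if red_base is not None else 5 * ones, float),
    )


class TestNormalizeGreen:
    def test_constant_reference_affine_rescale(self):
        # pre 200, post 40, later 120 with a flat reference: (120-40)/(200-40)
        trace = make_trace([-1 / 6, 0, 1], [200, 40, 120])
        norm = mt.normalize_green(trace)
        assert norm.values[0] == pytest.approx(1.0)
        assert norm.values[1] == pytest.approx(0.0)
        assert norm.values[2] == pytest.approx(0.5)

    def test_decayed_reference_is_corrected_first(self):
        # reference 200 -> 160 at "later": corrected 120 * 200/160 = 150
        trace = make_trace([-1 / 6, 0, 1], [200, 40, 120], green_ref=[200, 200, 160])
        norm = mt.normalize_green(trace)
        assert norm.values[2] == pytest.approx((150 - 40) / (200 - 40))

    def test_zero_reference_reports_time_index(self):
        trace = make_trace([-1 / 6, 0, 1], [200, 40, 120], green_ref=[200, 0, 160])
        with pytest.raises(DegenerateTraceError, match="sample 1"):
            mt.normalize_green(trace)

    def test_zero_dynamic_range_rejected(self):
        trace = make_trace([-1 / 6, 0, 1], [100, 100, 100])
        with pytest.raises(DegenerateTraceError):
            mt.normalize_green(trace)

    def test_idempotent_on_already_normalized_trace(self):
        t = np.concatenate([[-1 / 6], np.linspace(0, 10, 20)])
        values = np.concatenate([[1.0], 0.6 * (1 - np.exp(-0.5 * np.linspace(0, 10, 20)))])
        # a "raw" trace whose converted channel is already the normalized
        # curve (pre = 1, post = 0) with a flat reference
        trace = make_trace(t, values, green_ref=np.ones_like(t))
        norm = mt.normalize_green(trace)
        np.testing.assert_allclose(norm.values, values, atol=1e-12)

    def test_simulator_round_trip_with_bleach(self, frap_times):
        render = mt.RenderConfig(noise_sd=0.0, bleach_rate_green=0.1, red_linear_drift=0.0)
        kin = mt.preset("monoexp_green")
        trace = mt.simulate_frap_trace(kin, render, frap_times, seed=0)
        norm = mt.normalize_green(trace)
        np.testing.assert_allclose(norm.post_values, trace.truth_replaced, atol=1e-12)


class TestNormalizeRed:
    def test_drift_free_correction_value_is_zero(self, frap_times):
        render = mt.RenderConfig(noise_sd=0.0, bleach_rate_green=0.0, red_linear_drift=0.0)
        trace = mt.simulate_frap_trace(mt.preset("monoexp_red"), render, frap_times, seed=0)
        norm = mt.normalize_red(trace)
        # only the residual exponential decay contributes to the window
        # slope (about 0.006 intensity/min here, on a post level of 100)
        assert abs(norm.correction_value) < 0.01

    def test_affine_rescale_against_nonconverted_zero(self):
        # post 80, non-converted level 5, later corrected 42.5 -> 0.5
        t = np.concatenate([[-1 / 6], np.linspace(0, 10, 61)])
        red = np.full(len(t), 42.5)
        red[1] = 80.0
        trace = make_trace(t, 100 * np.ones(len(t)), red_conv=red,
                           red_base=5 * np.ones(len(t)))
        norm = mt.normalize_red(trace)
        assert norm.values[1] == pytest.approx(1.0)
        assert norm.values[-1] == pytest.approx((42.5 - 5) / (80 - 5), abs=1e-6)

    def test_linear_drift_removed_in_correction_window(self):
        """On 100 e^{-0.3 t} plus a -0.01/min ramp the fitted 500-600 min
        slope is recovered and the corrected segment is >= 90% flatter."""
        t_post = np.linspace(0, 10, 61)
        t = np.concatenate([[-1 / 6], t_post])
        drift_per_min = -0.01
        raw = 100 * np.exp(-0.3 * np.maximum(t, 0)) + drift_per_min * np.maximum(t, 0) * 60
        trace = make_trace(t, 100 * np.ones(len(t)), red_conv=raw,
                           red_base=np.zeros(len(t)))
        norm = mt.normalize_red(trace)
        # least-squares oracle on the same window
        tm = trace.elapsed_min
        win = (tm >= 500) & (tm <= 600)
        oracle_slope = np.polyfit(tm[win], raw[win], 1)[0]
        assert norm.correction_value == pytest.approx(-oracle_slope, abs=1e-12)
        corrected = raw + norm.correction_value * tm
        resid_slope = np.polyfit(tm[win], corrected[win], 1)[0]
        assert abs(resid_slope) <= 0.1 * abs(oracle_slope)

    def test_short_trace_uses_final_window_with_warning(self):
        t = np.concatenate([[-1 / 6], np.linspace(0, 5, 31)])
        trace = make_trace(t, 100 * np.ones(len(t)),
                           red_conv=np.linspace(80, 30, len(t)),
                           red_base=np.zeros(len(t)))
        with pytest.warns(UserWarning, match="correction window"):
            mt.normalize_red(trace)

    def test_too_few_window_samples_rejected(self):
        t = np.array([-1 / 6, 0.0, 5.0, 10.0])
        trace = make_trace(t, 100 * np.ones(4), red_conv=[0, 80, 50, 30],
                           red_base=np.zeros(4))
        with pytest.raises(CorrectionWindowError):
            mt.normalize_red(trace)


class TestFitRecovery:
    def test_generative_identity_to_1e6(self, frap_times):
        t = np.concatenate([[-1 / 6], frap_times])
        y = np.concatenate([[1.0], 0.6 * (1 - np.exp(-np.log(2) * frap_times))])
        trace = make_trace(t, y, green_ref=np.ones(len(t)))
        fit = mt.fit_recovery(mt.normalize_green(trace))
        assert fit.converged
        assert fit.mf == pytest.approx(0.600, abs=1e-6)
        assert fit.t_half == pytest.approx(1.000, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_constant_series_flagged(self):
        t = np.concatenate([[-1 / 6], np.linspace(0, 10, 20)])
        y = np.concatenate([[1.0], np.zeros(20)])
        trace = make_trace(t, y, green_ref=np.ones(len(t)))
        fit = mt.fit_recovery(mt.normalize_green(trace))
        assert not fit.converged
        assert fit.mf == pytest.approx(0.0)
        assert np.isnan(fit.t_half)

    def test_too_few_samples_rejected(self):
        t = np.array([-1 / 6, 0, 1, 2, 3])
        trace = make_trace(t, [200, 40, 80, 100, 110])
        with pytest.raises(InsufficientDataError):
            mt.fit_recovery(mt.normalize_green(trace))

    def test_t_half_consistency_on_fitted_curve(self, frap_times):
        rng = np.random.default_rng(0)
        t = np.concatenate([[-1 / 6], frap_times])
        y = np.concatenate(
            [[1.0], 0.55 * (1 - np.exp(-0.4 * frap_times)) + rng.normal(0, 0.01, len(frap_times))]
        )
        fit = mt.fit_recovery(mt.normalize_green(make_trace(t, y, green_ref=np.ones(len(t)))))
        assert fit.converged
        # FI(t_half) - FI(0) = Mf / 2 exactly on the fitted curve
        delta = fit.curve(fit.t_half) - fit.curve(0.0)
        assert delta == pytest.approx(fit.mf / 2, abs=1e-9)

    def test_red_channel_fits_change_magnitude(self, frap_times):
        """The red path on a decreasing series equals the green path on its
        mirror 1 - y (channel symmetry)."""
        render = mt.RenderConfig(noise_sd=0.0, bleach_rate_green=0.0, red_linear_drift=0.0)
        kin = mt.preset("monoexp_red")
        trace = mt.simulate_frap_trace(kin, render, frap_times, seed=0)
        fit_red = mt.fit_recovery(mt.normalize_red(trace))
        norm = mt.normalize_red(trace)
        mirrored = mt.NormalizedTrace(
            times_h=norm.times_h, values=1.0 - norm.values, channel="green",
            post_index=norm.post_index,
        )
        fit_mirror = mt.fit_recovery(mirrored)
        assert fit_red.mf == pytest.approx(fit_mirror.mf, abs=1e-9)
        assert fit_red.t_half == pytest.approx(fit_mirror.t_half, abs=1e-9)
        # the 500-600 min window still carries a small residual of the
        # exponential itself, so the correction tilts the curve slightly
        # even on noiseless data; the fitted Mf stays within a few points
        assert fit_red.mf == pytest.approx(0.6698, abs=0.03)

    def test_noisy_preset_recovery(self, frap_times):
        """Seven noisy red traces recover the generative Mf and half-life."""
        render = mt.RenderConfig()
        fits = []
        for seed in range(7):
            trace = mt.simulate_frap_trace(mt.preset("monoexp_red"), render,
                                           frap_times, seed=300 + seed)
            fits.append(mt.fit_recovery(mt.normalize_red(trace)))
        assert np.mean([f.mf for f in fits]) == pytest.approx(0.6698, abs=0.05)
        assert np.mean([f.t_half for f in fits]) == pytest.approx(1.38, abs=0.25)


class TestCompareFits:
    @staticmethod
    def fits(values):
        return [
            FitResult(mf=v, rate=1.0, offset=0.0, t_half=np.log(2), residual_rms=0.0,
                      converged=True)
            for v in values
        ]

    def test_identical_groups_t0_p1(self):
        cmp = mt.compare_mf(self.fits([0.5, 0.6, 0.7]), self.fits([0.5, 0.6, 0.7]))
        assert cmp.t_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_shifted_groups_against_permutation_oracle(self):
        a = [0.5, 0.6, 0.7]
        b = [10.5, 10.6, 10.7]
        cmp = mt.compare_mf(self.fits(a), self.fits(b))
        assert abs(cmp.t_statistic) > 50
        assert cmp.p_value < 1e-3
        # permutation oracle: the observed |mean difference| is the most
        # extreme over all 6-choose-3 group relabelings
        import itertools

        pooled = a + b
        obs = abs(np.mean(a) - np.mean(b))
        count = sum(
            abs(np.mean(c) - np.mean([v for v in pooled if v not in c])) >= obs - 1e-12
            for c in itertools.combinations(pooled, 3)
        )
        assert count / 20 < 0.11  # only the 2 extreme splits match

    def test_single_element_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mt.compare_mf(self.fits([0.5]), self.fits([0.5, 0.6]))
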
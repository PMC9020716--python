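"""Region quantification, trace normalization and exponential recovery fits."""

import numpy as np
import pytest

from turboprox.frap import (
    FitError,
    FrapError,
    FrapTrace,
    Rect,
    RegionPair,
    extract_trace,
    fit_recovery,
    integrated_intensity,
    normalize_trace,
    recovery_model,
)
from turboprox.synthetic import generate_frap_stack, generate_frap_trace

REGIONS = RegionPair(inner=Rect(10, 10, 15, 15), outer=Rect(5, 5, 20, 20))


class TestIntegratedIntensity:
    def test_flat_signal_over_flat_background(self):
        frame = np.full((30, 30), 40.0)
        frame[10:15, 10:15] = 100.0
        # inner mean 100, ring mean 40, inner area 25 -> (100-40)*25
        assert integrated_intensity(frame, REGIONS) == pytest.approx(1500.0)

    def test_uniform_image_gives_zero(self):
        assert integrated_intensity(np.full((30, 30), 7.0), REGIONS) == 0.0

    def test_matches_brute_force_pixel_arithmetic(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:40, 0:40]
        frame = (
            20.0
            + 500 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 18.0)
            + rng.normal(0, 1, size=(40, 40))
        )
        regions = RegionPair(inner=Rect(14, 14, 27, 27), outer=Rect(8, 8, 33, 33))
        # oracle: explicit mask-based pixel sums
        inner_mask = np.zeros((40, 40), bool)
        inner_mask[14:27, 14:27] = True
        outer_mask = np.zeros((40, 40), bool)
        outer_mask[8:33, 8:33] = True
        ring_mask = outer_mask & ~inner_mask
        expected = (
            frame[inner_mask].mean() - frame[ring_mask].mean()
        ) * inner_mask.sum()
        assert integrated_intensity(frame, regions) == pytest.approx(expected)

    def test_out_of_bounds_region(self):
        with pytest.raises(FrapError, match="bounds"):
            integrated_intensity(np.zeros((12, 12)), REGIONS)

    def test_empty_ring_rejected(self):
        with pytest.raises(FrapError, match="ring"):
            RegionPair(inner=Rect(5, 5, 20, 20), outer=Rect(5, 5, 20, 20))


class TestExtractTrace:
    def test_identical_frames_give_constant_trace(self):
        frame = np.full((30, 30), 10.0)
        frame[10:15, 10:15] = 50.0
        stack = np.stack([frame] * 3)
        trace = extract_trace(stack, REGIONS, times=[0.0, 1.0, 2.0], bleach_index=1)
        assert np.allclose(trace.raw, trace.raw[0])

    def test_length_mismatch(self):
        stack = np.zeros((3, 30, 30))
        with pytest.raises(FrapError, match="mismatch"):
            extract_trace(stack, REGIONS, times=[0.0, 1.0], bleach_index=1)

    def test_recovers_generator_amplitude_series(self):
        times = np.arange(0, 20.0)
        trace = generate_frap_trace(0.8, 0.3, 0.1, times, bleach_index=4, seed=1)
        scaled = FrapTrace(times=times, raw=trace.raw * 2000, bleach_index=4)
        noise_sd = 0.5
        stack, regions = generate_frap_stack(
            scaled, frame_shape=(48, 48), background_level=30.0,
            noise_sd=noise_sd, seed=2,
        )
        measured = extract_trace(stack, regions, times, bleach_index=4)
        # per-point tolerance: 3 SD of the background-subtracted sum over
        # inner area plus ring-mean leakage of the Gaussian tail (~2%)
        n_inner = regions.inner.area
        tol = 3 * noise_sd * np.sqrt(2 * n_inner) + 0.03 * scaled.raw.max()
        assert np.all(np.abs(measured.raw - scaled.raw) < tol)


class TestNormalizeTrace:
    def test_division_by_prebleach_mean(self):
        trace = FrapTrace(
            times=np.arange(5.0), raw=[4.0, 4.0, 1.0, 2.0, 3.0], bleach_index=2
        )
        out = normalize_trace(trace)
        assert np.allclose(out.normalized, [1.0, 1.0, 0.25, 0.5, 0.75])

    def test_prebleach_all_twos_halves_everything(self):
        trace = FrapTrace(
            times=np.arange(4.0), raw=[2.0, 2.0, 0.5, 1.0], bleach_index=2
        )
        assert np.allclose(
            normalize_trace(trace).normalized, [1.0, 1.0, 0.25, 0.5]
        )

    def test_zero_prebleach_mean_rejected(self):
        trace = FrapTrace(
            times=np.arange(4.0), raw=[0.0, 0.0, 1.0, 2.0], bleach_index=2
        )
        with pytest.raises(FrapError, match="pre-bleach"):
            normalize_trace(trace)

    def test_n_pre_restricts_baseline_window(self):
        trace = FrapTrace(
            times=np.arange(5.0), raw=[8.0, 2.0, 2.0, 1.0, 1.5], bleach_index=3
        )
        out = normalize_trace(trace, n_pre=2)  # baseline = mean(2, 2) = 2
        assert out.normalized[3] == pytest.approx(0.5)


class TestFitRecovery:
    def make_trace(self, A, k, B, noise_sd=0.0, seed=0, t_max=30.0, n_pre=3):
        times = np.arange(-n_pre, t_max + 1.0)
        return generate_frap_trace(
            A, k, B, times, bleach_index=n_pre, noise_sd=noise_sd, seed=seed
        )

    def test_noiseless_identity(self):
        trace = normalize_trace(self.make_trace(0.8, 0.2, 0.05))
        fit = fit_recovery(trace)
        assert fit.A == pytest.approx(0.8, abs=1e-6)
        assert fit.k == pytest.approx(0.2, abs=1e-6)
        assert fit.B == pytest.approx(0.05, abs=1e-6)
        assert fit.t_half == pytest.approx(np.log(2) / 0.2, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_t_half_times_k_is_ln2(self):
        for seed in range(5):
            trace = normalize_trace(
                self.make_trace(0.9, 0.14, 0.1, noise_sd=0.05, seed=seed)
            )
            fit = fit_recovery(trace)
            assert fit.t_half * fit.k == pytest.approx(np.log(2), abs=1e-12)

    def test_invariant_to_time_translation(self):
        trace = normalize_trace(self.make_trace(0.7, 0.25, 0.1, noise_sd=0.02, seed=3))
        shifted = FrapTrace(
            times=trace.times + 100.0,
            raw=trace.raw,
            bleach_index=trace.bleach_index,
            normalized=trace.normalized,
        )
        a = fit_recovery(trace)
        b = fit_recovery(shifted)
        assert a.A == pytest.approx(b.A, rel=1e-9)
        assert a.k == pytest.approx(b.k, rel=1e-9)

    def test_matches_grid_search_oracle(self):
        trace = normalize_trace(self.make_trace(0.8, 0.2, 0.1, noise_sd=0.04, seed=7))
        fit = fit_recovery(trace)
        y = trace.normalized[trace.bleach_index:]
        x = trace.times[trace.bleach_index:] - trace.times[trace.bleach_index]
        # brute-force grid over (A, k, B)
        As = np.linspace(0.5, 1.1, 61)
        ks = np.linspace(0.05, 0.5, 91)
        Bs = np.linspace(-0.1, 0.3, 41)
        best = None
        for Ag in As:
            for kg in ks:
                pred = Ag * (1 - np.exp(-kg * x))
                for Bg in Bs:
                    ss = ((y - pred - Bg) ** 2).sum()
                    if best is None or ss < best[0]:
                        best = (ss, Ag, kg, Bg)
        _, Ag, kg, Bg = best
        assert fit.A == pytest.approx(Ag, abs=As[1] - As[0])
        assert fit.k == pytest.approx(kg, abs=ks[1] - ks[0])
        assert fit.B == pytest.approx(Bg, abs=Bs[1] - Bs[0])

    @pytest.mark.parametrize("A,k,B", [(0.9, np.log(2) / 5, 0.1), (0.85, 0.18, 0.08)])
    def test_parameter_recovery_over_seeded_ensemble(self, A, k, B):
        # median absolute relative error of (A, t_half) <= 5% at noise 0.05,
        # sampled at ~10 frames per half-time (0.5 s for these rates)
        times = np.arange(-1.5, 30.0, 0.5)
        errs_A, errs_t = [], []
        for seed in range(100):
            trace = normalize_trace(
                generate_frap_trace(
                    A, k, B, times, bleach_index=3, noise_sd=0.05, seed=seed
                )
            )
            fit = fit_recovery(trace)
            errs_A.append(abs(fit.A - A) / A)
            errs_t.append(abs(fit.t_half - np.log(2) / k) / (np.log(2) / k))
        assert np.median(errs_A) <= 0.05
        assert np.median(errs_t) <= 0.05

    def test_no_recovery_detected(self):
        times = np.arange(-2, 10.0)
        raw = np.ones_like(times)
        x = np.arange(10.0)
        # accelerating loss: the least-squares exponential has k < 0
        raw[2:] = 0.5 - 0.01 * (np.exp(0.2 * x) - 1)
        trace = normalize_trace(FrapTrace(times=times, raw=raw, bleach_index=2))
        with pytest.raises((FitError, FrapError)):
            fit_recovery(trace)

    def test_requires_normalization_and_enough_points(self):
        trace = self.make_trace(0.8, 0.2, 0.05)
        with pytest.raises(FrapError, match="normalize"):
            fit_recovery(trace)
        short = normalize_trace(
            generate_frap_trace(
                0.8, 0.2, 0.05, np.arange(-2, 3.0), bleach_index=2, seed=0
            )
        )
        with pytest.raises(FrapError, match="post-bleach"):
            fit_recovery(short)
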
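"""Photon-budget normalization, half-time extraction and replicate summaries."""

import math

import numpy as np
import pytest

from fpquant.photobleach import (
    BleachTrace,
    absorption_cross_section,
    initial_emission_rate,
    normalize_trace,
    replicate_stats,
    t_half,
)
from fpquant.reference import get_fp
from fpquant.simulate import gen_bleach_trace

STAYGOLD = get_fp("StayGold")
IRRADIANCE = 8.66  # W cm⁻²
LAMBDA_EX = 483.0


class TestCrossSectionAndRate:
    def test_cross_section_constant(self):
        assert absorption_cross_section(105_000) == pytest.approx(4.015e-16, rel=1e-3)

    def test_cross_section_linear_in_eps(self):
        assert absorption_cross_section(2e5) == pytest.approx(
            2 * absorption_cross_section(1e5)
        )

    def test_nonpositive_eps_errors(self):
        with pytest.raises(ValueError):
            absorption_cross_section(0.0)

    def test_initial_rate_chain(self):
        r0 = initial_emission_rate(STAYGOLD, IRRADIANCE, LAMBDA_EX)
        assert r0 == pytest.approx(7.86e3, rel=2e-3)

    def test_initial_rate_linear_in_irradiance(self):
        r1 = initial_emission_rate(STAYGOLD, IRRADIANCE, LAMBDA_EX)
        r2 = initial_emission_rate(STAYGOLD, 2 * IRRADIANCE, LAMBDA_EX)
        assert r2 == pytest.approx(2 * r1)

    def test_missing_eps_at_ex_errors(self):
        from fpquant.spectra import FPPhotophysics

        fp = FPPhotophysics("bare", 496, 505, eps_peak=1e5, qy=0.9)
        with pytest.raises(ValueError):
            initial_emission_rate(fp, IRRADIANCE, LAMBDA_EX)


class TestNormalizeTrace:
    def make_trace(self, k=math.log(2) / 300, dt=5.0, duration=1500.0):
        t = np.arange(0.0, duration + dt / 2, dt)
        return BleachTrace(time=t, intensity=np.exp(-k * t))

    def test_initial_rate_is_exactly_1000(self):
        norm = normalize_trace(self.make_trace(), STAYGOLD, IRRADIANCE, LAMBDA_EX)
        assert norm.emission_rate[0] == 1000.0
        assert norm.norm_time[0] == 0.0

    def test_time_axis_scaled_by_r0_over_1000(self):
        trace = self.make_trace()
        norm = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        r0 = initial_emission_rate(STAYGOLD, IRRADIANCE, LAMBDA_EX)
        assert norm.scale_factor == pytest.approx(r0 / 1000.0)
        np.testing.assert_allclose(norm.norm_time, trace.time * norm.scale_factor)

    @pytest.mark.parametrize("gain", [0.01, 3.7, 1e5])
    def test_gain_invariance(self, gain):
        trace = self.make_trace()
        scaled = BleachTrace(time=trace.time, intensity=trace.intensity * gain)
        a = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        b = normalize_trace(scaled, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        np.testing.assert_allclose(a.emission_rate, b.emission_rate, rtol=1e-12)
        np.testing.assert_allclose(a.norm_time, b.norm_time)
        assert t_half(a).value == pytest.approx(t_half(b).value, rel=1e-12)

    def test_irradiance_linearity_of_scale_factor(self):
        trace = self.make_trace()
        a = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        b = normalize_trace(trace, STAYGOLD, 2 * IRRADIANCE, LAMBDA_EX)
        assert b.scale_factor == pytest.approx(2 * a.scale_factor, rel=1e-12)
        assert t_half(b).value == pytest.approx(2 * t_half(a).value, rel=1e-9)

    def test_zero_initial_intensity_errors(self):
        trace = BleachTrace(time=[0.0, 1.0, 2.0], intensity=[0.0, 0.5, 0.2])
        with pytest.raises(ValueError):
            normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)

    def test_input_trace_untouched(self):
        trace = self.make_trace()
        before = trace.intensity.copy()
        normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX, smooth_window=5)
        np.testing.assert_array_equal(trace.intensity, before)


class TestTHalf:
    def test_exact_halving_decay(self):
        t = np.arange(0.0, 1200.0, 1.0)
        from fpquant.photobleach import NormalizedTrace

        norm = NormalizedTrace(
            norm_time=t, emission_rate=1000.0 * 2 ** (-t / 300.0), scale_factor=1.0
        )
        res = t_half(norm)
        assert not res.censored
        assert res.value == pytest.approx(300.0, rel=1e-4)

    def test_raw_half_time_rescales_with_r0(self):
        # a raw trace halving at 660 s, R0 ≈ 7.86e3 → normalized t½ ≈ 5.19e3 s
        k = math.log(2) / 660.0
        t = np.arange(0.0, 3000.0, 1.0)
        trace = BleachTrace(time=t, intensity=np.exp(-k * t))
        norm = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        assert t_half(norm).value == pytest.approx(5.19e3, rel=2e-3)

    def test_biexponential_matches_brute_force_root(self):
        components = [(0.6, 0.01), (0.4, 0.001)]
        trace, gt = gen_bleach_trace(components, duration=2000.0, dt=1.0, noise_sd=0.0)
        # independent oracle: fine-grid bracketing at 1e-3 s resolution
        grid = np.arange(0.0, 2000.0, 1e-3)
        mix = 0.6 * np.exp(-0.01 * grid) + 0.4 * np.exp(-0.001 * grid)
        oracle = grid[np.argmax(mix <= 0.5)]
        assert gt.true_t_half == pytest.approx(oracle, abs=2e-3)

        norm = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        got = t_half(norm).value / norm.scale_factor
        assert got == pytest.approx(oracle, abs=1.0)  # within one sample interval

    def test_censored_trace_flagged(self):
        from fpquant.photobleach import NormalizedTrace

        t = np.arange(0.0, 100.0, 10.0)
        norm = NormalizedTrace(
            norm_time=t, emission_rate=np.linspace(1000, 600, t.size), scale_factor=1.0
        )
        res = t_half(norm)
        assert res.censored
        assert res.value == pytest.approx(t[-1])


class TestReplicateStats:
    def test_table_style_triple(self):
        stats = replicate_stats([5052.0, 5190.0, 5328.0])
        assert stats.mean == pytest.approx(5190.0)
        assert stats.sd == pytest.approx(138.0)
        assert stats.n == 3

    def test_permutation_invariance(self):
        a = replicate_stats([3.0, 1.0, 2.0])
        b = replicate_stats([1.0, 2.0, 3.0])
        assert (a.mean, a.sd) == (b.mean, b.sd)

    def test_single_value_policy(self):
        stats = replicate_stats([100.0])
        assert stats.mean == 100.0
        assert stats.sd == 0.0
        assert not stats.sd_defined

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            replicate_stats([])


class TestParameterRecovery:
    def test_analytic_monoexponential_agreement(self):
        # t½ = ln2/k × scale_factor, pipeline within 0.5% at dt = t½/50
        k = math.log(2) / 300.0
        trace, _ = gen_bleach_trace([(1.0, k)], duration=1200.0, dt=6.0)
        norm = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX)
        expected = math.log(2) / k * norm.scale_factor
        assert t_half(norm).value == pytest.approx(expected, rel=5e-3)

    def test_noisy_recovery_median_error(self):
        # 1% additive noise (within the ≤2% study condition), width-5 smoothing
        k = math.log(2) / 300.0
        errs = []
        for seed in range(100):
            trace, gt = gen_bleach_trace(
                [(1.0, k)], duration=1200.0, dt=6.0, noise_sd=0.01, seed=seed
            )
            norm = normalize_trace(trace, STAYGOLD, IRRADIANCE, LAMBDA_EX, smooth_window=5)
            true = gt.true_t_half * norm.scale_factor
            errs.append(abs(t_half(norm).value - true) / true)
        assert float(np.median(errs)) <= 0.02
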
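"""Synthetic-data generators: determinism, ground truth, statistical structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpquant.simulate import (
    SimulationConfig,
    gen_assay_counts,
    gen_bicistronic_field,
    gen_bleach_trace,
    gen_coloc_pair,
    gen_maturation_course,
    gen_motion_stack,
    gen_spectrum_pair,
    gen_titration_series,
    hill_fluorescence,
)

GRID = np.arange(350.0, 651.0)


class TestSpectrumPair:
    def test_unimodal_with_unit_peaks(self):
        ex, em = gen_spectrum_pair(496, 505, 25, 20, GRID)
        assert ex.intensity.max() == pytest.approx(1.0)
        assert em.intensity.max() == pytest.approx(1.0)
        assert GRID[np.argmax(ex.intensity)] == 496
        assert GRID[np.argmax(em.intensity)] == 505
        assert np.all(ex.intensity >= 0) and np.all(em.intensity >= 0)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            gen_spectrum_pair(496, 505, 0.0, 20, GRID)
        with pytest.raises(ValueError):
            gen_spectrum_pair(496, 505, 25, 20, np.array([]))
        with pytest.raises(ValueError):
            gen_spectrum_pair(505, 496, 25, 20, GRID)  # negative Stokes shift

    def test_seed_free_determinism(self):
        a = gen_spectrum_pair(496, 505, 25, 20, GRID)
        b = gen_spectrum_pair(496, 505, 25, 20, GRID)
        np.testing.assert_array_equal(a[0].intensity, b[0].intensity)
        np.testing.assert_array_equal(a[1].intensity, b[1].intensity)


class TestBleachTrace:
    def test_monoexponential_closed_form(self):
        k = math.log(2) / 300.0
        trace, gt = gen_bleach_trace([(1.0, k)], duration=900.0, dt=1.0)
        assert gt.true_t_half == pytest.approx(300.0)
        assert trace.intensity[0] == pytest.approx(1.0)
        i300 = np.argmin(np.abs(trace.time - 300.0))
        assert trace.intensity[i300] == pytest.approx(0.5, abs=1e-3)

    def test_biexponential_ground_truth_vs_fine_grid(self):
        trace, gt = gen_bleach_trace([(0.6, 0.01), (0.4, 0.001)], duration=1500.0, dt=1.0)
        grid = np.arange(0.0, 1500.0, 1e-3)
        mix = 0.6 * np.exp(-0.01 * grid) + 0.4 * np.exp(-0.001 * grid)
        oracle = grid[np.argmax(mix <= 0.5)]
        assert gt.true_t_half == pytest.approx(oracle, abs=2e-3)

    def test_noiseless_monotone_nonincreasing(self):
        trace, _ = gen_bleach_trace([(0.5, 0.01), (0.5, 0.002)], duration=500.0, dt=2.0)
        assert np.all(np.diff(trace.intensity) <= 0)

    def test_determinism_with_noise(self):
        a, _ = gen_bleach_trace([(1.0, 0.01)], 100.0, 1.0, noise_sd=0.01, seed=42)
        b, _ = gen_bleach_trace([(1.0, 0.01)], 100.0, 1.0, noise_sd=0.01, seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    @pytest.mark.parametrize(
        "components,duration,dt",
        [
            ([(1.0, 0.01)], 100.0, 0.0),
            ([(1.0, 0.01)], 0.5, 1.0),
            ([(0.5, 0.01)], 100.0, 1.0),  # fractions don't sum to 1
            ([(1.0, -0.01)], 100.0, 1.0),
        ],
    )
    def test_invalid_inputs_error(self, components, duration, dt):
        with pytest.raises(ValueError):
            gen_bleach_trace(components, duration, dt)


class TestBicistronicField:
    def test_equal_brightness_gives_unit_per_cell_ratio(self):
        cfg = SimulationConfig(seed=1, n_cells=30, noise_sd=0.0)
        _, _, table, gt = gen_bicistronic_field(cfg, 2.5, 2.5)
        ratios = np.array(table["green"]) / np.array(table["red"])
        np.testing.assert_allclose(ratios, 1.0, rtol=1e-12)
        assert gt.true_ratio == 1.0

    def test_mean_ratio_recovers_ground_truth(self):
        # Monte-Carlo across seeds: mean per-cell ratio within 3 SE of 0.22
        means = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_cells=100, noise_sd=0.5)
            _, _, table, _ = gen_bicistronic_field(cfg, 0.22, 1.0)
            means.append(np.mean(np.array(table["green"]) / np.array(table["red"])))
        means = np.array(means)
        se = means.std(ddof=1) / math.sqrt(means.size)
        assert abs(means.mean() - 0.22) <= max(3 * se, 1e-9)

    def test_empty_field(self):
        cfg = SimulationConfig(seed=0, n_cells=0, noise_sd=0.0)
        green, red, table, _ = gen_bicistronic_field(cfg, 1.0, 1.0)
        assert len(table["cell"]) == 0
        np.testing.assert_allclose(green, cfg.background)

    def test_too_many_cells_errors(self):
        cfg = SimulationConfig(seed=0, n_cells=10_000, image_shape=(64, 64))
        with pytest.raises(ValueError):
            gen_bicistronic_field(cfg, 1.0, 1.0)

    def test_determinism(self):
        cfg = SimulationConfig(seed=7, n_cells=20)
        a = gen_bicistronic_field(cfg, 0.5, 1.0)
        b = gen_bicistronic_field(cfg, 0.5, 1.0)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestMaturationCourse:
    def test_boundary_and_asymptote(self):
        t = np.array([0.0, 1e6])
        table, red_final, gt = gen_maturation_course(1e-4, 50.0, t, red_final=80.0)
        assert table["green"][0] == 0.0
        assert table["green"][-1] == pytest.approx(50.0, rel=1e-6)
        assert red_final == 80.0

    def test_noiseless_rate_recovery_by_least_squares(self):
        from fpquant.brightness import fit_maturation

        k_true = 2.0e-5
        t = np.linspace(0.0, 48 * 3600.0, 97)
        table, _, gt = gen_maturation_course(k_true, 1.0, t, red_final=1.0)
        k_fit, plateau = fit_maturation(t, table["green"])
        assert k_fit == pytest.approx(k_true, rel=1e-6)
        assert plateau == pytest.approx(1.0, rel=1e-6)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            gen_maturation_course(1e-4, 1.0, np.array([]), red_final=1.0)
        with pytest.raises(ValueError):
            gen_maturation_course(0.0, 1.0, np.array([0.0, 1.0]), red_final=1.0)


class TestTitration:
    def test_half_max_at_pka(self):
        ph = np.arange(3.0, 11.5, 0.5)
        table, gt = gen_titration_series(4.8, 1.0, 100.0, ph)
        f_at_pka = hill_fluorescence(np.array([4.8]), 4.8, 1.0, 100.0)[0]
        assert f_at_pka == pytest.approx(50.0)
        assert gt.true_pka == 4.8
        # asymptote: far above the pKa fluorescence approaches the plateau
        assert table["fluorescence"][-1] == pytest.approx(100.0, rel=1e-3)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            gen_titration_series(4.8, 0.0, 1.0, np.arange(3.0, 11.0))
        with pytest.raises(ValueError):
            gen_titration_series(4.8, 1.0, 1.0, np.array([-1.0, 5.0]))


class TestAssayCounts:
    def test_boundaries(self):
        (n_normal, n_total), _ = gen_assay_counts(1.0, 50, seed=0)
        assert (n_normal, n_total) == (50, 50)
        (n_normal, n_total), _ = gen_assay_counts(0.0, 50, seed=0)
        assert n_normal == 0
        (n_normal, n_total), _ = gen_assay_counts(0.5, 0, seed=0)
        assert (n_normal, n_total) == (0, 0)

    def test_observed_fraction_within_binomial_se(self):
        (n_normal, n_total), gt = gen_assay_counts(0.95, 10_000, seed=11)
        se = math.sqrt(0.95 * 0.05 / 10_000)
        assert abs(n_normal / n_total - 0.95) <= 3 * se

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            gen_assay_counts(0.5, -1)


class TestColocPair:
    def test_rho_one_is_affine(self):
        a, b, _ = gen_coloc_pair(1.0, 1000, seed=0)
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sample_r_within_fisher_z_tolerance(self):
        a, b, gt = gen_coloc_pair(0.8, 100_000, seed=5)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r - 0.8) <= 0.01  # ≫ Fisher-z SE (1-ρ²)/√n ≈ 0.0011

    def test_saturated_pixel_count_exact(self):
        n = 12_345
        a, b, _ = gen_coloc_pair(0.5, n, saturation_fraction=0.1, seed=2)
        assert int((a == 4095.0).sum()) == int(0.1 * n)
        assert int((b == 4095.0).sum()) == int(0.1 * n)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            gen_coloc_pair(1.5, 100)
        with pytest.raises(ValueError):
            gen_coloc_pair(0.5, 1)


class TestMotionStack:
    def test_static_frames_bit_identical(self):
        stack, _ = gen_motion_stack("static", n_frames=5, seed=3)
        for i in range(1, 5):
            np.testing.assert_array_equal(stack[i], stack[0])

    def test_zero_shift_equals_static(self):
        a, _ = gen_motion_stack("static", n_frames=4, seed=9)
        b, _ = gen_motion_stack("shifting", shift_per_frame=0.0, n_frames=4, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_shifting_is_exact_translation(self):
        stack, gt = gen_motion_stack("shifting", shift_per_frame=3, n_frames=4, seed=1)
        np.testing.assert_array_equal(stack[1], np.roll(stack[0], 3, axis=1))
        assert gt.shift_per_frame == 3.0

    def test_remodeling_frame_correlation(self):
        stack, gt = gen_motion_stack(
            "remodeling", n_frames=30, seed=4, shape=(96, 96), texture_corr=0.5
        )
        rs = [
            np.corrcoef(stack[i].ravel(), stack[i + 1].ravel())[0, 1]
            for i in range(stack.shape[0] - 1)
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.02)

    def test_all_intensities_nonnegative(self):
        for mode in ("static", "shifting", "remodeling"):
            stack, _ = gen_motion_stack(mode, shift_per_frame=1, n_frames=3, seed=0)
            assert np.all(stack >= 0)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            gen_motion_stack("swirling", n_frames=3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_generators_are_seed_deterministic(seed):
    """Identical (parameters, seed) must give bit-identical outputs."""
    a, _ = gen_bleach_trace([(1.0, 0.01)], 50.0, 1.0, noise_sd=0.05, seed=seed)
    b, _ = gen_bleach_trace([(1.0, 0.01)], 50.0, 1.0, noise_sd=0.05, seed=seed)
    np.testing.assert_array_equal(a.intensity, b.intensity)
    s1, _ = gen_motion_stack("remodeling", n_frames=3, seed=seed, shape=(16, 16))
    s2, _ = gen_motion_stack("remodeling", n_frames=3, seed=seed, shape=(16, 16))
    np.testing.assert_array_equal(s1, s2)
    c1 = gen_coloc_pair(0.3, 100, seed=seed)
    c2 = gen_coloc_pair(0.3, 100, seed=seed)
    np.testing.assert_array_equal(c1[0], c2[0])
    np.testing.assert_array_equal(c1[1], c2[1])
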
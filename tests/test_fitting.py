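"""Noise-floor screening, extreme flagging and the three model fits."""

import numpy as np
import pytest

from mmtid import (ADCParams, FitConfig, MMParams, TIDParams, add_rician_noise,
                   adc_signal, fit_adc, fit_mm, fit_tid, fit_voxel_models,
                   is_extreme, mm_signal, noise_floor_mask, rician_s_noise,
                   tid_signal)


class TestNoiseFloor:
    def test_threshold_rule(self):
        mask = noise_floor_mask(np.array([0.5, 0.2, 0.09, 0.11]), s_noise=0.05)
        assert mask.tolist() == [True, True, False, True]

    def test_zero_s_noise_rejected(self):
        with pytest.raises(ValueError):
            noise_floor_mask(np.array([1.0]), s_noise=0.0)

    def test_all_below_floor_flags_voxel_unfittable(self, two_dt, fast_config):
        raw = np.full(8, 1e-4)
        mm, tid, mask = fit_voxel_models(raw, two_dt, fast_config, s_noise=0.05)
        assert not mask.any()
        assert not mm.fittable and not tid.fittable


class TestExtremeFlag:
    @pytest.mark.parametrize("values,expected", [
        ({"R": 0.3}, True),          # 0.3 - 0.1 < 0.01 * 24.9
        ({"R": 12.0}, False),
        ({"fi": 0.995}, True),
    ])
    def test_range_rule(self, values, expected):
        bounds = {"R": (0.1, 25.0), "fi": (0.01, 1.0)}
        assert is_extreme(values, bounds, margin=0.01, mode="range") is expected

    def test_value_mode_differs_near_wide_lower_bound(self):
        # 0.3 is extreme relative to the 24.9-wide range but not within
        # 1% of the bound value 0.1
        bounds = {"R": (0.1, 25.0)}
        assert is_extreme({"R": 0.3}, bounds, mode="range")
        assert not is_extreme({"R": 0.3}, bounds, mode="value")


class TestTIDFit:
    def test_noiseless_self_consistency(self, two_dt, fast_config):
        y = tid_signal(TIDParams(Dprime=1.5), two_dt)
        fit = fit_tid(y, two_dt, np.ones(8, bool), fast_config)
        assert fit.params.Dprime == pytest.approx(1.5, abs=1e-4)
        assert fit.rss < 1e-12
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_cannot_fit_time_dependent_signal(self, two_dt, fast_config):
        y = mm_signal(MMParams(R=10.0, Di=1.0, De=0.6, fi=0.41), two_dt)
        fit = fit_tid(y, two_dt, np.ones(8, bool), fast_config)
        assert fit.rss > 1e-4

    def test_single_point_unfittable(self, two_dt, fast_config):
        mask = np.zeros(8, bool)
        mask[0] = True
        fit = fit_tid(np.ones(8), two_dt, mask, fast_config)
        assert not fit.fittable


class TestMMFit:
    def test_discrete_di_noiseless_recovery(self, two_dt, fast_config):
        truth = MMParams(R=10.0, Di=1.0, De=0.6, fi=0.41)
        y = mm_signal(truth, two_dt)
        fit = fit_mm(y, two_dt, np.ones(8, bool), fast_config, "discrete_di")
        assert fit.params.Di == 1.0
        assert fit.params.R == pytest.approx(truth.R, rel=0.01)
        assert fit.params.De == pytest.approx(truth.De, rel=0.01)
        assert fit.params.fi == pytest.approx(truth.fi, rel=0.01)
        assert not fit.extreme

    def test_discrete_di_floors_low_diffusivity(self, two_dt, fast_config):
        # ground truth below the discrete set: the fit cannot return less
        # than the smallest allowed value
        y = mm_signal(MMParams(R=10.0, Di=0.2, De=0.6, fi=0.5), two_dt)
        fit = fit_mm(y, two_dt, np.ones(8, bool), fast_config, "discrete_di")
        assert fit.params.Di == 0.5

    def test_boundary_fraction_flagged_extreme(self, two_dt, fast_config):
        y = mm_signal(MMParams(R=10.0, Di=1.0, De=0.6, fi=1.0), two_dt)
        fit = fit_mm(y, two_dt, np.ones(8, bool), fast_config, "discrete_di")
        assert fit.extreme
        assert fit.params.fi > 0.99

    def test_too_few_points_unfittable(self, two_dt, fast_config):
        mask = np.zeros(8, bool)
        mask[:4] = True
        assert not fit_mm(np.ones(8), two_dt, mask, fast_config, "fit_di").fittable
        mask[4] = True  # 5 points: enough for discrete (3 free), not checked for fit_di
        assert fit_mm(np.ones(8), two_dt, mask, fast_config, "discrete_di").fittable

    def test_objective_monotone_in_starts(self, two_dt, rng):
        truth = MMParams(R=7.0, Di=2.0, De=0.4, fi=0.6)
        noisy = add_rician_noise(mm_signal(truth, two_dt), 54.0, rng)
        rss = {}
        for n in (2, 5, 15):
            cfg = FitConfig(n_starts=n, seed=77)
            rss[n] = fit_mm(noisy, two_dt, np.ones(8, bool), cfg, "fit_di").rss
        assert rss[5] <= rss[2] + 1e-15
        assert rss[15] <= rss[5] + 1e-15

    def test_bit_reproducible_under_fixed_seed(self, two_dt, rng):
        noisy = add_rician_noise(
            mm_signal(MMParams(R=9.0, Di=1.5, De=0.7, fi=0.5), two_dt), 54.0, rng)
        cfg = FitConfig(n_starts=8, seed=3)
        fits = [fit_mm(noisy, two_dt, np.ones(8, bool), cfg, s, voxel_index=11)
                for s in ("discrete_di", "discrete_di")]
        assert fits[0].params == fits[1].params
        assert fits[0].rss == fits[1].rss

    def test_discrete_winner_has_best_r2(self, two_dt, rng):
        """The returned discrete-Di fit attains the max R^2 over the set."""
        noisy = add_rician_noise(
            mm_signal(MMParams(R=10.0, Di=1.5, De=0.6, fi=0.45), two_dt), 54.0, rng)
        cfg = FitConfig(n_starts=6, seed=5)
        best = fit_mm(noisy, two_dt, np.ones(8, bool), cfg, "discrete_di")
        for di in cfg.discrete_di_values:
            single = FitConfig(n_starts=6, seed=5, discrete_di_values=(di,))
            fit = fit_mm(noisy, two_dt, np.ones(8, bool), single, "discrete_di")
            assert best.r2 >= fit.r2 - 1e-12


class TestADCFit:
    def test_noiseless_self_consistency(self, single_dt, fast_config):
        y = adc_signal(ADCParams(adc=0.7), single_dt)
        fit = fit_adc(y, single_dt, fast_config)
        assert fit.params.adc == pytest.approx(0.7, abs=1e-4)

    def test_flat_signals_pin_lower_bound(self, single_dt, fast_config):
        fit = fit_adc(np.ones(3), single_dt, fast_config)
        assert fit.params.adc == pytest.approx(0.1, abs=1e-3)
        assert fit.extreme

    def test_matches_brute_force_grid(self, single_dt, fast_config):
        # independent oracle: dense grid over the SSE objective for a
        # signal that no single exponential fits exactly
        b = single_dt.b_values
        ref = single_dt.reference_index()
        y = np.array([1.0,
                      np.exp(-(b[1] - b[ref]) * 0.8e-3),
                      np.exp(-(b[2] - b[ref]) * 0.6e-3)])
        fit = fit_adc(y, single_dt, fast_config)
        grid = np.linspace(0.1, 3.0, 300001)
        x = (b - b[ref])[None, :] * 1e-3
        sse = ((np.exp(-grid[:, None] * x) - y[None, :]) ** 2).sum(axis=1)
        assert fit.params.adc == pytest.approx(grid[np.argmin(sse)], abs=1e-3)
        assert fit.rss <= sse.min() + 1e-12

    def test_reference_below_floor_unfittable(self, single_dt, fast_config):
        y = np.array([0.05, 0.5, 0.3])
        fit = fit_adc(y, single_dt, fast_config, s_noise=0.05)
        assert not fit.fittable
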
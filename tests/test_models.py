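"""Forward models: GPD eigenvalues, sphere attenuation, signal vectors."""

import numpy as np
import pytest
from scipy.optimize import bisect
from scipy.special import spherical_jn

from mmtid import (ADCParams, MMParams, PGSEMeasurement, TIDParams,
                   adc_signal, mm_signal, restricted_sphere_attenuation,
                   restricted_sphere_attenuation_waveform, sphere_gpd_roots,
                   tid_signal)
from mmtid import _kernels


class TestGPDRoots:
    def test_first_roots_match_bisection_oracle(self):
        # independent oracle: bisection on j1'(x) over known brackets
        oracle = [
            bisect(lambda x: spherical_jn(1, x, derivative=True), lo, hi, xtol=1e-12)
            for lo, hi in [(1.0, 3.0), (4.0, 7.0), (8.0, 10.0)]
        ]
        got = sphere_gpd_roots(3)
        assert got == pytest.approx(oracle, abs=1e-10)
        assert got == pytest.approx([2.08158, 5.94037, 9.20584], abs=1e-5)

    def test_strictly_increasing_with_pi_spacing(self):
        roots = sphere_gpd_roots(40)
        assert np.all(np.diff(roots) > 0)
        assert np.diff(roots)[-1] == pytest.approx(np.pi, abs=1e-3)

    def test_count_validation(self):
        with pytest.raises(ValueError):
            sphere_gpd_roots(0)


class TestSphereAttenuation:
    def test_no_gradient_is_unity(self, two_dt):
        b0 = two_dt.measurements[0]
        assert b0.G == 0
        assert restricted_sphere_attenuation(10.0, 1.0, b0) == 1.0

    def test_motional_narrowing_limit(self, two_dt):
        strongest = max(two_dt, key=lambda m: m.b)
        assert restricted_sphere_attenuation(0.1, 1.0, strongest) > 0.999

    def test_in_unit_interval_and_decreasing_in_G(self, two_dt):
        short = [m for m in two_dt if m.Delta == 9.86]
        vals = [restricted_sphere_attenuation(8.0, 1.2, m) for m in short]
        assert all(0 < v <= 1 for v in vals)
        assert np.all(np.diff(vals) <= 0)  # measurements ordered by G

    @pytest.mark.parametrize("R,Di", [(5.0, 0.5), (5.0, 2.0), (10.0, 1.0)])
    def test_kernel_matches_reference_implementation(self, two_dt, R, Di):
        """The compiled GPD evaluation is an independent coding of the
        series; the two must agree to numerical precision."""
        pref2, idx, u_delta, d_s, b1e3 = _kernels.protocol_arrays(two_dt)
        mu = sphere_gpd_roots(30)
        out = np.empty(len(two_dt))
        _kernels.mm_predict(R, Di, 0.6, 1.0, pref2, idx, u_delta, d_s, b1e3, mu, out)
        ref = np.array([restricted_sphere_attenuation(R, Di, m) for m in two_dt])
        assert out == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("R,Di", [(5.0, 1.0), (10.0, 0.5), (10.0, 2.0)])
    def test_rectangular_width_matches_trapezoid_integrals(self, two_dt, R, Di):
        """At the protocol's 0.245 ms ramps, the rectangular effective-width
        closed form agrees with the exact trapezoidal-waveform GPD to well
        under 0.5% attenuation."""
        for m in two_dt:
            if m.G == 0:
                continue
            rect = restricted_sphere_attenuation(R, Di, m)
            trap = restricted_sphere_attenuation_waveform(R, Di, m)
            assert abs(rect - trap) < 5e-3
            assert abs(rect - trap) < 5e-4  # measured headroom is ~1e-4

    def test_series_truncation_converged(self, two_dt):
        strongest = max(two_dt, key=lambda m: m.b)
        a30 = restricted_sphere_attenuation(10.0, 1.0, strongest, n_roots=30)
        a40 = restricted_sphere_attenuation(10.0, 1.0, strongest, n_roots=40)
        assert abs(a30 - a40) < 1e-8


class TestSignalVectors:
    def test_mm_zero_intracellular_fraction_is_pure_exponential(self, two_dt):
        # fi at its lower bound 0.01 is the admissible limit; compare the
        # analytic decomposition instead at an interior fi
        p = MMParams(R=10.0, Di=1.0, De=0.8, fi=0.5)
        s = mm_signal(p, two_dt)
        sphere = np.array([restricted_sphere_attenuation(10.0, 1.0, m) for m in two_dt])
        hindered = np.exp(-two_dt.b_values * 0.8e-3)
        assert s == pytest.approx(0.5 * sphere + 0.5 * hindered, abs=1e-14)

    def test_unit_signal_at_b0(self, two_dt):
        p = MMParams(R=10.0, Di=1.0, De=0.6, fi=1.0)
        s = mm_signal(p, two_dt)
        assert s[list(two_dt.b0_indices)] == pytest.approx([1.0, 1.0])

    def test_signals_decrease_with_b_at_fixed_delta(self, two_dt):
        p = MMParams(R=8.0, Di=1.5, De=0.6, fi=0.4)
        s = mm_signal(p, two_dt)
        for Delta in (9.86, 40.0):
            sel = [j for j, m in enumerate(two_dt) if m.Delta == Delta]
            sub = s[sel]  # ordered by increasing b
            assert np.all(np.diff(sub) < 0)

    def test_tid_closed_form(self, two_dt):
        s = tid_signal(TIDParams(Dprime=1.0), two_dt)
        b = two_dt.b_values
        assert s[b == 0] == pytest.approx([1.0, 1.0])
        j = int(np.argmin(np.abs(b - 1000.0)))
        assert s[j] == pytest.approx(np.exp(-b[j] * 1e-3), rel=1e-12)
        assert s[j] == pytest.approx(0.3679, abs=2e-4)

    def test_tid_identical_at_equal_b_across_delta(self, two_dt):
        s = tid_signal(TIDParams(Dprime=2.0), two_dt)
        bmap = {}
        for m, v in zip(two_dt, s):
            bmap.setdefault(round(m.b, 6), []).append(v)
        for vals in bmap.values():
            assert max(vals) == min(vals)

    def test_adc_closed_form(self, single_dt):
        s = adc_signal(ADCParams(adc=0.7), single_dt)
        b = single_dt.b_values
        ref = single_dt.reference_index()
        assert s[ref] == 1.0
        j = int(np.argmax(b))
        assert s[j] == pytest.approx(np.exp(-(b[j] - b[ref]) * 0.7e-3), rel=1e-12)
        # nominal-b sanity: exp(-0.85 * 0.7) ~ 0.5517
        assert s[j] == pytest.approx(0.5517, abs=2e-3)
        s_lo = adc_signal(ADCParams(adc=0.1), single_dt)
        assert s_lo[j] == pytest.approx(0.9185, abs=2e-3)

    def test_adc_rejects_two_diffusion_time_protocol(self, two_dt):
        with pytest.raises(ValueError, match="single-diffusion-time"):
            adc_signal(ADCParams(adc=0.7), two_dt)

    @pytest.mark.parametrize("R", [5.0, 10.0, 15.0])
    def test_restriction_lowers_long_delta_diffusivity(self, two_dt, R):
        """Apparent diffusivity from the short-Delta subset exceeds that
        from the long-Delta subset for restricted (MM) signals."""
        p = MMParams(R=R, Di=1.0, De=0.6, fi=0.41)
        s = mm_signal(p, two_dt)

        def apparent_d(Delta):
            sel = [j for j, m in enumerate(two_dt) if m.Delta == Delta and m.G > 0]
            b = two_dt.b_values[sel] * 1e-3
            y = -np.log(s[sel])
            return float(np.sum(b * y) / np.sum(b * b))

        assert apparent_d(9.86) >= apparent_d(40.0)

    def test_out_of_bounds_parameters_rejected(self, two_dt):
        with pytest.raises(ValueError, match="fit constraints"):
            mm_signal(MMParams(R=30.0, Di=1.0, De=0.6, fi=0.4), two_dt)
        with pytest.raises(ValueError, match="fit constraints"):
            tid_signal(TIDParams(Dprime=5.0), two_dt)
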
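"""Pharmacokinetic model curves: closed forms, convolution, limit branches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dcepk as d
from dcepk.phantom import TOFTS_KTRANS_GRID, TOFTS_VE_GRID


def _minutes(duration_s=600.0, dt_s=0.5):
    return np.arange(0, duration_s, dt_s) / 60.0


class TestConvolution:
    def test_zero_ktrans_gives_zero(self, aif):
        t = _minutes()
        cp = aif.cp_minutes(t)
        np.testing.assert_array_equal(d.exp_kernel_convolve(cp, t, 0.0, 1.0), 0.0)

    def test_kep_zero_reduces_to_running_integral(self, aif):
        t = _minutes(120.0)
        cp = aif.cp_minutes(t)
        out = d.exp_kernel_convolve(cp, t, 0.3, 0.0)
        expected = 0.3 * np.concatenate(
            [[0.0], np.cumsum((cp[1:] + cp[:-1]) / 2.0) * (t[1] - t[0])])
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-14)

    def test_non_uniform_grid_rejected(self, aif):
        t = np.array([0.0, 0.5, 1.5, 2.0])
        with pytest.raises(ValueError):
            d.exp_kernel_convolve(np.ones(4), t, 0.1, 1.0)

    @pytest.mark.parametrize("kt", TOFTS_KTRANS_GRID)
    @pytest.mark.parametrize("ve", TOFTS_VE_GRID)
    def test_matches_analytic_solution_on_half_second_grid(self, aif, kt, ve):
        """Discrete convolution vs closed form: <0.1% relative past 30 s."""
        t = _minutes(600.0, 0.5)
        p = d.ToftsParams(kt, ve)
        analytic = d.tofts_ct_analytic(p, aif, t)
        numeric = d.exp_kernel_convolve(aif.cp_minutes(t), t, kt, p.kep)
        late = t > 0.5  # minutes
        rel = np.abs(numeric[late] - analytic[late]) / analytic[late]
        assert rel.max() < 1e-3


class TestToftsAnalytic:
    def test_zero_at_and_before_injection(self, aif):
        p = d.ToftsParams(0.2, 0.3)
        assert d.tofts_ct_analytic(p, aif, 0.0) == 0.0
        assert d.tofts_ct_analytic(p, aif, -1.0) == 0.0

    def test_zero_ktrans(self, aif):
        t = _minutes(120.0)
        np.testing.assert_array_equal(
            d.tofts_ct_analytic(d.ToftsParams(0.0, 0.3), aif, t), 0.0)

    @given(kt=st.floats(0.01, 1.0), ve=st.floats(0.05, 1.0))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_non_negative_everywhere(self, aif, kt, ve):
        t = _minutes(300.0, 1.0)
        ct = d.tofts_ct_analytic(d.ToftsParams(kt, ve), aif, t)
        assert np.all(ct >= 0)

    def test_removable_singularity_branch_continuous(self, aif):
        # kep equal to one AIF rate vs infinitesimally off it
        kep = aif.rates[0]
        t = _minutes(300.0, 1.0)
        at = d.tofts_ct_analytic(d.ToftsParams(kep * 0.1, 0.1), aif, t)
        near = d.tofts_ct_analytic(
            d.ToftsParams((kep + 1e-10) * 0.1, 0.1), aif, t)
        np.testing.assert_allclose(at, near, rtol=1e-5)

    def test_dispatch_sampled_equals_numeric(self, aif):
        t = _minutes(120.0)
        sampled = d.SampledAIF(t * 60.0, aif.cp_minutes(t))
        p = d.ToftsParams(0.1, 0.2)
        np.testing.assert_allclose(
            d.tofts_ct(p, sampled, t),
            d.exp_kernel_convolve(aif.cp_minutes(t), t, 0.1, 0.5))


class TestExtendedTofts:
    def test_vp_zero_reduces_to_standard(self, aif):
        t = _minutes(120.0)
        ext = d.ext_tofts_ct(d.ExtToftsParams(0.1, 0.2, 0.0), aif, t)
        std = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.2), aif, t)
        np.testing.assert_allclose(ext, std)

    def test_ktrans_zero_is_pure_vascular(self, aif):
        t = _minutes(120.0)
        ext = d.ext_tofts_ct(d.ExtToftsParams(0.0, 0.2, 0.05), aif, t)
        np.testing.assert_allclose(ext, 0.05 * aif.cp_minutes(t))

    def test_volume_fraction_budget_enforced(self):
        with pytest.raises(ValueError):
            d.ExtToftsParams(0.1, 0.7, 0.4)


class TestHoffmann:
    def test_unity_ratio_at_injection(self):
        p = d.HoffmannParams(1.0, 1.0, 0.1)
        assert d.hoffmann_signal(p, 100.0, 0.0) == pytest.approx(100.0)
        assert d.hoffmann_signal(p, 100.0, -2.0) == pytest.approx(100.0)

    def test_printed_arithmetic_value(self):
        # 1 + (e^-1 - e^-0.1) / (0.1 - 1)
        p = d.HoffmannParams(1.0, 1.0, 0.1)
        expected = 1.0 + (np.exp(-1) - np.exp(-0.1)) / (0.1 - 1.0)
        assert d.hoffmann_signal(p, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert d.hoffmann_signal(p, 1.0, 1.0) == pytest.approx(1.59662, abs=1e-5)

    def test_equal_rates_limit_value(self):
        p = d.HoffmannParams(1.0, 0.5, 0.5)
        assert d.hoffmann_signal(p, 1.0, 2.0) == pytest.approx(
            1.0 + 0.5 * 2.0 * np.exp(-1.0), rel=1e-12)

    def test_limit_branch_continuous(self):
        t = np.linspace(0, 10, 101)
        at = d.hoffmann_signal(d.HoffmannParams(2.0, 0.7, 0.7), 1.0, t)
        near = d.hoffmann_signal(d.HoffmannParams(2.0, 0.7, 0.7 + 1e-9), 1.0, t)
        np.testing.assert_allclose(at, near, rtol=1e-6)

    def test_peaks_then_decays(self):
        t = np.linspace(0, 60, 2000)
        s = d.hoffmann_signal(d.HoffmannParams(1.5, 1.0, 0.05), 1.0, t)
        peak = np.argmax(s)
        assert 0 < peak < len(t) - 1
        assert np.all(np.diff(s[peak:]) <= 1e-12)


class TestLarsson:
    def test_baseline_at_injection(self, aif):
        p = d.LarssonParams(1.0, 100.0, 50.0)
        assert d.larsson_signal(p, aif.amplitudes, aif.rates, 0.0) == pytest.approx(100.0)

    def test_initial_slope_equals_sdot0(self, aif):
        """Central finite difference at t=0+ recovers the slope parameter."""
        p = d.LarssonParams(0.8, 100.0, 37.5)
        h = 1e-4
        s = d.larsson_signal(p, aif.amplitudes, aif.rates, np.array([h, 2 * h]))
        slope = (4 * s[0] - s[1] - 3 * 100.0) / (2 * h)  # one-sided 2nd order
        assert slope == pytest.approx(37.5, abs=1e-4)

    def test_single_exponential_input_direct_evaluation(self):
        kep, m, a, sdot = 0.5, 0.2, 2.0, 10.0
        t = np.linspace(0, 10, 50)
        out = d.larsson_signal(d.LarssonParams(kep, 1.0, sdot), (a,), (m,), t)
        expected = 1.0 + sdot * (np.exp(-kep * t) - np.exp(-m * t)) / (m - kep)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestReferenceRegion:
    def test_identity_when_tissue_equals_reference(self, aif):
        t = _minutes(300.0, 1.0)
        ct_r = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, t)
        p = d.RRParams(0.1, 0.1, 0.1, 0.1)
        np.testing.assert_allclose(d.rr_ct(p, ct_r, t), ct_r, atol=1e-14)

    def test_zero_ktrans_gives_zero(self, aif):
        t = _minutes(120.0)
        ct_r = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, t)
        np.testing.assert_allclose(
            d.rr_ct(d.RRParams(0.0, 0.2, 0.1, 0.1), ct_r, t), 0.0, atol=1e-14)

    def test_reconstructs_tissue_curve_from_reference(self, aif):
        """Both curves generated from one plasma input; the reference-region
        form must reproduce the tissue curve to <1% on a 1 s grid."""
        t = np.arange(0, 600, 1.0) / 60.0
        ct = d.tofts_ct_analytic(d.ToftsParams(0.25, 0.4), aif, t)
        ct_r = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, t)
        out = d.rr_ct(d.RRParams(0.25, 0.4, 0.1, 0.1), ct_r, t)
        sig = ct > 0.05 * ct.max()
        rel = np.abs(out[sig] - ct[sig]) / ct[sig]
        assert rel.max() < 0.01

    def test_linear_in_reference_curve(self, aif):
        t = _minutes(120.0)
        ct_r = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, t)
        p = d.RRParams(0.2, 0.3, 0.1, 0.1)
        np.testing.assert_allclose(d.rr_ct(p, 3.0 * ct_r, t),
                                   3.0 * d.rr_ct(p, ct_r, t), rtol=1e-12)
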
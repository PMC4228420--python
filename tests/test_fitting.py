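"""Binning, curve fitting, ROI fitting and map statistics."""

import numpy as np
import pytest

import dcepk as d
from dcepk.fitting import FitConfig, fit_curve, _model_spec


def _series_from_plane(plane_yx_t, acq):
    data = np.transpose(plane_yx_t, (1, 0, 2))[:, :, np.newaxis, :]
    nT = plane_yx_t.shape[2]
    return d.DCESeries(data, np.arange(nT) * acq.frame_interval, acq)


ACQ = d.AcquisitionParams("spgr", TR=5.0, flip_angle=30.0,
                          frame_interval=0.5, injection_frame=4)


class TestBinning:
    def test_identity_at_bin_factor_one(self):
        rng = np.random.default_rng(7)
        plane = rng.random((6, 5, 12)) + 1.0
        series = _series_from_plane(plane, ACQ)
        roi = d.ROI.full((6, 5))
        out = d.bin_signals(series, roi)
        assert out.grid_shape == (6, 5)
        for (i, j), curve in zip(out.cells, out.curves):
            np.testing.assert_array_equal(curve, plane[i, j])

    def test_cell_curve_is_mean_of_members(self):
        plane = np.zeros((4, 4, 10))
        plane[0, 0], plane[0, 1], plane[1, 0], plane[1, 1] = 1, 2, 3, 4
        series = _series_from_plane(plane, ACQ)
        out = d.bin_signals(series, d.ROI.full((4, 4), bin_factor=2))
        np.testing.assert_allclose(out.curves[0], 2.5)

    def test_masked_pixels_excluded_and_empty_cells_skipped(self):
        plane = np.ones((4, 4, 10))
        plane[0, 0] = 5.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True  # only one pixel of the first 2x2 cell
        series = _series_from_plane(plane, ACQ)
        out = d.bin_signals(series, d.ROI(0, mask, 2))
        assert len(out.cells) == 1
        np.testing.assert_allclose(out.curves[0], 5.0)

    @pytest.mark.parametrize("k,expected", [(2, 0.10), (5, 0.04)])
    def test_block_averaging_scales_noise_by_one_over_k(self, k, expected):
        """sigma = 20% i.i.d. baseline noise -> 20%/k after k x k averaging."""
        rng = np.random.default_rng(11)
        base = 100.0
        plane = base + rng.standard_normal((80, 80, 100)) * (0.2 * base)
        series = _series_from_plane(plane, ACQ)
        out = d.bin_signals(series, d.ROI.full((80, 80), bin_factor=k))
        resid = out.curves - base
        assert resid.size >= 2e4
        assert resid.std() / base == pytest.approx(expected, rel=0.02)


class TestFitCurve:
    def test_noise_free_hoffmann_recovery(self):
        t = np.linspace(-0.5, 15, 400)
        truth = d.HoffmannParams(1.0, 1.0, 0.1)
        y = d.hoffmann_signal(truth, 100.0, t)
        names, init, lo, hi, _, factory = _model_spec("hoffmann")
        res = fit_curve(factory(100.0), t, y, names, init, lo, hi)
        assert res.converged
        assert res.params["A_H"] == pytest.approx(1.0, rel=1e-6)
        assert res.params["kep"] == pytest.approx(1.0, rel=1e-6)
        assert res.params["kel"] == pytest.approx(0.1, rel=1e-6)
        assert res.stderr is not None

    def test_flat_curve_reported_degenerate(self):
        t = np.linspace(0, 10, 50)
        names, init, lo, hi, _, factory = _model_spec("hoffmann")
        res = fit_curve(factory(100.0), t, np.full(50, 100.0), names, init, lo, hi)
        assert not res.converged
        assert res.message == "degenerate"
        assert res.stderr is None

    def test_nan_frames_dropped(self, aif):
        t = np.linspace(0, 10, 80)
        y = d.tofts_ct_analytic(d.ToftsParams(0.2, 0.3), aif, t)
        y[::7] = np.nan
        names, init, lo, hi, _, factory = _model_spec("tofts", aif=aif)
        res = fit_curve(factory(1.0), t, y, names, init, lo, hi)
        assert res.converged
        assert res.params["Ktrans"] == pytest.approx(0.2, rel=1e-4)

    def test_too_few_observations_raises(self, aif):
        names, init, lo, hi, _, factory = _model_spec("tofts", aif=aif)
        with pytest.raises(ValueError):
            fit_curve(factory(1.0), np.array([0.0, 1.0]),
                      np.array([0.0, np.nan]), names, init, lo, hi)

    def test_noise_free_larsson_recovery(self, aif):
        t = np.linspace(-0.5, 10, 300)
        y = d.larsson_signal(d.LarssonParams(0.8, 100.0, 40.0),
                             aif.amplitudes, aif.rates, t)
        names, init, lo, hi, _, factory = _model_spec("larsson", aif=aif)
        res = fit_curve(factory(100.0), t, y, names, init, lo, hi)
        assert res.converged
        assert res.params["kep"] == pytest.approx(0.8, rel=1e-5)
        assert res.params["Sdot0"] == pytest.approx(40.0, rel=1e-5)


class TestFitROI:
    def test_missing_aif_block_named(self, tofts_phantom):
        _, series, truth = tofts_phantom
        roi = d.ROI(0, truth.tissue_mask, 10)
        with pytest.raises(d.ConfigurationError, match=r"\[aif\]"):
            d.fit_roi(series, roi, "tofts",
                      relax=d.RelaxationParams(4.5, 1000.0))

    def test_missing_rr_block_named(self, tofts_phantom):
        _, series, truth = tofts_phantom
        roi = d.ROI(0, truth.tissue_mask, 10)
        with pytest.raises(d.ConfigurationError, match=r"\[rr\]"):
            d.fit_roi(series, roi, "rr",
                      relax=d.RelaxationParams(4.5, 1000.0))

    def test_binned_fit_equals_single_pixel_fit_on_homogeneous_patch(
            self, tofts_phantom):
        """Averaging a noise-free homogeneous patch changes nothing."""
        spec, series, truth = tofts_phantom
        relax = d.RelaxationParams(spec.r1, spec.T10_tissue)
        mask = np.zeros_like(truth.tissue_mask)
        mask[:10, :10] = True  # one patch
        coarse = d.fit_roi(series, d.ROI(0, mask, 10), "tofts",
                           relax=relax, aif=spec.aif)
        pix = np.zeros_like(mask)
        pix[3, 4] = True
        fine = d.fit_roi(series, d.ROI(0, pix, 1), "tofts",
                         relax=relax, aif=spec.aif)
        for n in ("Ktrans", "ve"):
            a = coarse[n][coarse.converged][0]
            b = fine[n][fine.converged][0]
            assert a == pytest.approx(b, abs=1e-9)

    def test_repeat_fit_bit_identical(self, tofts_phantom):
        spec, series, truth = tofts_phantom
        relax = d.RelaxationParams(spec.r1, spec.T10_tissue)
        mask = np.zeros_like(truth.tissue_mask)
        mask[:10, :30] = True
        roi = d.ROI(0, mask, 10)
        a = d.fit_roi(series, roi, "tofts", relax=relax, aif=spec.aif)
        b = d.fit_roi(series, roi, "tofts", relax=relax, aif=spec.aif)
        for n in a.param_names:
            np.testing.assert_array_equal(a[n], b[n])

    def test_reference_region_roi_pipeline_recovers_truth(self, aif):
        """Synthesize tissue + reference tissue from one plasma input and
        recover the tissue constants with the reference-region model."""
        acq = d.AcquisitionParams("spin_echo", TR=200.0, frame_interval=2.0,
                                  injection_frame=10)
        relax = d.RelaxationParams(4.5, 1000.0)
        nT = 200
        t_min = (np.arange(nT) * 2.0 - 20.0) / 60.0
        ct_tis = d.tofts_ct_analytic(d.ToftsParams(0.25, 0.4), aif, t_min)
        ct_ref = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, t_min)
        S0eq = 1000.0
        plane = np.empty((2, 2, nT))
        plane[:, :, :] = d.spin_echo_signal(
            S0eq, d.t1_from_concentration(ct_tis, relax), 200.0)
        series = _series_from_plane(plane, acq)
        pm = d.fit_roi(series, d.ROI.full((2, 2)), "rr", relax=relax,
                       rr_constants=(0.1, 0.1), rr_reference=ct_ref)
        assert pm.converged.all()
        np.testing.assert_allclose(pm["Ktrans"], 0.25, rtol=2e-3)
        np.testing.assert_allclose(pm["ve"], 0.4, rtol=2e-3)


class TestStatistics:
    def test_constant_map_sd_zero(self, tofts_phantom):
        spec, series, truth = tofts_phantom
        mask = np.zeros_like(truth.tissue_mask)
        mask[:10, :10] = True
        pm = d.fit_roi(series, d.ROI(0, mask, 5), "tofts",
                       relax=d.RelaxationParams(spec.r1, spec.T10_tissue),
                       aif=spec.aif)
        stats = d.roi_statistics(pm)
        assert stats["Ktrans"]["n"] == 4
        assert stats["Ktrans"]["sd"] == pytest.approx(0.0, abs=1e-8)
        assert stats["Ktrans"]["mean"] == pytest.approx(0.01, rel=1e-6)

    def test_single_cell_sd_zero_by_convention(self, tofts_phantom):
        spec, series, truth = tofts_phantom
        mask = np.zeros_like(truth.tissue_mask)
        mask[0, 0] = True
        pm = d.fit_roi(series, d.ROI(0, mask, 1), "tofts",
                       relax=d.RelaxationParams(spec.r1, spec.T10_tissue),
                       aif=spec.aif)
        stats = d.roi_statistics(pm)
        assert stats["ve"]["n"] == 1 and stats["ve"]["sd"] == 0.0
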
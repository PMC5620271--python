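"""SPGR relaxometry, concentration conversion and extended-Tofts fitting."""

import numpy as np
import pytest

from ivimdce import FitError, ValidationError
from ivimdce.aif import Aif
from ivimdce.dce import (
    ToftsParams,
    exp_convolve,
    extended_tofts_forward,
    fit_dce_map,
    fit_extended_tofts,
    signal_to_concentration,
    spgr_signal,
    vfa_t1,
)
from ivimdce.phantom import generate_phantom
from ivimdce.simulate import simulate_dce


class TestSpgr:
    def test_saturation_limit_long_T1(self):
        assert spgr_signal(1000.0, 1e9 * 4.8, 4.8, 15.0) < 1e-3 * 1000.0

    def test_full_relaxation_limit(self):
        # TR >> T1: signal reaches M0*sin(alpha)
        s = spgr_signal(100.0, 10.0, 1e5, 30.0)
        assert s == pytest.approx(100.0 * np.sin(np.deg2rad(30.0)), rel=1e-9)

    def test_matches_closed_form(self):
        a = np.deg2rad(15.0)
        e1 = np.exp(-4.8 / 1000.0)
        expected = 1000.0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert spgr_signal(1000.0, 1000.0, 4.8, 15.0) == pytest.approx(expected, rel=1e-14)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValidationError):
            spgr_signal(1.0, -5.0, 4.8, 15.0)
        with pytest.raises(ValidationError):
            spgr_signal(1.0, 1000.0, 4.8, 95.0)


class TestVfaT1:
    @pytest.mark.parametrize("t1,m0", [(1000.0, 1000.0), (800.0, 500.0),
                                       (1400.0, 2000.0)])
    def test_exact_two_point_inversion(self, t1, m0):
        s5 = spgr_signal(m0, t1, 4.8, 5.0)
        s15 = spgr_signal(m0, t1, 4.8, 15.0)
        fit = vfa_t1(s5, s15, 4.8, 5.0, 15.0)
        assert fit.valid
        assert fit.T10 == pytest.approx(t1, abs=1e-6)
        assert fit.M0 == pytest.approx(m0, rel=1e-9)

    def test_inconsistent_signal_pair_flags_invalid(self):
        # a pre-contrast signal far below the dynamic one pushes the
        # two-point slope E1 above 1: no T1 reproduces the pair
        fit = vfa_t1(50.0, 200.0, 4.8, 5.0, 15.0)
        assert not fit.valid
        assert np.isnan(fit.T10)

    def test_equal_signals_at_both_angles_have_a_crossing_T1(self):
        # with 5 deg / 15 deg and TR=4.8 ms equal signals are attainable
        # (the Ernst curve crossing); the solved T1 must reproduce them
        fit = vfa_t1(50.0, 50.0, 4.8, 5.0, 15.0)
        assert fit.valid
        assert spgr_signal(fit.M0, fit.T10, 4.8, 5.0) == pytest.approx(50.0)
        assert spgr_signal(fit.M0, fit.T10, 4.8, 15.0) == pytest.approx(50.0)

    def test_array_form_matches_scalar(self):
        s5 = spgr_signal(np.array([500.0, 1000.0]), np.array([800.0, 1200.0]), 4.8, 5.0)
        s15 = spgr_signal(np.array([500.0, 1000.0]), np.array([800.0, 1200.0]), 4.8, 15.0)
        t10, m0, valid = vfa_t1(s5, s15, 4.8, 5.0, 15.0)
        assert valid.all()
        np.testing.assert_allclose(t10, [800.0, 1200.0], rtol=1e-9)


class TestConcentration:
    def _fit(self, t1=1000.0, m0=1000.0):
        from ivimdce.dce import T1Fit

        return T1Fit(T10=t1, M0=m0)

    def test_constant_baseline_series_gives_zero_ct(self):
        t1 = self._fit()
        s = np.full(65, spgr_signal(1000.0, 1000.0, 4.8, 15.0))
        ct, ok, valid = signal_to_concentration(s, t1, 4.8, 15.0, 3.5)
        assert valid and ok.all()
        np.testing.assert_allclose(ct, 0.0, atol=1e-12)

    def test_round_trip_recovers_known_concentration(self):
        # synthesize the signal from a known Ct and invert it back
        t10, m0, r1 = 1200.0, 800.0, 3.5
        ct_true = np.concatenate([np.zeros(7), 0.5 * (1 - np.exp(-np.arange(58) / 10))])
        r1_t = 1000.0 / t10 + r1 * ct_true
        s = spgr_signal(m0, 1000.0 / r1_t, 4.8, 15.0)
        ct, _, valid = signal_to_concentration(s, self._fit(t10, m0), 4.8, 15.0, r1)
        assert valid
        np.testing.assert_allclose(ct, ct_true, atol=0.005 * ct_true.max())

    def test_doubling_r1_halves_concentration(self):
        t10, m0 = 1000.0, 1000.0
        r1_t = 1000.0 / t10 + 3.5 * np.concatenate([np.zeros(7), np.full(20, 0.3)])
        s = spgr_signal(m0, 1000.0 / r1_t, 4.8, 15.0)
        ct1, _, _ = signal_to_concentration(s, self._fit(t10, m0), 4.8, 15.0, 3.5)
        ct2, _, _ = signal_to_concentration(s, self._fit(t10, m0), 4.8, 15.0, 7.0)
        np.testing.assert_allclose(ct2, ct1 / 2, atol=1e-12)

    def test_uninvertible_points_invalidate_voxel_past_20pct(self):
        t1 = self._fit()
        s = np.full(20, spgr_signal(1000.0, 1000.0, 4.8, 15.0))
        s[5:11] = 1e9  # 30% of points beyond any physical signal
        ct, ok, valid = signal_to_concentration(s, t1, 4.8, 15.0, 3.5)
        assert not valid
        assert not ok[5:11].any()


class TestToftsForward:
    def _boxcar_aif(self, n=200, dt=1.0, height=1.0, width=60.0):
        t = np.arange(n) * dt
        cp = np.where(t <= width, height, 0.0)
        return Aif(times=t, cp=cp)

    def test_pure_plasma_term_when_ktrans_zero(self, aif):
        p = ToftsParams(Ktrans=0.0, kep=0.0, ve=0.5, vp=0.1)
        np.testing.assert_allclose(extended_tofts_forward(p, aif),
                                   0.1 * aif.cp, rtol=1e-14)

    def test_boxcar_convolution_matches_closed_form(self):
        """During a unit boxcar input, Ct(t) = ve(1 - exp(-kep t)) for
        vp=0 (uptake phase closed form)."""
        aif = self._boxcar_aif()
        ktrans, ve = 0.6, 0.4  # kep = 1.5/min
        kep_s = ktrans / ve / 60.0
        p = ToftsParams(Ktrans=ktrans, kep=ktrans / ve, ve=ve, vp=0.0)
        ct = extended_tofts_forward(p, aif)
        inside = aif.times <= 60
        expected = ve * (1 - np.exp(-kep_s * aif.times[inside]))
        np.testing.assert_allclose(ct[inside], expected,
                                   rtol=1e-3, atol=1e-6)

    def test_exponential_aif_matches_closed_form(self):
        """Cp = e^{-at}: the convolution with e^{-kep t} has the exact
        two-exponential difference form."""
        t = np.arange(300) * 1.0
        a = 1 / 50.0
        cp = np.exp(-a * t)
        kep_s = 2.4 / 60.0
        integ = exp_convolve(cp, t, kep_s)
        expected = (np.exp(-a * t) - np.exp(-kep_s * t)) / (kep_s - a)
        np.testing.assert_allclose(integ[5:], expected[5:], rtol=1e-3)

    def test_null_model_gives_zero(self, aif):
        p = ToftsParams(Ktrans=0.0, kep=0.0, ve=0.0, vp=0.0)
        np.testing.assert_allclose(extended_tofts_forward(p, aif), 0.0)

    def test_causality_zero_until_bolus(self, aif, dce_scheme):
        p = ToftsParams(Ktrans=0.5, kep=1.0, ve=0.5, vp=0.05)
        ct = extended_tofts_forward(p, aif)
        assert np.all(ct[: dce_scheme.injection_index] == 0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValidationError, match="times"):
            exp_convolve(np.ones(3), np.array([0.0, 2.0, 1.0]), 0.01)


class TestToftsFit:
    def test_recovers_low_stage_triple(self, aif):
        p = ToftsParams(Ktrans=0.645, kep=0.645 / 0.555, ve=0.555, vp=0.088)
        ct = extended_tofts_forward(p, aif)
        fit = fit_extended_tofts(ct, aif)
        assert fit.converged
        assert abs(fit.Ktrans / 0.645 - 1) < 0.01
        assert abs(fit.ve / 0.555 - 1) < 0.01
        assert abs(fit.vp / 0.088 - 1) < 0.01

    def test_zero_curve_excluded_as_unphysiological(self, aif):
        fit = fit_extended_tofts(np.zeros_like(aif.cp), aif)
        assert not fit.converged

    def test_kep_equals_ktrans_over_ve(self, aif):
        p = ToftsParams(Ktrans=0.4, kep=0.4 / 0.3, ve=0.3, vp=0.02)
        fit = fit_extended_tofts(extended_tofts_forward(p, aif), aif)
        assert abs(fit.kep * fit.ve - fit.Ktrans) <= 1e-6 * fit.Ktrans

    def test_matches_exhaustive_grid_search(self, aif):
        """Brute-force oracle over (Ktrans, ve, vp) on random voxels:
        the fit must dominate every grid point in RSS (global optimum)
        and sit next to the grid argmin — within 1.5 cells per axis,
        the grid's own localization limit along the Ktrans-ve valley."""
        from ivimdce.dce import exp_convolve

        rng = np.random.default_rng(21)
        kt_g = np.linspace(0.05, 1.5, 59)
        ve_g = np.linspace(0.05, 0.95, 61)
        vp_g = np.linspace(0.0, 0.3, 31)
        for _ in range(5):
            kt = rng.uniform(0.2, 1.2)
            ve = rng.uniform(0.2, 0.9)
            vp = rng.uniform(0.01, 0.25)
            p = ToftsParams(Ktrans=kt, kep=kt / ve, ve=ve, vp=vp)
            ct = extended_tofts_forward(p, aif)
            fit = fit_extended_tofts(ct, aif)
            best, arg = np.inf, None
            for kg in kt_g:
                for vg in ve_g:
                    base = (kg / 60.0) * exp_convolve(
                        aif.cp, aif.times, (kg / vg) / 60.0)
                    rss = ((base[None, :] + vp_g[:, None] * aif.cp[None, :]
                            - ct[None, :]) ** 2).sum(axis=1)
                    j = int(np.argmin(rss))
                    if rss[j] < best:
                        best, arg = float(rss[j]), (kg, vg, vp_g[j])
            assert fit.rss <= best + 1e-12
            assert abs(fit.Ktrans - arg[0]) <= 1.5 * (kt_g[1] - kt_g[0])
            assert abs(fit.ve - arg[1]) <= 1.5 * (ve_g[1] - ve_g[0])
            assert abs(fit.vp - arg[2]) <= 1.5 * (vp_g[1] - vp_g[0])

    def test_aif_scaling_leaves_parameters_unchanged(self, aif):
        """Scaling Cp and Ct together is a pure unit change."""
        p = ToftsParams(Ktrans=0.5, kep=1.0, ve=0.5, vp=0.06)
        ct = extended_tofts_forward(p, aif)
        scaled = Aif(times=aif.times, cp=3.0 * aif.cp)
        fit = fit_extended_tofts(3.0 * ct, scaled)
        assert abs(fit.Ktrans / 0.5 - 1) < 1e-6
        assert abs(fit.ve / 0.5 - 1) < 1e-6
        assert abs(fit.vp / 0.06 - 1) < 1e-6


class TestDceMap:
    def test_noiseless_homogeneous_phantom_recovered(self, dce_scheme, aif):
        truth = generate_phantom(shape=(4, 4, 3), tumor_cv=0.0,
                                 semi_axes=(99, 99, 99), seed=0)
        series = simulate_dce(truth, dce_scheme, aif, 0.0)
        maps = fit_dce_map(series.data, series.pre_volume, truth.roi_mask,
                           aif, dce_scheme)
        assert maps.valid_mask.all()
        np.testing.assert_allclose(maps.Ktrans_map, truth.Ktrans_map, rtol=1e-6)
        np.testing.assert_allclose(maps.ve_map, truth.ve_map, rtol=1e-6)
        np.testing.assert_allclose(maps.vp_map, truth.vp_map, rtol=1e-5)

    def test_zero_enhancement_voxels_excluded(self, dce_scheme, aif):
        truth = generate_phantom(tumor_params={"Ktrans": 0.0, "vp": 0.0},
                                 tumor_cv=0.0, shape=(4, 4, 3),
                                 semi_axes=(99, 99, 99), seed=0)
        series = simulate_dce(truth, dce_scheme, aif, 0.0)
        maps = fit_dce_map(series.data, series.pre_volume, truth.roi_mask,
                           aif, dce_scheme)
        assert not maps.valid_mask.any()

    def test_empty_roi_is_an_error(self, dce_scheme, aif, flat_phantom):
        series = simulate_dce(flat_phantom, dce_scheme, aif, 0.0)
        with pytest.raises(FitError, match="empty ROI"):
            fit_dce_map(series.data, series.pre_volume,
                        np.zeros(flat_phantom.shape, dtype=bool), aif, dce_scheme)
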
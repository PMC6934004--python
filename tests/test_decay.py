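import dataclasses

import numpy as np
import pytest

from aquamap.acquisition import AcqProtocol, GAMMA_PROTON, steady_state_factor
from aquamap.decay import (DEPHASING_LIMIT, estimate_background_gradients,
                           fit_monoexponential, fit_monoexponential_nls,
                           fit_volume, select_echoes, sinc_corrected_fit)
from aquamap.io import EchoSeriesVolume
from aquamap.phantom import (GradientSpec, PhantomSpec, make_brain_phantom,
                             simulate_echo_series)
from aquamap._utils import sinc, wrap_phase

from conftest import interior

TE32 = tuple(3.87 + 4.08 * i for i in range(32))


def constructed_series(gz=0.0, phi0_slope=0.0, shape=(8, 8, 8), t2star_ms=80.0,
                       n_echoes=8):
    """Series with linear-in-z phase phi = phi0(z) + gamma * gz * z * TE and
    spatially uniform exponential magnitude (all echoes qualify)."""
    protocol = dataclasses.replace(AcqProtocol.default_3t(n_echoes),
                                   voxel_mm=(2.0, 2.0, 1.5))
    te = protocol.te_s
    z = np.arange(shape[2]) * 1.5e-3  # m
    phase = (phi0_slope * np.arange(shape[2])[None, None, :, None]
             + GAMMA_PROTON * gz * z[None, None, :, None] * te)
    phase = np.broadcast_to(phase, shape + (n_echoes,))
    mag = np.broadcast_to(np.exp(-te / (t2star_ms * 1e-3)), shape + (n_echoes,))
    return EchoSeriesVolume(magnitude=np.array(mag), phase=wrap_phase(phase),
                            protocol=protocol)


class TestBackgroundGradients:
    def test_constructed_linear_phase_exact(self):
        series = constructed_series(gz=50e-6)
        g = estimate_background_gradients(series)
        inner = np.s_[:-1, :-1, :-1]
        np.testing.assert_allclose(g.gz[inner], 50e-6, rtol=1e-10)
        np.testing.assert_allclose(g.gx[inner], 0.0, atol=1e-18)
        np.testing.assert_allclose(g.gy[inner], 0.0, atol=1e-18)

    def test_uniform_phase_gives_zero(self):
        series = constructed_series(gz=0.0)
        g = estimate_background_gradients(series)
        for arr in (g.gx, g.gy, g.gz):
            np.testing.assert_allclose(arr, 0.0, atol=1e-18)

    def test_edge_voxels_copy_inner_neighbor(self):
        series = constructed_series(gz=50e-6)
        g = estimate_background_gradients(series)
        np.testing.assert_allclose(g.gz[:, :, -1], g.gz[:, :, -2], rtol=1e-12)

    def test_phi0_subtraction_vs_literal_contamination(self):
        gz, a = 30e-6, 0.05  # rad per z-step offset field
        series = constructed_series(gz=gz, phi0_slope=a)
        g_sub = estimate_background_gradients(series, subtract_phi0=True)
        g_lit = estimate_background_gradients(series, subtract_phi0=False)
        inner = np.s_[:-1, :-1, :-1]
        np.testing.assert_allclose(g_sub.gz[inner], gz, rtol=1e-10)
        # literal Eq-5 bias: mean over echoes of d(phi0)/(gamma*dz*TE_n)
        te = series.protocol.te_s
        contamination = np.mean(a / (GAMMA_PROTON * 1.5e-3 * te))
        np.testing.assert_allclose(g_lit.gz[inner], gz + contamination, rtol=1e-10)

    def test_half_intensity_echo_qualification(self):
        series = constructed_series(gz=50e-6, t2star_ms=20.0, n_echoes=16)
        te = np.asarray(series.protocol.te_ms)
        qual_expected = np.exp(-te / 20.0) >= 0.5 * np.exp(-te[0] / 20.0)
        g = estimate_background_gradients(series)
        assert np.all(g.n_echoes_used == qual_expected[1:].sum())  # echo 1 dropped

    def test_no_qualifying_echo_flags_voxel(self):
        series = constructed_series(gz=50e-6, n_echoes=4)
        mag = series.magnitude.copy()
        mag[2, 2, 2, 1:] = 0.0  # only first echo retains signal
        series = EchoSeriesVolume(magnitude=mag, phase=series.phase,
                                  protocol=series.protocol)
        g = estimate_background_gradients(series)
        assert not g.valid[2, 2, 2]
        assert g.gz[2, 2, 2] == 0.0

    def test_error_decreases_with_echo_count(self):
        rng = np.random.default_rng(7)
        errs = []
        for n_echoes in (8, 32):
            series = constructed_series(gz=50e-6, n_echoes=n_echoes,
                                        t2star_ms=1e6)
            noisy = wrap_phase(series.phase
                               + rng.normal(0, 0.05, series.phase.shape))
            s = EchoSeriesVolume(magnitude=series.magnitude, phase=noisy,
                                 protocol=series.protocol)
            g = estimate_background_gradients(s)
            errs.append(np.std(g.gz[:-1, :-1, :-1] - 50e-6))
        assert errs[1] < 0.75 * errs[0]


class TestSelectEchoes:
    def test_zero_gradient_selects_all(self):
        series = constructed_series(n_echoes=32)
        counts = select_echoes(series, np.zeros(series.shape))
        assert np.all(counts == 32)

    def test_threshold_between_echo_12_and_13(self):
        series = constructed_series(n_echoes=32)
        te = np.asarray(TE32) * 1e-3
        te_thr = 0.5 * (te[11] + te[12])
        gz = DEPHASING_LIMIT / (GAMMA_PROTON * 1.5e-3 * te_thr)
        # direct inequality oracle
        assert (GAMMA_PROTON * gz * 1.5e-3 * te <= DEPHASING_LIMIT).sum() == 12
        counts = select_echoes(series, np.full(series.shape, gz))
        assert np.all(counts == 12)

    def test_huge_gradient_selects_none(self):
        series = constructed_series(n_echoes=8)
        counts = select_echoes(series, np.full(series.shape, 1.0))
        assert np.all(counts == 0)

    def test_monotone_in_gradient_magnitude(self):
        series = constructed_series(n_echoes=32)
        shape = series.shape
        prev = np.full(shape, 33)
        for gz in (0, 2e-5, 5e-5, 1e-4, 3e-4, 1e-3):
            counts = select_echoes(series, np.full(shape, gz))
            assert np.all(counts <= prev)
            prev = counts

    def test_max_echoes_cap(self):
        series = constructed_series(n_echoes=32)
        counts = select_echoes(series, np.zeros(series.shape), max_echoes=12)
        assert np.all(counts == 12)


class TestFitMonoexponential:
    def test_noiseless_exact(self):
        te = np.asarray(TE32)
        s0, t2, rss = fit_monoexponential(te, 80.0 * np.exp(-te / 50.0))
        assert s0 == pytest.approx(80.0, rel=1e-12)
        assert t2 == pytest.approx(50.0, rel=1e-12)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_flat_signal_capped_at_2000ms(self):
        te = np.asarray(TE32)
        s0, t2, rss = fit_monoexponential(te, np.full(32, 7.0))
        assert t2 == 2000.0
        assert np.isfinite(s0) and s0 > 0

    def test_too_few_positive_signals_invalid(self):
        s0, t2, rss = fit_monoexponential([1.0, 2.0, 3.0], [5.0, 0.0, 0.0])
        assert np.isnan(s0) and np.isnan(t2)

    def test_monte_carlo_median_within_1pct_at_snr97(self):
        te = np.asarray(TE32)
        s_true = np.exp(-te / 50.0)
        sd = s_true[0] / 97.0
        rng = np.random.default_rng(11)
        n = 2000
        noisy = np.abs(s_true + sd * (rng.standard_normal((n, 32))
                                      + 1j * rng.standard_normal((n, 32))))
        t2s = np.array([fit_monoexponential(te, row)[1] for row in noisy])
        assert abs(np.median(t2s) - 50.0) / 50.0 < 0.01
        # nonlinear least-squares reference on a subsample agrees
        t2_nls = np.array([fit_monoexponential_nls(te, row)[1]
                           for row in noisy[:200]])
        assert abs(np.median(t2_nls) - np.median(t2s[:200])) / 50.0 < 0.01

    def test_nls_agrees_on_noiseless(self):
        te = np.asarray(TE32)
        sig = 12.0 * np.exp(-te / 70.0)
        s0l, t2l, _ = fit_monoexponential(te, sig)
        s0n, t2n = fit_monoexponential_nls(te, sig)
        assert abs(s0l - s0n) / s0n < 1e-3
        assert abs(t2l - t2n) / t2n < 1e-3

    def test_csf_benefits_from_many_echoes(self):
        # slow CSF decay: full 32-echo fit beats a 12-echo subset by > 2x
        te = np.asarray(TE32)
        s_true = np.exp(-te / 200.0)
        sd = s_true[0] / 97.0
        rng = np.random.default_rng(3)
        n = 1500
        noisy = np.abs(s_true + sd * (rng.standard_normal((n, 32))
                                      + 1j * rng.standard_normal((n, 32))))
        from aquamap.decay import _fit_loglinear

        inc_all = np.ones_like(noisy, bool)
        inc12 = np.zeros_like(noisy, bool)
        inc12[:, :12] = True
        t2_all = _fit_loglinear(te, noisy, inc_all)[1]
        t2_sub = _fit_loglinear(te, noisy, inc12)[1]
        rmse_all = np.sqrt(np.mean((t2_all - 200.0) ** 2))
        rmse_sub = np.sqrt(np.mean((t2_sub - 200.0) ** 2))
        assert rmse_all < 0.5 * rmse_sub


class TestSincCorrectedFit:
    def test_zero_gradient_identical_to_plain(self):
        te = np.asarray(TE32)
        sig = 9.0 * np.exp(-te / 45.0)
        assert sinc_corrected_fit(te, sig, 0.0, 1.5) == fit_monoexponential(te, sig)

    def test_forward_inverse_round_trip(self):
        te = np.asarray(TE32)
        gz, dz = 8e-5, 1.5
        factor = sinc(0.5 * GAMMA_PROTON * gz * dz * 1e-3 * te * 1e-3)
        sig = 9.0 * np.exp(-te / 45.0) * factor
        s0, t2, _ = sinc_corrected_fit(te, sig, gz, dz)
        assert s0 == pytest.approx(9.0, rel=1e-10)
        assert t2 == pytest.approx(45.0, rel=1e-10)


class TestFitVolume:
    def test_noiseless_forward_inverse_identity(self, brain_truth,
                                                noiseless_series):
        decay = fit_volume(noiseless_series)
        t = brain_truth
        brain = t.label_map > 0
        assert np.all(decay.valid[brain])
        m0 = t.water_map / 100.0 * 1000.0
        f = steady_state_factor(10.0, t.t1_map, 72.0)
        s0_true = m0 * f * np.sin(np.deg2rad(72.0))
        assert np.max(np.abs(decay.s0[brain] - s0_true[brain])
                      / s0_true[brain]) < 1e-6
        assert np.max(np.abs(decay.t2star_ms[brain] - t.t2star_map[brain])
                      / t.t2star_map[brain]) < 1e-6
        wm, gm = t.class_mask("WM"), t.class_mask("GM")
        assert decay.t2star_ms[wm].mean() == pytest.approx(50.0, abs=1e-9)
        assert decay.t2star_ms[gm].mean() == pytest.approx(55.7, abs=1e-9)

    def test_r2star_t2star_product(self, noiseless_series):
        decay = fit_volume(noiseless_series)
        v = decay.valid
        np.testing.assert_allclose(decay.r2star[v] * decay.t2star_ms[v],
                                   1000.0, rtol=1e-12)

    def test_vectorized_matches_scalar_path(self, noiseless_series):
        decay = fit_volume(noiseless_series, correct_gradients=False)
        te = np.asarray(noiseless_series.protocol.te_ms)
        rng = np.random.default_rng(0)
        valid_idx = np.argwhere(decay.valid)
        for i, j, k in valid_idx[rng.choice(len(valid_idx), 10, replace=False)]:
            s0, t2, rss = fit_monoexponential(
                te, noiseless_series.magnitude[i, j, k])
            assert decay.s0[i, j, k] == pytest.approx(s0, rel=1e-12)
            assert decay.t2star_ms[i, j, k] == pytest.approx(t2, rel=1e-12)

    def test_gradient_correction_recovers_truth_in_hotspot(self, protocol32):
        spec = PhantomSpec(kind="brain",
                           b0_gradient_z=GradientSpec("hotspot", value=1e-4))
        truth = make_brain_phantom(spec)
        series = simulate_echo_series(truth, protocol32, noise_sd=0.0)
        decay = fit_volume(series, correct_gradients=True)
        decay_plain = fit_volume(series, correct_gradients=False)
        sel = interior(truth.label_map > 0) & decay.valid
        err_corr = np.median(np.abs(decay.s0[sel] / decay_plain.s0[sel] - 1.0))
        # corrected fit restores truth where the plain fit is biased
        m0 = truth.water_map / 100.0 * 1000.0
        f = steady_state_factor(10.0, truth.t1_map, 72.0)
        s0_true = m0 * f * np.sin(np.deg2rad(72.0))
        assert np.max(np.abs(decay.s0[sel] - s0_true[sel]) / s0_true[sel]) < 1e-6
        hot = sel & (truth.gz_map > 5e-5)
        assert np.any(hot)
        assert np.max(np.abs(decay_plain.s0[hot] - s0_true[hot])
                      / s0_true[hot]) > 0.01

    def test_wm_t2star_spread_matches_monte_carlo_prediction(self, brain_truth,
                                                             protocol32):
        from aquamap.phantom import noise_sd_for_snr

        sd = noise_sd_for_snr(brain_truth, protocol32, 97.0)
        series = simulate_echo_series(brain_truth, protocol32, noise_sd=sd,
                                      seed=9)
        decay = fit_volume(series, correct_gradients=False)
        wm = brain_truth.class_mask("WM")
        observed = decay.t2star_ms[wm & decay.valid].std()
        # scalar Monte-Carlo oracle at the same voxel SNR
        te = np.asarray(protocol32.te_ms)
        s_true = 690.0 * steady_state_factor(10.0, 0.9, 72.0) \
            * np.sin(np.deg2rad(72.0)) * np.exp(-te / 50.0)
        rng = np.random.default_rng(1)
        noisy = np.abs(s_true + sd * 1000.0
                       * (rng.standard_normal((2000, 32))
                          + 1j * rng.standard_normal((2000, 32))))
        from aquamap.decay import _fit_loglinear

        t2_mc = _fit_loglinear(te, noisy, np.ones_like(noisy, bool))[1]
        assert observed == pytest.approx(t2_mc.std(), rel=0.2)

    def test_deterministic(self, noiseless_series):
        a = fit_volume(noiseless_series)
        b = fit_volume(noiseless_series)
        assert np.array_equal(a.s0, b.s0, equal_nan=True)
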
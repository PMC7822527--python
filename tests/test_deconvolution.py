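import math

import numpy as np
import pytest
from scipy.signal import find_peaks

import dyadeda as dd
from dyadeda.deconvolution import SCRKernel, detrend_tonic, reconvolve
from dyadeda.errors import DegenerateSignalError, ParameterError

from conftest import make_trace


class TestBatemanKernel:
    @pytest.mark.parametrize("tr,td", [(0.75, 2.0), (0.5, 3.0), (1.0, 4.0)])
    def test_peak_time_matches_closed_form(self, tr, td):
        fs = 128.0
        k = dd.bateman_kernel(tr, td, fs=fs)
        analytic = math.log(td / tr) * (tr * td) / (td - tr)
        assert abs(np.argmax(k.samples) / fs - analytic) <= 1.0 / fs

    def test_unit_sum_and_nonnegative(self):
        k = dd.bateman_kernel(0.75, 2.0, fs=128.0)
        assert k.samples.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(k.samples >= 0)

    def test_known_peak_value(self):
        # tau_rise=0.75, tau_decay=2.0: peak at ln(2/0.75)*1.5/1.25 ~ 1.177 s
        k = dd.bateman_kernel(0.75, 2.0, fs=128.0)
        assert k.peak_time == pytest.approx(1.177, abs=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ParameterError):
            dd.bateman_kernel(2.0, 0.75, fs=128.0)
        with pytest.raises(ParameterError):
            dd.bateman_kernel(2.0, 2.0, fs=128.0)

    def test_short_support_rejected(self):
        with pytest.raises(ParameterError, match="support"):
            dd.bateman_kernel(0.75, 2.0, fs=128.0, support=0.2)


class TestZNormalize:
    def test_hand_computed_values(self):
        drv = dd.DriverSignal(fs=1.0, t0=0.0, samples=np.array([0.0, 1.0, 2.0]))
        z = dd.znormalize(drv)
        assert np.allclose(z.z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert z.mu == pytest.approx(1.0)
        assert z.sigma == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_z_view_has_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        drv = dd.DriverSignal(fs=1.0, t0=0.0, samples=rng.random(1000))
        z = dd.znormalize(drv)
        assert abs(z.z.mean()) < 1e-12
        assert z.z.std() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(2)
        x = rng.random(100)
        x = (x - x.mean()) / x.std()
        z = dd.znormalize(dd.DriverSignal(fs=1.0, t0=0.0, samples=x))
        assert np.allclose(z.z, x, atol=1e-9)

    def test_constant_driver_rejected(self):
        drv = dd.DriverSignal(fs=1.0, t0=0.0, samples=np.full(10, 3.0))
        with pytest.raises(DegenerateSignalError):
            dd.znormalize(drv)


class TestRichardsonLucy:
    def test_single_impulse_mass_concentrates(self, kernel, peak_kernel):
        # forward-convolution oracle: one SCR at t=10 s
        tr = make_trace([(10.0, 0.5)], peak_kernel=peak_kernel)
        for n_iter in (50, 100):
            drv = dd.deconvolve_rl(tr, kernel, n_iter=n_iter)
            t = drv.times
            mask = (t >= 9.5) & (t <= 10.5)
            frac = drv.samples[mask].sum() / drv.samples.sum()
            assert frac >= 0.90

    def test_all_zero_trace_gives_all_zero_driver(self, kernel):
        tr = dd.SCTrace("p", "d", 128.0, np.zeros(1000))
        drv = dd.deconvolve_rl(tr, kernel)
        assert np.all(drv.samples == 0)

    def test_constant_trace_gives_all_zero_driver(self, kernel):
        tr = dd.SCTrace("p", "d", 128.0, np.full(1000, 2.0))
        drv = dd.deconvolve_rl(tr, kernel)
        assert np.all(drv.samples == 0)

    def test_identity_kernel_returns_detrended_trace(self):
        rng = np.random.default_rng(3)
        x = 2.0 + rng.random(2000)
        tr = dd.SCTrace("p", "d", 128.0, x)
        ident = SCRKernel(tau_rise=0.1, tau_decay=0.2, fs=128.0, support=0.0,
                          samples=np.array([1.0]))
        drv = dd.deconvolve_rl(tr, ident, n_iter=5)
        expected = detrend_tonic(x, 128.0)
        assert np.allclose(drv.samples, expected, atol=1e-5)

    def test_driver_nonnegative_at_any_iteration_count(self, kernel, peak_kernel):
        tr = make_trace([(5.0, 0.3), (6.0, 0.4), (20.0, 0.2)],
                        peak_kernel=peak_kernel, duration=30.0)
        for n_iter in (1, 5, 25, 100):
            drv = dd.deconvolve_rl(tr, kernel, n_iter=n_iter)
            assert np.all(drv.samples >= 0)

    def test_reconvolution_residual_nonincreasing_in_iterations(
            self, kernel, peak_kernel):
        # plain multiplicative updates; RMSE against the detrended trace
        tr = make_trace([(8.0, 0.4), (9.5, 0.3), (22.0, 0.5)],
                        peak_kernel=peak_kernel, duration=35.0)
        target = detrend_tonic(tr.samples, tr.fs)
        rmses = []
        for n_iter in (1, 2, 5, 10, 25, 50, 100):
            drv = dd.deconvolve_rl(tr, kernel, n_iter=n_iter, tol=0.0,
                                   accelerate=False)
            recon = reconvolve(drv, kernel)
            rmses.append(np.sqrt(np.mean((recon - target) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_overlapping_scrs_separate_into_two_clusters(self, kernel,
                                                         peak_kernel):
        # 1.5 s apart: one visible hump in the raw trace, but two driver
        # mass clusters after deconvolution
        tr = make_trace([(10.0, 0.4), (11.5, 0.4)], peak_kernel=peak_kernel)
        raw_peaks, _ = find_peaks(tr.samples, prominence=0.05)
        assert raw_peaks.size == 1  # merged in the raw signal
        drv = dd.deconvolve_rl(tr, kernel)
        t = drv.times
        m1 = drv.samples[(t >= 9.4) & (t < 10.75)].sum()
        m2 = drv.samples[(t >= 10.75) & (t < 12.2)].sum()
        assert m1 > 0.2 * drv.samples.sum()
        assert m2 > 0.2 * drv.samples.sum()
        # and the detector sees both
        peaks = dd.detect_scr_peaks(dd.znormalize(drv))
        assert len(peaks) == 2

    def test_amplitude_calibration_on_isolated_scrs(self, kernel, peak_kernel):
        # driver peak reads as the SCR amplitude in μS
        tr = make_trace([(10.0, 0.5), (25.0, 0.2)], peak_kernel=peak_kernel)
        drv = dd.deconvolve_rl(tr, kernel)
        t = drv.times
        p1 = drv.samples[(t > 9) & (t < 11)].max()
        p2 = drv.samples[(t > 24) & (t < 26)].max()
        assert p1 == pytest.approx(0.5, rel=0.15)
        assert p2 == pytest.approx(0.2, rel=0.15)

    def test_matches_reference_richardson_lucy(self, kernel, peak_kernel):
        # independent oracle: the image-restoration RL implementation, with
        # the causal kernel zero-padded to a centered PSF and the data
        # scaled so both use the same flat initialization
        skrest = pytest.importorskip("skimage.restoration")
        tr = make_trace([(6.0, 0.4), (12.0, 0.25)], peak_kernel=peak_kernel,
                        duration=20.0)
        d = detrend_tonic(tr.samples, tr.fs) + 1e-6
        d = d * (0.5 / d.mean())  # reference implementation starts at 0.5
        h = kernel.samples
        psf = np.concatenate([np.zeros(h.size - 1), h])  # center = causal t0
        ref = skrest.richardson_lucy(d, psf, num_iter=20, clip=False)
        tr2 = dd.SCTrace("p", "d", tr.fs, d)  # already detrended & positive

        from dyadeda.deconvolution import _rl_iterate
        mine = _rl_iterate(d, h, n_iter=20, tol=0.0, accelerate=False)
        assert np.allclose(mine, ref, atol=1e-6 * d.max())

    def test_invalid_parameters(self, kernel):
        tr = dd.SCTrace("p", "d", 128.0, np.full(1000, 2.0))
        with pytest.raises(ParameterError):
            dd.deconvolve_rl(tr, kernel, n_iter=0)
        bad_fs = dd.bateman_kernel(fs=64.0)
        with pytest.raises(ParameterError, match="fs"):
            dd.deconvolve_rl(tr, bad_fs)
        with pytest.raises(ParameterError):
            detrend_tonic(tr.samples, tr.fs, window=-1.0)
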
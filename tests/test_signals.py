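"""Pulse synthesis, RF simulation, noise, SNR, envelopes and FWHM."""

import numpy as np
import pytest

from sparsebeam import (
    PA,
    US_PLANEWAVE,
    MetricError,
    SamplingError,
    SourceSet,
    TruncationError,
    add_noise,
    envelope,
    lateral_fwhm,
    make_grid,
    make_linear_probe,
    make_pulse,
    measure_snr,
    select_elements,
    synthesize_rf,
)


class TestPulse:
    def test_spectral_peak_at_center_frequency(self):
        pulse = make_pulse(15e6, 0.6, 62.5e6)
        spec = np.abs(np.fft.rfft(pulse.waveform))
        freqs = np.fft.rfftfreq(pulse.waveform.size, 1 / 62.5e6)
        bin_width = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(spec)] - 15e6) <= bin_width

    def test_minus6db_bandwidth(self):
        pulse = make_pulse(15e6, 0.6, 250e6)
        n = 1 << 14
        spec = np.abs(np.fft.rfft(pulse.waveform, n))
        freqs = np.fft.rfftfreq(n, 1 / 250e6)
        half = spec.max() / 2
        above = freqs[spec >= half]
        width = above.max() - above.min()
        assert width == pytest.approx(0.6 * 15e6, rel=0.05)

    def test_envelope_peak_normalized(self):
        pulse = make_pulse(15e6, 0.93, 62.5e6)
        assert envelope(pulse.waveform).max() == pytest.approx(1.0, abs=0.01)
        # the analytic model peaks exactly at the reference time
        assert pulse.sample(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_nyquist_guard(self):
        with pytest.raises(SamplingError):
            make_pulse(15e6, 0.6, 20e6)


class TestSynthesizeRF:
    def _one_source(self, probe, pulse, modality, z=15e-3):
        subset = select_elements(probe, probe.n_elements_total, "all")
        src = SourceSet(positions=[(0.0, z)], amplitudes=[1.0])
        return synthesize_rf(src, probe, subset, pulse, modality, 1500.0)

    def test_pa_peak_at_one_way_time_of_flight(self, pulse):
        probe = make_linear_probe(2, 100e-6)
        rf = self._one_source(probe, pulse, PA)
        env = envelope(rf.samples[:, 0])
        t_peak = rf.times[np.argmax(env)]
        # 15 mm / 1500 m/s = 10 µs (element 50 µm off-axis: +8 ps)
        assert t_peak == pytest.approx(10e-6, abs=2 / pulse.sampling_rate)

    def test_planewave_doubles_the_path(self, pulse):
        probe = make_linear_probe(2, 100e-6)
        rf = self._one_source(probe, pulse, US_PLANEWAVE)
        env = envelope(rf.samples[:, 0])
        t_peak = rf.times[np.argmax(env)]
        assert t_peak == pytest.approx(20e-6, abs=2 / pulse.sampling_rate)

    def test_linearity_in_amplitudes(self, small_probe, pulse):
        subset = select_elements(small_probe, 16, "all")
        kw = dict(t_start=2.9e-6, n_samples=96)
        one = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, subset, pulse, PA, 1500.0, **kw)
        two = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3), (0.0, 5e-3)],
                      amplitudes=[1.0, 1.0]),
            small_probe, subset, pulse, PA, 1500.0, **kw)
        assert np.allclose(two.samples, 2 * one.samples, atol=1e-12)

    def test_superposition_of_distinct_sources(self, small_probe, pulse):
        subset = select_elements(small_probe, 16, "all")
        kw = dict(t_start=2.9e-6, n_samples=128)
        a = synthesize_rf(SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
                          small_probe, subset, pulse, PA, 1500.0, **kw)
        b = synthesize_rf(SourceSet(positions=[(125e-6, 5.2e-3)],
                                    amplitudes=[0.5]),
                          small_probe, subset, pulse, PA, 1500.0, **kw)
        ab = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3), (125e-6, 5.2e-3)],
                      amplitudes=[1.0, 0.5]),
            small_probe, subset, pulse, PA, 1500.0, **kw)
        assert np.allclose(ab.samples, a.samples + b.samples, atol=1e-10)

    def test_axial_shift_moves_arrivals_consistently(self, small_probe, pulse):
        # moving the source deeper by dz delays every element's envelope
        # peak by dz/c (PA) within half a sample
        subset = select_elements(small_probe, 16, "all")
        kw = dict(t_start=2.9e-6, n_samples=160)
        dz = 150e-6
        rf1 = synthesize_rf(SourceSet(positions=[(0.0, 5e-3)],
                                      amplitudes=[1.0]),
                            small_probe, subset, pulse, PA, 1500.0, **kw)
        rf2 = synthesize_rf(SourceSet(positions=[(0.0, 5e-3 + dz)],
                                      amplitudes=[1.0]),
                            small_probe, subset, pulse, PA, 1500.0, **kw)
        def subsample_peak(env):
            i = int(np.argmax(env))
            a, b, c = env[i - 1], env[i], env[i + 1]
            return i + 0.5 * (a - c) / (a - 2 * b + c)

        for k in range(0, 16, 5):
            e1 = envelope(rf1.samples[:, k])
            e2 = envelope(rf2.samples[:, k])
            shift = (subsample_peak(e2) - subsample_peak(e1)) \
                / pulse.sampling_rate
            assert shift == pytest.approx(dz / 1500.0,
                                          abs=0.5 / pulse.sampling_rate)

    def test_out_of_window_source_refused(self, small_probe, pulse):
        subset = select_elements(small_probe, 16, "all")
        with pytest.raises(TruncationError):
            synthesize_rf(SourceSet(positions=[(0.0, 20e-3)],
                                    amplitudes=[1.0]),
                          small_probe, subset, pulse, PA, 1500.0,
                          t_start=6.0e-6, n_samples=64)


class TestNoiseAndSNR:
    def test_zero_sigma_is_identity(self, small_scene_rf):
        assert add_noise(small_scene_rf, 0.0, seed=1) is small_scene_rf

    def test_noise_rms_matches_sigma(self, small_scene_rf):
        noisy = add_noise(small_scene_rf, 30.0, seed=3)
        resid = noisy.samples - small_scene_rf.samples
        assert np.std(resid) == pytest.approx(30.0, rel=0.02)

    def test_noise_deterministic_from_seed(self, small_scene_rf):
        a = add_noise(small_scene_rf, 30.0, seed=11)
        b = add_noise(small_scene_rf, 30.0, seed=11)
        assert np.array_equal(a.samples, b.samples)

    @staticmethod
    def _rf_with_quiet_prefix(small_scene_rf, peak, sigma, seed):
        """RF whose first 200 samples are pure noise and whose signal part
        is scaled to the requested noiseless peak."""
        from dataclasses import replace
        rng = np.random.default_rng(seed)
        sig = small_scene_rf.samples
        sig = peak * sig / np.max(np.abs(sig))
        quiet = np.zeros((200, sig.shape[1]))
        samples = np.vstack([quiet, sig])
        if sigma > 0:
            samples = samples + rng.normal(0, sigma, samples.shape)
        return replace(small_scene_rf, samples=samples)

    def test_snr_definition_paper_pairing(self, small_scene_rf):
        # peak 4500 over noise std 30 -> SNR 150
        rf = self._rf_with_quiet_prefix(small_scene_rf, 4500.0, 30.0, seed=5)
        snr = measure_snr(rf, slice(0, 200))
        assert snr == pytest.approx(150.0, rel=0.05)

    def test_snr_scales_with_amplitude(self, small_scene_rf):
        rf1 = self._rf_with_quiet_prefix(small_scene_rf, 10.0, 0.01, seed=2)
        rf10 = self._rf_with_quiet_prefix(small_scene_rf, 100.0, 0.01, seed=2)
        r = measure_snr(rf10, slice(0, 200)) / measure_snr(rf1, slice(0, 200))
        assert r == pytest.approx(10.0, rel=0.05)

    def test_infinite_snr_sentinel(self, small_scene_rf):
        rf = self._rf_with_quiet_prefix(small_scene_rf, 1.0, 0.0, seed=0)
        assert measure_snr(rf, slice(0, 200)) == np.inf

    def test_pure_noise_record_has_small_finite_snr(self, small_scene_rf):
        from dataclasses import replace
        zero = replace(small_scene_rf, samples=np.zeros_like(
            small_scene_rf.samples))
        noisy = add_noise(zero, 30.0, seed=9)
        snr = measure_snr(noisy, slice(None))
        assert 2.0 < snr < 8.0  # max/std of ~1500 Gaussian samples


class TestEnvelopeAndFWHM:
    def test_cosine_envelope_is_flat(self):
        t = np.arange(4096) / 62.5e6
        x = 3.0 * np.cos(2 * np.pi * 5e6 * t)
        env = envelope(x)
        interior = env[100:-100]
        assert np.allclose(interior, 3.0, rtol=0.01)

    def test_envelope_invariant_to_sign_flip(self, pulse):
        assert np.allclose(envelope(pulse.waveform),
                           envelope(-pulse.waveform))

    def test_gaussian_profile_fwhm_closed_form(self):
        grid = make_grid(-500e-6, 500e-6, 0, 25e-6, 12.5e-6)
        sigma_g = 66e-6
        img = np.exp(-grid.x_coords**2 / (2 * sigma_g**2))[None, :].repeat(
            grid.nz, axis=0)
        fwhm = lateral_fwhm(img, grid)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma_g,
                                     rel=0.01)

    def test_single_pixel_peak_fwhm_below_step(self):
        grid = make_grid(-100e-6, 100e-6, 0, 0, 12.5e-6)
        img = np.zeros((1, grid.nx))
        img[0, grid.nx // 2] = 1.0
        assert lateral_fwhm(img, grid) <= 12.5e-6

    def test_profile_never_below_half_max_raises(self):
        grid = make_grid(-100e-6, 100e-6, 0, 0, 12.5e-6)
        img = np.ones((1, grid.nx))
        img[0, grid.nx // 2] = 1.2
        with pytest.raises(MetricError):
            lateral_fwhm(img, grid)
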
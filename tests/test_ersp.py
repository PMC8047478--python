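"""Morlet wavelet bank, time-frequency transform, ERSP, band traces."""

import numpy as np
import pytest

from illuseeg import synth
from illuseeg.ersp import (
    WaveletBank,
    band_trace,
    cycles_at,
    ersp,
    fdhm,
    make_wavelet,
    relative_baseline,
    sigma_t,
    spectral_fwhm,
    tfr_transform,
)

LN2 = np.log(2.0)


class TestBankFormulas:
    @pytest.mark.parametrize("f, n", [(1.0, 3.0), (45.0, 10.0), (23.0, 6.5)])
    def test_linear_cycle_count(self, f, n):
        assert cycles_at(f) == pytest.approx(n)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cycles_at(0.5)
        with pytest.raises(ValueError):
            cycles_at(50.0)

    def test_printed_width_extremes(self):
        assert round(float(fdhm(1.0)) * 1000) == 1124
        assert round(float(fdhm(45.0)) * 1000) == 83
        assert round(float(spectral_fwhm(1.0)), 2) == 0.78
        assert round(float(spectral_fwhm(45.0)), 2) == 10.60

    def test_time_bandwidth_product_constant(self):
        freqs = np.linspace(1.0, 45.0, 89)
        product = fdhm(freqs) * spectral_fwhm(freqs)
        np.testing.assert_allclose(product, 4 * LN2 / np.pi, atol=1e-12)

    def test_fdhm_consistent_with_envelope_sigma(self):
        freqs = np.array([1.0, 10.0, 45.0])
        np.testing.assert_allclose(
            fdhm(freqs), 2 * np.sqrt(2 * LN2) * sigma_t(freqs), rtol=1e-12
        )

    def test_doubling_cycles_halves_spectral_width(self):
        assert spectral_fwhm(10.0, n=10.0) == pytest.approx(
            spectral_fwhm(10.0, n=5.0) / 2
        )


class TestMakeWavelet:
    def test_symmetric_unit_energy(self):
        w = make_wavelet(10.0, 200.0)
        np.testing.assert_allclose(np.abs(w), np.abs(w)[::-1], atol=1e-12)
        assert np.sum(np.abs(w) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_measured_half_max_width_matches_fdhm(self):
        rate = 1000.0
        for f in (2.0, 10.0, 30.0):
            w = np.abs(make_wavelet(f, rate))
            above = np.nonzero(w >= w.max() / 2)[0]
            measured = (above[-1] - above[0]) / rate
            assert measured == pytest.approx(float(fdhm(f)), abs=2.5 / rate)

    def test_peak_frequency(self):
        rate = 500.0
        for f in (5.0, 20.0):
            w = make_wavelet(f, rate)
            spec = np.abs(np.fft.fft(w, 65536))
            freqs = np.fft.fftfreq(65536, 1 / rate)
            assert freqs[np.argmax(spec)] == pytest.approx(f, abs=rate / 65536 * 2)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            make_wavelet(120.0, 200.0)


def _epochs(data, rate=200.0, t0=-2.0):
    from illuseeg.preprocess import EpochSet

    data = np.asarray(data, float)
    times = t0 + np.arange(data.shape[2]) / rate
    labels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, times=times, rate=rate, channel_labels=labels)


class TestTransform:
    def test_pure_tone_ridge(self):
        rate = 200.0
        t = np.arange(-2.0, 2.0, 1 / rate)
        tone = np.cos(2 * np.pi * 10.0 * t)
        bank = WaveletBank(freqs=np.arange(5.0, 15.01, 0.2), rate=rate)
        coeffs, tmpl = tfr_transform(_epochs(tone[None, None, :]), bank)
        power = ersp(coeffs, tmpl)
        core = tmpl.valid.all(axis=0)
        profile = power.power[0][:, core].mean(axis=1)
        assert abs(bank.freqs[np.argmax(profile)] - 10.0) <= 0.2

    def test_power_scales_with_amplitude_squared(self):
        rate = 200.0
        t = np.arange(-2.0, 2.0, 1 / rate)
        bank = WaveletBank(freqs=np.array([10.0]), rate=rate)
        powers = []
        for amp in (1.0, 3.0):
            coeffs, tmpl = tfr_transform(
                _epochs(amp * np.cos(2 * np.pi * 10 * t)[None, None, :]), bank
            )
            p = ersp(coeffs, tmpl).power
            powers.append(p[0, 0, tmpl.valid[0]].mean())
        assert powers[1] / powers[0] == pytest.approx(9.0, rel=1e-3)

    def test_two_tone_ridges(self):
        rate = 200.0
        t = np.arange(-3.0, 3.0, 1 / rate)
        x = np.cos(2 * np.pi * 5 * t) + np.cos(2 * np.pi * 20 * t)
        bank = WaveletBank(freqs=np.arange(2.0, 30.01, 0.5), rate=rate)
        coeffs, tmpl = tfr_transform(_epochs(x[None, None, :]), bank)
        power = ersp(coeffs, tmpl)
        core = tmpl.valid.all(axis=0)
        profile = power.power[0][:, core].mean(axis=1)
        half = bank.freqs < 12.0
        assert abs(bank.freqs[half][np.argmax(profile[half])] - 5.0) <= 0.5
        assert abs(bank.freqs[~half][np.argmax(profile[~half])] - 20.0) <= 0.5

    def test_epoch_shorter_than_wavelet_rejected(self):
        bank = WaveletBank(freqs=np.array([1.0]), rate=200.0)
        with pytest.raises(ValueError, match="shorter"):
            tfr_transform(_epochs(np.zeros((1, 1, 100))), bank)


class TestErsp:
    def test_single_trial_squared_magnitude(self, rng):
        bank = WaveletBank(freqs=np.array([8.0]), rate=200.0)
        coeffs, tmpl = tfr_transform(
            _epochs(rng.standard_normal((1, 2, 800))), bank
        )
        out = ersp(coeffs, tmpl)
        np.testing.assert_allclose(out.power, np.abs(coeffs[0]) ** 2)

    def test_phase_randomization_invariance(self, rng):
        bank = WaveletBank(freqs=np.array([8.0]), rate=200.0)
        coeffs, tmpl = tfr_transform(
            _epochs(rng.standard_normal((1, 1, 800))), bank
        )
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 5))
        stacked = np.concatenate([coeffs * ph for ph in phases])
        np.testing.assert_allclose(
            ersp(stacked, tmpl).power, ersp(coeffs, tmpl).power, rtol=1e-12
        )

    def test_duplicated_trials_leave_ersp_unchanged(self, rng):
        bank = WaveletBank(freqs=np.array([12.0]), rate=200.0)
        coeffs, tmpl = tfr_transform(
            _epochs(rng.standard_normal((4, 1, 800))), bank
        )
        doubled = np.concatenate([coeffs, coeffs])
        np.testing.assert_allclose(
            ersp(doubled, tmpl).power, ersp(coeffs, tmpl).power, rtol=1e-12
        )

    def test_tone_in_noise_additivity(self, rng):
        # power of tone + independent noise ~ tone power + noise floor
        rate, f0 = 200.0, 10.0
        t = np.arange(-2.5, 2.5, 1 / rate)
        tone = np.cos(2 * np.pi * f0 * t)
        bank = WaveletBank(freqs=np.array([f0]), rate=rate)
        n = 60
        noise = rng.standard_normal((n, 1, t.size)) * 0.5
        c_mix, tmpl = tfr_transform(_epochs(noise + tone[None, None, :]), bank)
        c_tone, _ = tfr_transform(_epochs(tone[None, None, :]), bank)
        c_noise, _ = tfr_transform(_epochs(noise), bank)
        core = tmpl.valid[0]
        mixed = ersp(c_mix, tmpl).power[0, 0, core].mean()
        expected = (
            ersp(c_tone, tmpl).power[0, 0, core].mean()
            + ersp(c_noise, tmpl).power[0, 0, core].mean()
        )
        assert mixed == pytest.approx(expected, rel=0.05)


class TestRelativeBaseline:
    def _stationary_tfr(self, rng, freqs=(8.0,), n_trials=30):
        rate = 200.0
        bank = WaveletBank(freqs=np.asarray(freqs), rate=rate)
        data = rng.standard_normal((n_trials, 1, 1200))
        coeffs, tmpl = tfr_transform(_epochs(data, t0=-3.0), bank)
        return ersp(coeffs, tmpl)

    def test_stationary_signal_near_zero(self, rng):
        tfr = self._stationary_tfr(rng)
        rel = relative_baseline(tfr, baseline=(-2.5, -1.0), activation_start=-1.0)
        core = rel.valid[0]
        assert abs(rel.power[0, 0, core].mean()) < 0.15

    def test_power_doubling_gives_relative_one(self):
        tfr = self._stationary_tfr(np.random.default_rng(0))
        from dataclasses import replace

        const = np.ones_like(tfr.power)
        const[:, :, tfr.times > 0.0] = 2.0
        tfr2 = replace(tfr, power=const)
        rel = relative_baseline(tfr2, baseline=(-2.5, -1.0), activation_start=0.0)
        late = rel.valid[0] & (rel.times > 0.0)
        np.testing.assert_allclose(rel.power[0, 0, late], 1.0, atol=1e-9)
        early = rel.valid[0] & (rel.times < -1.0)
        np.testing.assert_allclose(rel.power[0, 0, early], 0.0, atol=1e-9)

    def test_margin_violation_names_frequency(self, rng):
        tfr = self._stationary_tfr(rng, freqs=(2.0,))
        with pytest.raises(ValueError, match="2"):
            relative_baseline(tfr, baseline=(-2.9, -2.8), activation_start=-2.8)

    def test_planted_scp_enhancement_recovered(self, rng):
        # +50% 1-4 Hz power in the activation window, via the generator
        rate = 200.0
        spec = synth.EffectSpec(
            "SCP", "band", 0.5, latency=0.0, width=2.0,
            topography=np.ones(4), band=(1.0, 4.0),
        )
        n_trials = 200  # slow-band power estimates have few dof per trial
        t0 = -6.0
        n_t = int(12.0 * rate) + 1
        data = np.stack(
            [synth.pink_noise(n_t, 4, 1.0, 20.0, s) for s in range(n_trials)]
        )
        eps = _epochs(data, rate=rate, t0=t0)
        eps = synth.add_component(eps, spec)
        bank = WaveletBank(freqs=np.arange(1.0, 4.01, 0.5), rate=rate)
        coeffs, tmpl = tfr_transform(eps, bank)
        raw = ersp(coeffs, tmpl)
        rel = relative_baseline(raw, baseline=(-5.0, -2.5), activation_start=-2.0)
        trace = band_trace(rel, (1.0, 4.0))
        peak_region = (rel.times > -0.2) & (rel.times < 0.2)
        recovered = trace[:, peak_region].mean()
        assert recovered == pytest.approx(0.5, abs=0.1)


class TestBandTrace:
    def test_single_bin_band(self, rng):
        tfr = TestRelativeBaseline()._stationary_tfr(rng, freqs=(8.0, 12.0))
        trace = band_trace(tfr, (7.9, 8.1))
        np.testing.assert_allclose(trace, tfr.power[:, 0, :])

    def test_flat_spectrum_equals_broadband_mean(self, rng):
        tfr = TestRelativeBaseline()._stationary_tfr(rng, freqs=(8.0, 10.0, 12.0))
        np.testing.assert_allclose(
            band_trace(tfr, (7.0, 13.0)), tfr.power.mean(axis=1), rtol=1e-12
        )

    def test_empty_band_rejected(self, rng):
        tfr = TestRelativeBaseline()._stationary_tfr(rng)
        with pytest.raises(ValueError):
            band_trace(tfr, (30.0, 35.0))

    def test_planted_alpha_erd_dip(self, rng):
        rate = 200.0
        spec = synth.EffectSpec(
            "alphaERD", "band", -0.4, latency=0.0, width=2.0,
            topography=np.ones(1), band=(8.0, 12.0),
        )
        n_t = int(10.0 * rate) + 1
        data = np.stack(
            [synth.pink_noise(n_t, 1, 1.0, 20.0, 1000 + s) for s in range(40)]
        )
        eps = _epochs(data, rate=rate, t0=-5.0)
        eps = synth.add_component(eps, spec)
        bank = WaveletBank(freqs=np.arange(8.0, 12.01, 0.5), rate=rate)
        coeffs, tmpl = tfr_transform(eps, bank)
        rel = relative_baseline(
            ersp(coeffs, tmpl), baseline=(-4.0, -2.0), activation_start=-2.0
        )
        trace = band_trace(rel, (8.0, 12.0))
        dip_region = (rel.times > -0.2) & (rel.times < 0.2)
        depth = trace[0, dip_region].mean()
        assert depth == pytest.approx(-0.4, abs=0.08)  # within 20% of -0.4
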
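import numpy as np
import pytest

import delaypop as dp
from delaypop import SampledSignal
from delaypop.spectral import CutoffResult, coding_summary


def band_noise(duration, fs, lo, hi, seed, sigma=1.0):
    return dp.generate_band_noise(dp.StimulusSpec(duration, fs, lo, hi, sigma, seed))


class TestWelchSpectra:
    def test_identity_response(self):
        x = band_noise(10.0, 2000.0, 0.0, 300.0, 1)
        pxx, pyy, pxy = dp.welch_spectra(x, [x], nperseg=1024)
        assert np.allclose(pyy.values, pxx.values)
        assert np.allclose(pxy.values.real, pxx.values)
        assert np.allclose(pxy.values.imag, 0.0, atol=1e-12)

    def test_independent_signals_coherence_scales_as_one_over_segments(self):
        x = band_noise(30.0, 2000.0, 0.0, 300.0, 2)
        y = band_noise(30.0, 2000.0, 0.0, 300.0, 3)
        coh = dp.coherence(x, [y], nperseg=512)
        n = coh.n_segments
        in_band = coh.values[(coh.frequencies > 5) & (coh.frequencies < 295)]
        assert 0.3 / n < in_band.mean() < 3.0 / n

    def test_too_short_signal_raises(self):
        x = band_noise(0.1, 2000.0, 0.0, 300.0, 4)
        with pytest.raises(ValueError, match="shorter than one segment"):
            dp.welch_spectra(x, [x], nperseg=2**15)


class TestTransferFunction:
    def test_static_gain(self):
        x = band_noise(10.0, 2000.0, 0.0, 300.0, 5)
        y = x.copy_with(2.0 * x.values)
        h = dp.transfer_function(x, [y], nperseg=1024)
        in_band = np.abs(h.values[(h.frequencies > 2) & (h.frequencies < 298)])
        assert np.allclose(in_band, 2.0, rtol=1e-6)

    def test_pure_delay_leaves_gain_and_sets_phase_slope(self):
        fs = 2000.0
        x = band_noise(20.0, fs, 0.0, 300.0, 6)
        d = 0.01
        y = x.copy_with(np.roll(x.values, int(d * fs)))
        h = dp.transfer_function(x, [y], nperseg=1024)
        band = (h.frequencies > 10) & (h.frequencies < 280)
        assert np.allclose(np.abs(h.values[band]), 1.0, atol=0.05)
        slope = np.polyfit(h.frequencies[band], np.unwrap(np.angle(h.values[band])), 1)[0]
        assert np.isclose(slope, -2 * np.pi * d, rtol=1e-3)

    def test_differentiator_gain_grows_linearly(self):
        fs = 2000.0
        x = band_noise(20.0, fs, 10.0, 300.0, 7)
        y = x.copy_with(np.gradient(x.values, 1.0 / fs))
        h = dp.transfer_function(x, [y], nperseg=1024)
        band = (h.frequencies > 30) & (h.frequencies < 250)
        # np.gradient is a central difference whose gain is sin(w dt)/dt
        expected = np.sin(2 * np.pi * h.frequencies[band] / fs) * fs
        ratio = np.abs(h.values[band]) / expected
        assert np.allclose(ratio, 1.0, rtol=0.02)


class TestCoherenceAndMi:
    def test_perfect_coherence_for_identical_signals(self):
        x = band_noise(10.0, 2000.0, 0.0, 300.0, 8)
        coh = dp.coherence(x, [x], nperseg=1024)
        band = (coh.frequencies > 2) & (coh.frequencies < 298)
        assert np.allclose(coh.values[band], 1.0, atol=1e-9)

    def test_linear_gaussian_channel_closed_form(self):
        # response = stimulus + equal-power independent noise -> gamma^2 = 1/2
        fs = 2000.0
        x = band_noise(40.0, fs, 0.0, 300.0, 9)
        n = band_noise(40.0, fs, 0.0, 300.0, 10)
        y = x.copy_with(x.values + n.values)
        coh = dp.coherence(x, [y], nperseg=1024)
        band = (coh.frequencies > 10) & (coh.frequencies < 290)
        assert abs(coh.values[band].mean() - 0.5) < 0.02

    @pytest.mark.parametrize(
        "gamma,lo,hi,expected",
        [(0.5, 0.0, 300.0, 300.0), (0.0, 0.0, 300.0, 0.0), (0.75, 0.0, 100.0, 200.0)],
    )
    def test_mi_of_constant_coherence(self, gamma, lo, hi, expected):
        freqs = np.linspace(0, 400, 801)
        est = dp.SpectralEstimate(freqs, np.full(freqs.size, gamma), 10, 1024)
        assert np.isclose(dp.lower_bound_mi(est, lo, hi), expected, rtol=1e-9)

    def test_band_mi_tiles_to_full_range(self):
        freqs = np.linspace(0, 300, 601)
        rng = np.random.default_rng(11)
        est = dp.SpectralEstimate(freqs, rng.uniform(0.1, 0.9, freqs.size), 10, 1024)
        full = dp.lower_bound_mi(est, 0.0, 300.0)
        parts = dp.band_mi(est, [(0.0, 100.0), (100.0, 200.0), (200.0, 300.0)])
        assert np.isclose(sum(parts), full, rtol=1e-9)

    def test_band_mi_rejects_overlap(self):
        freqs = np.linspace(0, 300, 601)
        est = dp.SpectralEstimate(freqs, np.full(freqs.size, 0.5), 10, 1024)
        with pytest.raises(ValueError, match="overlap"):
            dp.band_mi(est, [(0.0, 150.0), (100.0, 300.0)])

    def test_mi_is_invariant_to_small_response_shifts(self):
        fs = 2000.0
        x = band_noise(30.0, fs, 0.0, 300.0, 12)
        n = band_noise(30.0, fs, 0.0, 300.0, 13)
        y = x.values + 0.5 * n.values
        mi0 = dp.lower_bound_mi(dp.coherence(x, [x.copy_with(y)], nperseg=1024))
        # 5 ms shift, far below the 512 ms segment
        mi1 = dp.lower_bound_mi(
            dp.coherence(x, [x.copy_with(np.roll(y, int(0.005 * fs)))], nperseg=1024)
        )
        assert abs(mi1 - mi0) / mi0 < 0.05


class TestCutoffsAndSmoothing:
    def test_flat_gain_is_flagged_at_edges(self):
        freqs = np.linspace(0, 300, 301)
        est = dp.SpectralEstimate(freqs, np.ones(301), 10, 1024)
        cut = dp.cutoff_frequencies(est, mode="gain")
        assert (cut.lower, cut.upper) == (0.0, 300.0)
        assert cut.lower_flagged and cut.upper_flagged

    def test_single_pole_lowpass_cutoff(self):
        freqs = np.linspace(0, 500, 2001)
        gain = 1.0 / np.sqrt(1.0 + (freqs / 100.0) ** 2)
        est = dp.SpectralEstimate(freqs, gain, 10, 1024)
        cut = dp.cutoff_frequencies(est, mode="gain")
        assert np.isclose(cut.upper, 100.0, rtol=0.01)
        assert cut.lower_flagged  # never falls below threshold toward DC

    def test_symmetric_bandpass_cutoffs(self):
        freqs = np.linspace(0, 300, 1201)
        gain = np.exp(-0.5 * ((freqs - 150.0) / 40.0) ** 2)
        est = dp.SpectralEstimate(freqs, gain, 10, 1024)
        cut = dp.cutoff_frequencies(est, mode="gain")
        assert np.isclose(150.0 - cut.lower, cut.upper - 150.0, atol=0.5)

    def test_coherence_mode_uses_half_maximum(self):
        freqs = np.linspace(0, 300, 1201)
        vals = np.exp(-0.5 * ((freqs - 150.0) / 40.0) ** 2)
        est = dp.SpectralEstimate(freqs, vals, 10, 1024)
        cut = dp.cutoff_frequencies(est, mode="coherence")
        half_width = 40.0 * np.sqrt(2 * np.log(2.0))
        assert np.isclose(cut.upper - 150.0, half_width, atol=0.5)

    def test_smoothing_identity_and_impulse(self):
        freqs = np.arange(101, dtype=float)
        vals = np.zeros(101)
        vals[50] = 11.0
        est = dp.SpectralEstimate(freqs, vals, 10, 1024)
        assert np.array_equal(dp.smooth_spectrum(est, 1).values, vals)
        sm = dp.smooth_spectrum(est, 11)
        assert np.allclose(sm.values[45:56], 1.0)
        const = dp.SpectralEstimate(freqs, np.full(101, 3.3), 10, 1024)
        assert np.allclose(dp.smooth_spectrum(const, 11).values, 3.3)
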
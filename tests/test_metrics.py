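import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import delaypop as dp
from delaypop import SampledSignal, SpikeTrain


def train_from_isis(isis, pad=0.1):
    times = np.concatenate(([0.0], np.cumsum(isis)))
    return SpikeTrain(times, times[-1] + pad)


class TestFiringRate:
    def test_single_spike_peak_is_gaussian_height(self):
        tr = SpikeTrain([0.5], 1.0)
        est = dp.firing_rate(tr, kernel_sigma=1e-3, output_rate=20000.0)
        peak = est.rate.values.max()
        expected = 1.0 / (np.sqrt(2 * np.pi) * 1e-3)  # ~398.94 Hz
        assert np.isclose(peak, expected, rtol=1e-3)
        assert np.isclose(est.rate.times[np.argmax(est.rate.values)], 0.5, atol=1e-4)

    def test_empty_train_gives_zero_rate(self):
        est = dp.firing_rate(SpikeTrain([], 1.0), 1e-3)
        assert not est.rate.values.any()

    def test_rate_integral_equals_spike_count(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.05, 0.95, 60))
        tr = SpikeTrain(times, 1.0)
        est = dp.firing_rate(tr, 1e-3)
        integral = est.rate.values.sum() / est.rate.sampling_rate
        assert np.isclose(integral, 60, rtol=5e-3)

    def test_average_rate_equals_mean_of_single_trial_rates(self):
        rng = np.random.default_rng(1)
        trains = [
            SpikeTrain(np.sort(rng.uniform(0, 1, 40)), 1.0, trial_id=str(k))
            for k in range(3)
        ]
        avg = dp.average_rate(trains, 1e-3)
        singles = np.mean(
            [dp.firing_rate(t, 1e-3).rate.values for t in trains], axis=0
        )
        assert np.allclose(avg.rate.values, singles, atol=1e-9)


class TestVectorStrength:
    def test_perfect_locking(self):
        onsets = np.arange(0, 1.0, 0.01)
        times = onsets[:-1] + 0.0025  # all at phase pi/2
        vs, phase = dp.vector_strength(SpikeTrain(times, 1.0), onsets)
        assert np.isclose(vs, 1.0)
        assert np.isclose(phase, np.pi / 2)

    def test_symmetric_phases_cancel(self):
        onsets = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        times = np.array([0.0, 1.25, 2.5, 3.75])  # phases 0, pi/2, pi, 3pi/2
        vs, _ = dp.vector_strength(SpikeTrain(times, 5.0), onsets)
        assert vs < 1e-12

    def test_three_spike_vector_sum(self):
        # phases {0, 0, pi} -> |1 + 1 - 1| / 3 = 1/3
        onsets = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        times = np.array([1e-9, 1.0 + 1e-9, 2.5])
        vs, _ = dp.vector_strength(SpikeTrain(times, 4.0), onsets)
        assert np.isclose(vs, 1.0 / 3.0, atol=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.0, 2 * np.pi))
    def test_rigid_phase_rotation_leaves_vs_unchanged(self, shift):
        rng = np.random.default_rng(3)
        period = 0.01
        onsets = np.arange(0, 1.0 + period / 2, period)
        base_phases = rng.uniform(0, 2 * np.pi, 50)
        cycles = rng.integers(0, 90, 50)

        def mk(phases):
            t = np.sort(cycles * period + (phases % (2 * np.pi)) / (2 * np.pi) * period)
            t = t[np.concatenate(([True], np.diff(t) > 0))]
            return SpikeTrain(t, 1.0)

        vs0, _ = dp.vector_strength(mk(base_phases), onsets)
        vs1, _ = dp.vector_strength(mk(base_phases + shift), onsets)
        assert np.isclose(vs0, vs1, atol=1e-9)


class TestIsiStatistics:
    def test_cv_regular_train_is_zero(self):
        assert dp.cv_isi(train_from_isis([0.01] * 50)) < 1e-12

    def test_cv_worked_example(self):
        # ISIs {1,1,2}: population sd / mean = sqrt(2/9)/(4/3)
        cv = dp.cv_isi(train_from_isis([1.0, 1.0, 2.0], pad=1.0))
        assert np.isclose(cv, 0.35355, atol=1e-5)

    def test_cv_poisson_near_unity(self):
        rng = np.random.default_rng(7)
        cv = dp.cv_isi(train_from_isis(rng.exponential(0.005, 5000)))
        assert abs(cv - 1.0) < 0.05

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_cv_is_scale_invariant(self, c):
        isis = np.array([1.0, 2.0, 3.0, 1.5, 0.7])
        a = dp.cv_isi(train_from_isis(isis))
        b = dp.cv_isi(train_from_isis(isis * c))
        assert np.isclose(a, b, rtol=1e-9)

    def test_cv_requires_three_spikes(self):
        with pytest.raises(ValueError, match="3 spikes"):
            dp.cv_isi(SpikeTrain([0.1, 0.2], 1.0))

    @pytest.mark.parametrize(
        "isis_ms,period_ms,expected",
        [
            ([1.2, 1.2, 5.0], 1.0, 2.0 / 3.0),
            ([2.0, 3.0, 4.0], 1.0, 0.0),
            ([1.0, 1.2, 1.4], 1.0, 1.0),
        ],
    )
    def test_burst_fraction_threshold_counts(self, isis_ms, period_ms, expected):
        tr = train_from_isis(np.array(isis_ms) * 1e-3)
        assert np.isclose(dp.burst_fraction(tr, period_ms * 1e-3), expected)

    def test_burst_fraction_rejects_bad_period(self):
        with pytest.raises(ValueError, match="positive"):
            dp.burst_fraction(train_from_isis([0.01] * 5), 0.0)


class TestResponseMoments:
    def test_constant_rate_has_zero_modulation(self):
        rate = dp.RateEstimate(SampledSignal(np.full(1000, 200.0), 1000.0), 1e-3)
        assert dp.response_modulation(rate) == 0.0

    def test_sinusoidal_modulation_is_amplitude_over_sqrt2(self):
        fs = 10000.0
        t = np.arange(int(fs)) / fs  # exactly 1 s -> whole periods of 10 Hz
        vals = 200.0 + 30.0 * np.sin(2 * np.pi * 10.0 * t)
        rate = dp.RateEstimate(SampledSignal(vals, fs), 1e-3)
        assert np.isclose(dp.response_modulation(rate), 30.0 / np.sqrt(2), rtol=1e-6)

    def test_identical_trials_have_zero_variability(self):
        r = dp.RateEstimate(SampledSignal(np.linspace(0, 100, 500), 500.0), 1e-3)
        assert dp.response_variability([r, r]) == 0.0

    def test_two_offset_trials_give_half_offset(self):
        base = np.linspace(0, 100, 500)
        r1 = dp.RateEstimate(SampledSignal(base, 500.0), 1e-3)
        r2 = dp.RateEstimate(SampledSignal(base + 8.0, 500.0), 1e-3)
        assert np.isclose(dp.response_variability([r1, r2]), 4.0)


class TestSta:
    def test_fixed_lag_construction(self):
        fs = 20000.0
        stim = dp.generate_band_noise(dp.StimulusSpec(5.0, fs, 0.0, 100.0, 1.0, 9))
        d = 0.004
        peaks = []
        v = stim.values
        # spikes d after each strong stimulus upstroke
        idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > 1.5))[0] + 1
        times = idx / fs + d
        times = times[(times > 0.05) & (times < 4.95)]
        tr = SpikeTrain(times, 5.0)
        assert np.isclose(dp.sta_delay(tr, stim, window=0.02), d, atol=5e-4)

    def test_independent_spikes_give_flat_sta(self):
        fs = 20000.0
        stim = dp.generate_band_noise(dp.StimulusSpec(5.0, fs, 0.0, 300.0, 1.0, 10))
        rng = np.random.default_rng(11)
        tr = SpikeTrain(np.sort(rng.uniform(0.05, 4.95, 800)), 5.0)
        lags, avg = dp.sta(tr, stim, window=0.01)
        sem = stim.values.std() / np.sqrt(800)
        assert np.all(np.abs(avg) < 3.5 * sem)

    def test_no_usable_spikes_raises(self):
        stim = dp.generate_band_noise(dp.StimulusSpec(0.1, 20000.0, 0.0, 300.0, 1.0, 12))
        with pytest.raises(ValueError, match="window"):
            dp.sta(SpikeTrain([0.001], 0.1), stim, window=0.05)
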
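"""Single-train and across-trial response characterization.

Baseline activity of amplitude-coding afferents is summarized by the
firing rate, the coefficient of variation of the interspike intervals
(CV_ISI = sd(ISI)/mean(ISI)), the burst fraction (fraction of ISIs
shorter than 1.5 carrier periods) and the vector strength

    rho = | sum_j exp(-i 2 pi t_j / T_j) | / n

with t_j the spike time relative to the onset of its carrier cycle and
T_j that cycle's period; rho = 1 means perfect phase locking, rho = 0 a
symmetric phase distribution.  All standard deviations here are
population (divide-by-n) moments.

Driven responses are characterized on continuous firing rates obtained
by convolving spike trains with a unit-mass Gaussian kernel: the
response modulation (temporal sd of the trial-averaged rate), the
across-trial variability, and the spike-triggered average (STA) of the
stimulus whose peak lag estimates the response delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .signal import SampledSignal, SpikeTrain

__all__ = [
    "RateEstimate",
    "BaselineSummary",
    "firing_rate",
    "average_rate",
    "vector_strength",
    "cv_isi",
    "burst_fraction",
    "response_modulation",
    "response_variability",
    "sta",
    "sta_delay",
    "cycle_onsets_from_carrier",
    "sine_cycle_onsets",
    "baseline_summary",
]


@dataclass
class RateEstimate:
    """A kernel-convolved firing rate on a uniform grid (Hz)."""

    rate: SampledSignal
    kernel_sigma: float
    n_trials_averaged: int = 1


def _spike_counts(train: SpikeTrain, sampling_rate: float) -> np.ndarray:
    n = int(round(train.duration * sampling_rate))
    idx = np.clip(np.round(train.times * sampling_rate).astype(int), 0, n - 1)
    return np.bincount(idx, minlength=n).astype(float)


def _gauss_kernel(sigma: float, sampling_rate: float) -> np.ndarray:
    radius = max(1, int(np.ceil(5.0 * sigma * sampling_rate)))
    t = np.arange(-radius, radius + 1) / sampling_rate
    k = np.exp(-0.5 * (t / sigma) ** 2) / (np.sqrt(2.0 * np.pi) * sigma)
    return k


def firing_rate(
    train: SpikeTrain, kernel_sigma: float = 1e-3, output_rate: float = 20000.0
) -> RateEstimate:
    """Continuous firing rate by Gaussian kernel convolution.

    Each spike contributes a unit-mass Gaussian of width
    ``kernel_sigma``; the rate is sampled at ``output_rate`` on a grid
    covering ``[0, duration)``.  An empty train yields an all-zero rate.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    counts = _spike_counts(train, output_rate)
    kernel = _gauss_kernel(kernel_sigma, output_rate)
    vals = fftconvolve(counts, kernel, mode="same")
    np.clip(vals, 0.0, None, out=vals)
    return RateEstimate(SampledSignal(vals, output_rate), kernel_sigma, 1)


def average_rate(
    trains: Sequence[SpikeTrain],
    kernel_sigma: float = 1e-3,
    output_rate: float = 20000.0,
) -> RateEstimate:
    """Across-trial average firing rate.

    Equals the mean of the single-trial rates; computed as the kernel
    rate of the pooled spikes divided by the number of trains.
    """
    if not trains:
        raise ValueError("need at least one spike train")
    n = int(round(trains[0].duration * output_rate))
    counts = np.zeros(n)
    for tr in trains:
        c = _spike_counts(tr, output_rate)
        if c.size != n:
            raise ValueError("all trains must share one duration")
        counts += c
    kernel = _gauss_kernel(kernel_sigma, output_rate)
    vals = fftconvolve(counts / len(trains), kernel, mode="same")
    np.clip(vals, 0.0, None, out=vals)
    return RateEstimate(SampledSignal(vals, output_rate), kernel_sigma, len(trains))


def vector_strength(
    train: SpikeTrain, eod_cycle_onsets: np.ndarray
) -> tuple[float, float]:
    """Phase locking of spikes to the carrier cycle.

    Each spike is assigned the phase ``2 pi (t - onset)/period`` of its
    enclosing cycle; the vector strength is the resultant length of the
    unit phase vectors divided by the spike count, the preferred phase
    their circular mean in ``[0, 2 pi)``.
    """
    onsets = np.asarray(eod_cycle_onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("need at least two cycle onsets")
    t = train.times
    idx = np.searchsorted(onsets, t, side="right") - 1
    valid = (idx >= 0) & (idx < onsets.size - 1)
    if not np.any(valid):
        raise ValueError("no spikes within the cycle-onset range")
    i = idx[valid]
    phases = 2.0 * np.pi * (t[valid] - onsets[i]) / (onsets[i + 1] - onsets[i])
    z = np.exp(-1j * phases).sum()
    vs = float(np.abs(z) / phases.size)
    preferred = float((-np.angle(z)) % (2.0 * np.pi))
    return vs, preferred


def cv_isi(train: SpikeTrain) -> float:
    """Coefficient of variation of the interspike intervals.

    Zero for clock-like firing, about one for Poisson firing.
    """
    if train.n_spikes < 3:
        raise ValueError("cv_isi needs at least 3 spikes")
    isis = train.isis()
    return float(isis.std() / isis.mean())


def burst_fraction(train: SpikeTrain, eod_period: float) -> float:
    """Fraction of ISIs shorter than 1.5 carrier periods."""
    if eod_period <= 0:
        raise ValueError("eod_period must be positive")
    if train.n_spikes < 2:
        raise ValueError("burst_fraction needs at least 2 spikes")
    isis = train.isis()
    return float(np.mean(isis < 1.5 * eod_period))


def response_modulation(avg_rate: RateEstimate) -> float:
    """Temporal standard deviation of the trial-averaged rate (Hz)."""
    return float(avg_rate.rate.values.std())


def response_variability(trial_rates: Sequence[RateEstimate]) -> float:
    """Across-trial sd of single-trial rates, averaged over time (Hz)."""
    if len(trial_rates) < 2:
        raise ValueError("need at least 2 trials")
    mats = [r.rate.values for r in trial_rates]
    n = mats[0].size
    if any(m.size != n for m in mats):
        raise ValueError("trial rates must share one grid")
    stack = np.vstack(mats)
    return float(np.sqrt(stack.var(axis=0, ddof=0).mean()))


def sta(
    trains: Sequence[SpikeTrain] | SpikeTrain,
    stimulus: SampledSignal,
    window: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-triggered average of the stimulus.

    Returns ``(lags, avg)`` where ``lags`` runs from ``-window`` to
    ``+window`` (lag = time relative to the spike; negative lags are
    stimulus history).  Only spikes whose full window lies inside the
    stimulus support contribute.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    fs = stimulus.sampling_rate
    w = int(round(window * fs))
    offsets = np.arange(-w, w + 1)
    s = stimulus.values
    segs_sum = np.zeros(offsets.size)
    count = 0
    for tr in trains:
        idx = np.round((tr.times - stimulus.t0) * fs).astype(int)
        idx = idx[(idx - w >= 0) & (idx + w < s.size)]
        for start in range(0, idx.size, 4096):
            block = idx[start : start + 4096]
            segs_sum += s[block[:, None] + offsets[None, :]].sum(axis=0)
        count += idx.size
    if count == 0:
        raise ValueError("no spikes with a full window inside the stimulus")
    return offsets / fs, segs_sum / count


def sta_delay(
    trains: Sequence[SpikeTrain] | SpikeTrain,
    stimulus: SampledSignal,
    window: float = 0.01,
) -> float:
    """Response delay from the STA peak (seconds).

    Positive delays mean the stimulus precedes the spike, i.e. the STA
    peaks at a negative lag.
    """
    lags, avg = sta(trains, stimulus, window)
    return float(-lags[np.argmax(avg)])


def cycle_onsets_from_carrier(
    carrier: SampledSignal, threshold_fraction: float = 0.0
) -> np.ndarray:
    """Rising-crossing times of a carrier waveform.

    ``threshold_fraction = 0`` detects rising zero crossings (the
    default for synthetic sinusoidal carriers); ``0.5`` detects rising
    crossings at half-maximum, appropriate for recorded non-sinusoidal
    carrier shapes.
    """
    v = carrier.values
    thresh = threshold_fraction * v.max()
    below = v[:-1] < thresh
    above = v[1:] >= thresh
    idx = np.nonzero(below & above)[0]
    # linear interpolation of the crossing time within the sample step
    frac = (thresh - v[idx]) / (v[idx + 1] - v[idx])
    return carrier.t0 + (idx + frac) / carrier.sampling_rate


def sine_cycle_onsets(frequency: float, duration: float) -> np.ndarray:
    """Rising zero-crossing times of a pure sine carrier ``sin(2 pi f t)``."""
    n = int(np.floor(duration * frequency)) + 1
    return np.arange(n) / frequency


@dataclass
class BaselineSummary:
    """Summary statistics of the spontaneous (baseline) activity."""

    firing_rate: float
    cv_isi: float
    burst_fraction: float
    vector_strength: float
    preferred_phase: float
    phase_delay: float


def baseline_summary(
    train: SpikeTrain, eod_frequency: float, eod_cycle_onsets: np.ndarray | None = None
) -> BaselineSummary:
    """Compute the full baseline characterization of one spike train.

    ``phase_delay`` converts the preferred phase into an absolute delay
    after the cycle onset, ``preferred_phase / (2 pi f)`` seconds.
    """
    if eod_cycle_onsets is None:
        eod_cycle_onsets = sine_cycle_onsets(eod_frequency, train.duration)
    vs, phase = vector_strength(train, eod_cycle_onsets)
    return BaselineSummary(
        firing_rate=train.mean_rate,
        cv_isi=cv_isi(train),
        burst_fraction=burst_fraction(train, 1.0 / eod_frequency),
        vector_strength=vs,
        preferred_phase=phase,
        phase_delay=phase / (2.0 * np.pi * eod_frequency),
    )
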
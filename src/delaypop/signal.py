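"""Core containers: uniformly sampled waveforms and spike trains.

Every waveform in the package (stimulus, electric-organ carrier, firing
rate) is represented as a :class:`SampledSignal` — samples on a uniform
grid with an explicit sampling rate.  Spike responses are
:class:`SpikeTrain` objects holding spike times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SampledSignal", "SpikeTrain"]


@dataclass
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : ndarray
        Sample values.
    sampling_rate : float
        Samples per second (Hz).
    t0 : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be 1-D")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate

    def copy_with(self, values: np.ndarray) -> "SampledSignal":
        return SampledSignal(values, self.sampling_rate, self.t0)

    def interp_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the waveform at arbitrary times."""
        return np.interp(t, self.times, self.values)


@dataclass
class SpikeTrain:
    """Spike times (seconds) of one trial of one cell.

    Times are strictly increasing and lie within ``[0, duration]``.
    """

    times: np.ndarray
    duration: float
    cell_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def mean_rate(self) -> float:
        return self.times.size / self.duration

    def shifted(self, delay: float) -> "SpikeTrain":
        """Rigidly shift all spikes by ``delay`` seconds.

        Spikes shifted outside ``[0, duration]`` are dropped, mirroring
        what happens at the edges of a finite recording.
        """
        t = self.times + delay
        t = t[(t >= 0.0) & (t <= self.duration)]
        return replace(self, times=t)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)
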
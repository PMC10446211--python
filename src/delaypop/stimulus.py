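"""Frozen band-limited Gaussian noise stimuli and amplitude modulation.

Random amplitude modulations (RAMs) of a quasi-sinusoidal carrier are the
standard probe for amplitude-coding electroreceptor afferents: a frozen
band-limited Gaussian noise waveform multiplies the carrier so that the
envelope fluctuates with a defined contrast around the unperturbed field
amplitude.

The noise is synthesised in the frequency domain — Fourier coefficients
are drawn as complex Gaussians inside the pass band and zeroed outside —
which gives exact band edges; the time-domain trace is then rescaled to
the requested standard deviation.  Identical seeds reproduce identical
("frozen") waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import SampledSignal

__all__ = ["StimulusSpec", "generate_band_noise", "generate_am_stimulus", "sine_carrier"]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a frozen band-limited Gaussian noise waveform.

    ``band_low``/``band_high`` delimit the pass band in Hz, ``sigma`` is
    the standard deviation of the generated trace and ``seed`` freezes
    the realization.
    """

    duration: float
    sampling_rate: float
    band_low: float
    band_high: float
    sigma: float
    seed: int

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        nyquist = self.sampling_rate / 2.0
        if not (0 <= self.band_low < self.band_high):
            raise ValueError("need 0 <= band_low < band_high")
        if self.band_high > nyquist:
            raise ValueError(
                f"band_high={self.band_high} Hz exceeds the Nyquist "
                f"frequency {nyquist} Hz"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def generate_band_noise(spec: StimulusSpec) -> SampledSignal:
    """Generate frozen band-limited Gaussian noise.

    The output is zero-mean with standard deviation exactly
    ``spec.sigma``; spectral power outside ``[band_low, band_high]`` is
    zero up to the DC correction from mean removal.
    """
    spec.validate()
    n = int(round(spec.duration * spec.sampling_rate))
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    coeffs = np.zeros(freqs.size, dtype=complex)
    band = (freqs >= spec.band_low) & (freqs <= spec.band_high) & (freqs > 0)
    m = int(band.sum())
    if m == 0:
        raise ValueError("pass band contains no Fourier frequencies")
    coeffs[band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(coeffs, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0 and spec.sigma > 0:
        x *= spec.sigma / sd
    elif spec.sigma == 0:
        x = np.zeros(n)
    return SampledSignal(x, spec.sampling_rate)


def generate_am_stimulus(
    carrier: SampledSignal, am: SampledSignal, contrast: float
) -> SampledSignal:
    """Multiply a carrier with a noise envelope of a given contrast.

    The amplitude modulation ``am`` is normalised to unit standard
    deviation, so the induced envelope fluctuates with a standard
    deviation of ``contrast`` times the unperturbed carrier amplitude.
    A constant ``am`` (zero variance) is taken to be already expressed
    in units of its standard deviation.
    """
    if carrier.n_samples != am.n_samples or carrier.sampling_rate != am.sampling_rate:
        raise ValueError("carrier and AM must share the same sampling grid")
    sd = am.values.std()
    normalized = am.values / sd if sd > 0 else am.values
    return carrier.copy_with(carrier.values * (1.0 + contrast * normalized))


def sine_carrier(
    frequency: float, duration: float, sampling_rate: float, amplitude: float = 1.0
) -> SampledSignal:
    """Sinusoidal stand-in for the electric-organ discharge carrier."""
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    return SampledSignal(amplitude * np.sin(2.0 * np.pi * frequency * t), sampling_rate)
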
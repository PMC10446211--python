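"""Welch cross-spectra, transfer function, coherence and mutual information.

The stimulus–response transfer function is H(f) = P_sr(f) / P_ss(f) and
the squared coherence is

    gamma^2(f) = |P_sr(f)|^2 / (P_ss(f) P_rr(f)),

with all spectra averaged over overlapping, Hann-windowed,
mean-detrended segments pooled across trials.  The coherence yields a
lower bound on the mutual information rate between stimulus and
response,

    MI = - integral log2(1 - gamma^2(f)) df   [bit/s],

taken over the stimulated band.  Cross-spectrum convention: for a
response that lags the stimulus by d the phase of H is ``-2 pi f d``
(phase decreases with frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal

__all__ = [
    "SpectralEstimate",
    "CodingSummary",
    "welch_spectra",
    "transfer_function",
    "coherence",
    "lower_bound_mi",
    "band_mi",
    "cutoff_frequencies",
    "smooth_spectrum",
    "coding_summary",
]

#: coherence is clipped at 1 - _COH_EPS before the log
_COH_EPS = 1e-12


@dataclass
class SpectralEstimate:
    """Per-frequency values on a uniform nonnegative frequency grid."""

    frequencies: np.ndarray
    values: np.ndarray
    n_segments: int
    segment_length: int
    overlap: float = 0.5
    window: str = "hann"

    def copy_with(self, values: np.ndarray) -> "SpectralEstimate":
        return SpectralEstimate(
            self.frequencies, values, self.n_segments, self.segment_length,
            self.overlap, self.window,
        )


@dataclass
class CodingSummary:
    """Headline encoding numbers extracted from the spectral estimates."""

    mutual_information: float
    lower_cutoff: float
    upper_cutoff: float
    peak_gain: float


def _as_array(x) -> tuple[np.ndarray, float]:
    if isinstance(x, SampledSignal):
        return x.values, x.sampling_rate
    raise TypeError("expected a SampledSignal")


def _segment_count(n: int, nperseg: int, overlap: float) -> int:
    step = int(round(nperseg * (1.0 - overlap)))
    if n < nperseg:
        return 0
    return (n - nperseg) // step + 1


def welch_spectra(
    x: SampledSignal,
    y_trials: Sequence[SampledSignal] | SampledSignal,
    nperseg: int = 2**15,
    overlap: float = 0.5,
    window: str = "hann",
):
    """Segment-averaged auto- and cross-spectral densities.

    Segments of ``nperseg`` samples with the given fractional overlap
    are mean-detrended, windowed and pooled across all trials, so that
    the cross-spectrum is the grand average over every segment of every
    trial.

    Returns ``(Pxx, Pyy, Pxy)`` as :class:`SpectralEstimate` objects
    (Pxx, Pyy real; Pxy complex).
    """
    if isinstance(y_trials, SampledSignal):
        y_trials = [y_trials]
    if not y_trials:
        raise ValueError("need at least one response trial")
    xv, fs = _as_array(x)
    noverlap = int(round(nperseg * overlap))
    nseg_x = _segment_count(xv.size, nperseg, overlap)
    if nseg_x < 1:
        raise ValueError(
            f"signal of {xv.size} samples is shorter than one segment ({nperseg})"
        )
    freqs, pxx = sps.welch(
        xv, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    pyy_acc = np.zeros_like(pxx)
    pxy_acc = np.zeros(pxx.size, dtype=complex)
    total_segments = 0
    for y in y_trials:
        yv, fs_y = _as_array(y)
        if fs_y != fs:
            raise ValueError("stimulus and response sampling rates differ")
        if yv.size != xv.size:
            raise ValueError("stimulus and response must have equal length")
        nseg = _segment_count(yv.size, nperseg, overlap)
        _, pyy = sps.welch(
            yv, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend="constant",
        )
        _, pxy = sps.csd(
            xv, yv, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend="constant",
        )
        pyy_acc += pyy * nseg
        pxy_acc += pxy * nseg
        total_segments += nseg
    pyy_acc /= total_segments
    pxy_acc /= total_segments
    mk = lambda v: SpectralEstimate(freqs, v, total_segments, nperseg, overlap, window)
    return mk(pxx), mk(pyy_acc), mk(pxy_acc)


def transfer_function(
    stimulus: SampledSignal,
    response_trials: Sequence[SampledSignal] | SampledSignal,
    nperseg: int = 2**15,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Stimulus–response transfer function H(f) = P_sr / P_ss (complex).

    Frequencies where the stimulus has no power are masked with NaN.
    """
    pxx, _, pxy = welch_spectra(stimulus, response_trials, nperseg, overlap, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(pxx.values > 0, pxy.values / pxx.values, np.nan + 0j)
    return pxx.copy_with(h)


def coherence(
    stimulus: SampledSignal,
    response_trials: Sequence[SampledSignal] | SampledSignal,
    nperseg: int = 2**15,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Squared stimulus–response coherence, in [0, 1] per frequency."""
    pxx, pyy, pxy = welch_spectra(stimulus, response_trials, nperseg, overlap, window)
    denom = pxx.values * pyy.values
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(pxy.values) ** 2 / denom, 0.0)
    return pxx.copy_with(np.clip(coh, 0.0, 1.0))


def lower_bound_mi(
    coh: SpectralEstimate, f_low: float = 0.0, f_high: float = 300.0
) -> float:
    """Lower-bound mutual information rate in bit/s.

    Trapezoidal integral of ``-log2(1 - gamma^2)`` over
    ``[f_low, f_high]``, with the integrand linearly interpolated at the
    band edges.  Coherence is clipped just below one as a numerical
    guard.
    """
    if f_high <= f_low:
        raise ValueError("f_high must exceed f_low")
    f = coh.frequencies
    g = np.clip(np.nan_to_num(coh.values.real), 0.0, 1.0 - _COH_EPS)
    lo = max(f_low, f[0])
    hi = min(f_high, f[-1])
    if hi <= lo:
        raise ValueError("integration range does not overlap the frequency grid")
    inside = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inside], [hi]))
    integrand = -np.log2(1.0 - np.interp(grid, f, g))
    return float(np.trapezoid(integrand, grid))


def band_mi(
    coh: SpectralEstimate, bands: Sequence[tuple[float, float]]
) -> list[float]:
    """Lower-bound MI restricted to each of several disjoint bands."""
    bands = sorted(bands)
    for (a, b), (c, d) in zip(bands, bands[1:]):
        if c < b:
            raise ValueError(f"bands ({a},{b}) and ({c},{d}) overlap")
    return [lower_bound_mi(coh, lo, hi) for lo, hi in bands]


def smooth_spectrum(spectrum: SpectralEstimate, n_points: int = 11) -> SpectralEstimate:
    """Centered running average; the window truncates at the edges."""
    if n_points < 1 or n_points % 2 == 0:
        raise ValueError("n_points must be a positive odd number")
    if n_points == 1:
        return spectrum.copy_with(spectrum.values.copy())
    v = spectrum.values
    half = n_points // 2
    c = np.cumsum(np.concatenate(([0.0], v)))
    n = v.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (c[hi] - c[lo]) / (hi - lo)
    return spectrum.copy_with(out)


@dataclass
class CutoffResult:
    lower: float
    upper: float
    lower_flagged: bool = False
    upper_flagged: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))


def cutoff_frequencies(
    spectrum: SpectralEstimate, mode: str = "gain"
) -> CutoffResult:
    """Lower and upper cutoff frequencies of a gain or coherence curve.

    Scanning outward from the curve's peak, the cutoffs are the first
    frequencies at which the curve falls below ``max/sqrt(2)`` (-3 dB,
    ``mode='gain'``) or ``max/2`` (``mode='coherence'``), with linear
    interpolation between grid points.  If the curve never falls below
    the threshold on one side, that cutoff is reported at the range edge
    and flagged.
    """
    if mode not in ("gain", "coherence"):
        raise ValueError("mode must be 'gain' or 'coherence'")
    f = spectrum.frequencies
    v = np.abs(np.nan_to_num(spectrum.values))
    if not np.any(np.isfinite(v)):
        raise ValueError("spectrum has no finite values")
    ipeak = int(np.argmax(v))
    thresh = v[ipeak] / (np.sqrt(2.0) if mode == "gain" else 2.0)

    def scan(direction: int) -> tuple[float, bool]:
        i = ipeak
        while 0 <= i + direction < v.size:
            j = i + direction
            if v[j] < thresh:
                # interpolate the crossing between i and j
                frac = (v[i] - thresh) / (v[i] - v[j])
                return float(f[i] + frac * (f[j] - f[i])), False
            i = j
        return float(f[0] if direction < 0 else f[-1]), True

    lower, lflag = scan(-1)
    upper, uflag = scan(+1)
    return CutoffResult(lower, upper, lflag, uflag)


def coding_summary(
    stimulus: SampledSignal,
    response_trials: Sequence[SampledSignal] | SampledSignal,
    f_low: float = 0.0,
    f_high: float = 300.0,
    nperseg: int = 2**15,
    smooth_points: int = 11,
) -> CodingSummary:
    """One-call characterization: MI, transfer-function cutoffs, peak gain."""
    h = transfer_function(stimulus, response_trials, nperseg=nperseg)
    gain = smooth_spectrum(h.copy_with(np.abs(h.values)), smooth_points)
    cut = cutoff_frequencies(gain, mode="gain")
    coh = coherence(stimulus, response_trials, nperseg=nperseg)
    mi = lower_bound_mi(coh, f_low, f_high)
    return CodingSummary(
        mutual_information=mi,
        lower_cutoff=cut.lower,
        upper_cutoff=cut.upper,
        peak_gain=float(np.nanmax(np.abs(gain.values))),
    )
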
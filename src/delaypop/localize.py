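"""Receptor localization, phase unwrapping and conduction-velocity estimation.

A receptor's position on the body is found by scanning a local dipole
stimulus along the rostro-caudal axis: at each dipole position the
power of the firing rate at the stimulation frequency is extracted and
a Gaussian (with additive baseline) is fitted to power versus position;
the fitted center is the receptor location.

Because afferent spikes are tightly phase-locked to the carrier, the
preferred firing phase grows linearly with the receptor's distance from
the recording site — phases wrap at one carrier cycle, so the wrapped
cloud is split by K-means into a rostral and a caudal cluster and the
caudal cluster is shifted by 2 pi before regressing delay on position.
The inverse slope of the regression of absolute delay on absolute
position is the axonal conduction velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .metrics import RateEstimate

__all__ = [
    "PositionScan",
    "PhasePositionDataset",
    "LocalizationError",
    "power_at_frequency",
    "estimate_position",
    "cluster_and_unwrap",
    "velocity_from_delays",
    "correlate_with_position",
]


class LocalizationError(RuntimeError):
    """Raised when a dipole scan cannot be localized."""


@dataclass
class PositionScan:
    """Firing-rate power at the stimulation frequency per dipole position."""

    positions: np.ndarray
    response_powers: np.ndarray
    am_frequency: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.response_powers = np.asarray(self.response_powers, dtype=float)
        if self.positions.size != self.response_powers.size:
            raise ValueError("positions and powers must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.response_powers < 0):
            raise ValueError("powers must be nonnegative")


def power_at_frequency(
    rate: RateEstimate,
    f: float,
    segment_duration: float = 1.0,
    overlap: float = 0.5,
) -> float:
    """Welch power of a firing rate at the grid frequency nearest ``f``.

    Segments of ``segment_duration`` (Hann window, mean detrended, 50%
    overlap by default) follow the standard dipole-scan analysis.
    """
    from scipy.signal import welch

    fs = rate.rate.sampling_rate
    nperseg = int(round(segment_duration * fs))
    if rate.rate.n_samples < nperseg:
        raise ValueError(
            "rate shorter than one segment; reduce segment_duration"
        )
    freqs, pxx = welch(
        rate.rate.values, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant",
    )
    return float(pxx[np.argmin(np.abs(freqs - f))])


def _gauss_baseline(x, center, width, amplitude, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)


def estimate_position(scan: PositionScan) -> tuple[float, float, float]:
    """Receptor position from a Gaussian fit to power versus position.

    Returns ``(center, width, r_squared)`` of the least-squares fit of a
    Gaussian with additive baseline.  Intensity scaling of the scan does
    not move the fitted center.
    """
    x, p = scan.positions, scan.response_powers
    if x.size < 4:
        raise LocalizationError("need at least 4 scan positions")
    span = p.max() - p.min()
    if span <= 0:
        raise LocalizationError("flat scan: no dynamic range to localize")
    spacing = np.median(np.diff(x))
    p0 = [x[np.argmax(p)], 2.0 * spacing, span, p.min()]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_baseline, x, p, p0=p0,
            bounds=(
                [x[0] - (x[-1] - x[0]), spacing * 0.1, 0.0, 0.0],
                [x[-1] + (x[-1] - x[0]), (x[-1] - x[0]) * 2.0, np.inf, p.max()],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise LocalizationError(f"Gaussian fit failed: {exc}") from exc
    resid = p - _gauss_baseline(x, *popt)
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    center, width = float(popt[0]), float(abs(popt[1]))
    if not x[0] - spacing <= center <= x[-1] + spacing:
        raise LocalizationError(
            f"fitted center {center:.3g} outside the scanned range "
            f"[{x[0]:.3g}, {x[-1]:.3g}]"
        )
    return center, width, r2


@dataclass
class PhasePositionDataset:
    """Phase/position data after clustering and unwrapping."""

    phases: np.ndarray            # unwrapped preferred phases, radians
    positions: np.ndarray         # meters from the snout
    delays: np.ndarray            # absolute delays, seconds
    cluster_labels: np.ndarray
    shifted: bool                 # whether the caudal cluster was shifted by 2 pi
    slope: float = np.nan         # regression of phase on position
    intercept: float = np.nan


def cluster_and_unwrap(
    phases: np.ndarray,
    positions: np.ndarray,
    eod_frequencies: np.ndarray | float,
    seed: int = 0,
) -> PhasePositionDataset:
    """Split wrapped phases into two clusters and unwrap the caudal one.

    K-means (k = 2, 10 restarts, seeded) runs on per-axis standardized
    (phase, position) points.  The cluster with the larger mean position
    is taken as caudal; if its mean phase lies *below* the rostral
    cluster's — the signature of a 2 pi wrap, since phase must increase
    with distance — 2 pi is added to its phases.  Already-monotone data
    is returned unchanged, which makes the operation idempotent.

    ``eod_frequencies`` (scalar or per-cell) convert the unwrapped
    phases into absolute delays ``phase / (2 pi f)``.
    """
    phases = np.asarray(phases, dtype=float)
    positions = np.asarray(positions, dtype=float)
    f = np.broadcast_to(np.asarray(eod_frequencies, dtype=float), phases.shape)
    if phases.size < 4:
        raise ValueError("need at least 4 cells")
    pts = np.column_stack([phases, positions])
    std = pts.std(axis=0)
    std[std == 0] = 1.0
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict((pts - pts.mean(axis=0)) / std)
    mean_pos = [positions[labels == k].mean() for k in (0, 1)]
    caudal = int(np.argmax(mean_pos))
    rostral = 1 - caudal
    mean_phase_caudal = phases[labels == caudal].mean()
    mean_phase_rostral = phases[labels == rostral].mean()
    unwrapped = phases.copy()
    shifted = False
    if mean_phase_caudal < mean_phase_rostral:
        unwrapped[labels == caudal] += 2.0 * np.pi
        shifted = True
    # residual pass: phase must grow with position, so a *downward* jump
    # of more than pi along the position-sorted sequence is a residual
    # wrap (the intrinsic phase offset can put two wrap points inside the
    # sampled range); upward jumps are left alone — they may be genuine
    # gaps between sparse clusters
    order = np.argsort(positions, kind="stable")
    u = unwrapped[order]
    d = np.diff(u)
    correction = np.concatenate(
        ([0.0], np.cumsum(np.where(d < -np.pi, 2.0 * np.pi, 0.0)))
    )
    unwrapped[order] = u + correction
    unwrapped -= 2.0 * np.pi * np.floor(unwrapped.min() / (2.0 * np.pi))
    delays = unwrapped / (2.0 * np.pi * f)
    slope, intercept = np.polyfit(positions, unwrapped, 1)
    return PhasePositionDataset(
        unwrapped, positions, delays, labels, shifted,
        slope=float(slope), intercept=float(intercept),
    )


def velocity_from_delays(
    positions: np.ndarray, delays: np.ndarray
) -> tuple[float, float, float]:
    """Conduction velocity from the regression of delay on position.

    Ordinary least squares ``delay = a + b * position``; the velocity is
    ``1/b``.  Returns ``(velocity_m_per_s, pearson_r, p_value)``.  A
    constant offset in the delays (e.g. a common synaptic latency) is
    absorbed by the intercept.
    """
    positions = np.asarray(positions, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if positions.size < 3:
        raise ValueError("need at least 3 points")
    if positions.std() == 0:
        raise ValueError("positions have no spread")
    res = stats.linregress(positions, delays)
    if res.slope <= 0:
        raise ValueError(
            f"non-positive delay-vs-position slope ({res.slope:.3g} s/m) "
            "gives no physical conduction velocity"
        )
    return float(1.0 / res.slope), float(res.rvalue), float(res.pvalue)


def correlate_with_position(
    features: dict[str, np.ndarray],
    positions: np.ndarray,
    n_tests: int | None = None,
) -> "pd.DataFrame":
    """Pearson correlation of each feature with receptor position.

    Two-sided p-values are Bonferroni corrected by multiplying with
    ``n_tests`` (default: the number of features) and capping at 1.
    Zero-variance features are flagged with ``r = NaN``.
    """
    import pandas as pd

    positions = np.asarray(positions, dtype=float)
    if n_tests is None:
        n_tests = len(features)
    if n_tests < len(features):
        raise ValueError("n_tests must cover at least the listed features")
    rows = []
    for name, values in features.items():
        values = np.asarray(values, dtype=float)
        if values.size != positions.size:
            raise ValueError(f"feature {name!r} length mismatch")
        if values.std() == 0:
            rows.append({"feature": name, "r": np.nan, "p_bonferroni": np.nan,
                         "flagged": True})
            continue
        r, p = stats.pearsonr(values, positions)
        rows.append(
            {
                "feature": name,
                "r": float(r),
                "p_bonferroni": min(1.0, float(p) * n_tests),
                "flagged": False,
            }
        )
    return pd.DataFrame(rows)
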
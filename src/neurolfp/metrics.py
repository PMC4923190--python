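"""Analysis utilities: peak amplitudes, attenuation curves, spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    ConfigurationError,
    DataError,
    ElectrodeArray,
    Electrode,
    LFPTrace,
    Medium,
    Point3,
    SourceSet,
)
from .forward import compute_lfp


def peak_amplitude(trace: LFPTrace, window: tuple[float, float]):
    """Signed extremum of largest magnitude inside a time window.

    The pre-window mean (baseline) is subtracted first; if the window
    starts at the beginning of the trace the baseline is the first sample.
    Returns a scalar for a single-electrode trace, else one value per
    electrode.
    """
    t_min, t_max = window
    mask = (trace.time >= t_min) & (trace.time <= t_max)
    if not mask.any():
        raise DataError(f"empty window [{t_min}, {t_max}] ms")
    pre = trace.time < t_min
    baseline = (
        trace.values[:, pre].mean(axis=1) if pre.any() else trace.values[:, 0]
    )
    seg = trace.values[:, mask] - baseline[:, None]
    idx = np.argmax(np.abs(seg), axis=1)
    peaks = seg[np.arange(seg.shape[0]), idx]
    return float(peaks[0]) if trace.n_electrodes == 1 else peaks


def detect_negative_peaks(
    trace: LFPTrace,
    onset: float,
    window_ms: float = 25.0,
    min_prominence_frac: float = 0.10,
    electrode: int = 0,
) -> np.ndarray:
    """Times (ms) of negative deflections after a stimulus.

    Peaks are found on the baseline-subtracted, sign-flipped trace within
    ``[onset, onset + window_ms]``; the prominence threshold is the given
    fraction of the global extremum magnitude. This is the evoked-wave
    (N-wave) detection rule used by the granular-layer demos.
    """
    pre = trace.time < onset
    baseline = trace.values[electrode, pre].mean() if pre.any() else trace.values[electrode, 0]
    y = trace.values[electrode] - baseline
    prominence = min_prominence_frac * np.abs(y).max()
    idx, _ = signal.find_peaks(-y, prominence=prominence)
    t = trace.time[idx]
    keep = (t >= onset) & (t <= onset + window_ms) & (y[idx] < 0)
    return t[keep]


@dataclass
class AttenuationCurve:
    """Peak LFP magnitude versus recording distance, per method."""

    distances: np.ndarray  # um, strictly increasing
    amplitudes: dict[str, np.ndarray]  # method -> |uV| per distance

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if not np.all(np.diff(self.distances) > 0):
            raise DataError("distances must be strictly increasing")
        for m, a in self.amplitudes.items():
            if not np.all(np.isfinite(a)):
                raise DataError(f"non-finite amplitudes for method {m}")

    def loglog_slope(self, method: str) -> float:
        a = self.amplitudes[method]
        if np.any(a <= 0):
            raise DataError("cannot fit a log-log slope through zero amplitudes")
        return float(np.polyfit(np.log(self.distances), np.log(a), 1)[0])


def attenuation_curve(
    sources: SourceSet,
    direction,
    distances,
    medium: Medium,
    methods=("psa", "lsa"),
) -> AttenuationCurve:
    """Peak amplitude versus distance along a ray from the source centroid."""
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < medium.min_distance):
        raise ConfigurationError("all distances must be >= medium.min_distance")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ConfigurationError("direction must be a nonzero vector")
    d = d / norm
    centroid = sources.midpoints().mean(axis=0)
    electrodes = ElectrodeArray(
        [
            Electrode(Point3(*(centroid + r * d)), f"d{i}")
            for i, r in enumerate(distances)
        ]
    )
    amplitudes = {}
    for method in methods:
        trace = compute_lfp(sources, electrodes, medium, method)
        peaks = np.abs(trace.values).max(axis=1)
        amplitudes[method] = peaks
    return AttenuationCurve(distances, amplitudes)


def periodogram(trace: LFPTrace, electrode: int = 0):
    """Hann-windowed FFT periodogram of one electrode's trace.

    Returns (frequencies in Hz, power). Bin width is 1/duration.
    """
    fs = 1000.0 / trace.dt  # Hz
    freqs, power = signal.periodogram(
        trace.values[electrode], fs=fs, window="hann", detrend="constant"
    )
    return freqs, power


def dominant_frequency(
    trace: LFPTrace, f_min: float, f_max: float, electrode: int = 0
) -> float:
    """Frequency (Hz) of the maximum periodogram power within [f_min, f_max].

    Requires the trace to span at least 8 cycles of ``f_min``.
    """
    duration_s = trace.time.size * trace.dt / 1000.0  # signal duration
    if duration_s < 8.0 / f_min:
        raise DataError(
            f"trace of {duration_s * 1000:.0f} ms is shorter than 8 cycles of {f_min} Hz"
        )
    freqs, power = periodogram(trace, electrode)
    band = (freqs >= f_min) & (freqs <= f_max)
    if not band.any():
        raise DataError("no spectral bins inside the requested band")
    return float(freqs[band][np.argmax(power[band])])


def spectral_peak_ratio(
    trace: LFPTrace, f_min: float, f_max: float, electrode: int = 0
) -> float:
    """Band maximum power divided by the median power over all bins > 0 Hz.

    Used to decide whether a spectrum has a genuine peak (ratio > 3) or is
    flat/noise-like. The spectrum is a Welch estimate (Hann window, linear
    detrend, eight segments) so that single-bin fluctuations of a flat
    spectrum are averaged down and do not register as peaks.
    """
    fs = 1000.0 / trace.dt
    y = trace.values[electrode]
    nperseg = max(16, y.size // 8)
    freqs, power = signal.welch(y, fs=fs, window="hann", nperseg=nperseg, detrend="linear")
    band = (freqs >= f_min) & (freqs <= f_max)
    if not band.any():
        raise DataError("no spectral bins inside the requested band")
    # a (numerically) constant trace has no peak: everything below the
    # float rounding floor of the signal's own scale counts as zero power
    floor = 1e-20 * np.mean(y**2)
    if power[band].max() <= floor:
        return 0.0
    med = np.median(power[freqs > 0])
    if med == 0:
        return np.inf if power[band].max() > 0 else 0.0
    return float(power[band].max() / med)
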
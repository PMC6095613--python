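"""Band-limited phase preprocessing for continuous entrainment analysis.

Turns raw audio / time-series into the representations the information
estimators consume: a wideband amplitude envelope computed over
cochlear-spaced sub-bands, zero-phase band-pass analytic signals, and the
2D unit-circle phase representation used by the copula-based estimators.

All filtering is fourth-order Butterworth applied forward and reverse
(zero phase).  Sampling is 0-based; a positive lag means the neural
signal FOLLOWS the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "AnalyticBandSignal",
    "PhaseRepr",
    "cochlear_band_edges",
    "wideband_envelope",
    "bandpass_analytic",
    "phase_2d",
    "lag_align",
    "trim_edges",
]

# Greenwood cochlear position function f(x) = A (10**(a x) - k), x in [0, 1]
# from base to apex of the human cochlea.  Constants are overridable.
GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal."""

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("TimeSeries requires a 1-D array of length >= 2")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class AnalyticBandSignal:
    """Complex analytic signal restricted to a frequency band."""

    values: np.ndarray
    fs: float
    band_center: float
    band_halfwidth: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.band_center - self.band_halfwidth <= 0:
            raise ValueError("band must lie strictly above 0 Hz")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("analytic signal contains non-finite values")


@dataclass
class PhaseRepr:
    """Instantaneous phase as points (x, y) on the unit circle.

    Samples where the analytic amplitude is exactly zero have undefined
    phase; they are flagged in ``defined`` and must be dropped pairwise
    by downstream estimators.
    """

    x: np.ndarray
    y: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = np.ones(len(self.x), dtype=bool)


def greenwood_position(f: np.ndarray | float) -> np.ndarray | float:
    """Cochlear place (0 = apex) of frequency ``f`` in Hz."""
    return np.log10(np.asarray(f) / GREENWOOD_A + GREENWOOD_K) / GREENWOOD_ALPHA


def greenwood_frequency(x: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`greenwood_position`."""
    return GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * np.asarray(x)) - GREENWOOD_K)


def cochlear_band_edges(n_bands: int, f_lo: float = 100.0, f_hi: float = 10_000.0) -> np.ndarray:
    """Band edges equidistant on the cochlear (Greenwood) map.

    Returns ``n_bands + 1`` strictly increasing edge frequencies with
    ``edges[0] == f_lo`` and ``edges[-1] == f_hi``; successive edges are
    equally spaced in cochlear position, so bands widen with frequency.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    x = np.linspace(greenwood_position(f_lo), greenwood_position(f_hi), n_bands + 1)
    edges = np.asarray(greenwood_frequency(x), dtype=float)
    edges[0], edges[-1] = f_lo, f_hi  # exact endpoints
    return edges


def _butter_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is at or above the Nyquist frequency {nyq} Hz")
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def wideband_envelope(
    audio: TimeSeries,
    n_bands: int = 8,
    f_lo: float = 100.0,
    f_hi: float = 10_000.0,
    out_fs: float = 250.0,
) -> TimeSeries:
    """Wideband amplitude envelope of an acoustic signal.

    The audio is band-pass filtered into ``n_bands`` cochlear-spaced
    sub-bands (zero-phase fourth-order Butterworth), the analytic
    amplitude of each sub-band is taken via the Hilbert transform, the
    amplitudes are averaged across bands, and the result is resampled
    to ``out_fs`` with a polyphase anti-aliased resampler.
    """
    if audio.fs <= 2 * f_hi:
        raise ValueError(
            f"audio sampling rate {audio.fs} Hz cannot represent content up to "
            f"{f_hi} Hz (Nyquist limit {audio.fs / 2} Hz)"
        )
    edges = cochlear_band_edges(n_bands, f_lo, f_hi)
    acc = np.zeros_like(audio.values)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = _butter_sos(lo, hi, audio.fs)
        band = sps.sosfiltfilt(sos, audio.values)
        acc += np.abs(sps.hilbert(band))
    env = acc / n_bands
    if out_fs != audio.fs:
        ratio = Fraction(out_fs / audio.fs).limit_denominator(10_000)
        env = sps.resample_poly(env, ratio.numerator, ratio.denominator)
    # polyphase resampling can ring slightly below zero; an envelope is a magnitude
    env = np.clip(env, 0.0, None)
    return TimeSeries(env, out_fs, label=f"{audio.label}_envelope".lstrip("_"))


def bandpass_analytic(x: TimeSeries, center: float = 5.0, halfwidth: float = 2.0) -> AnalyticBandSignal:
    """Zero-phase band-pass then Hilbert analytic signal.

    Default band is centred at 5 Hz with half-width 2 Hz (3-7 Hz), the
    syllable-rate band in which audiovisual speech signals cohere.
    """
    if center - halfwidth <= 0:
        raise ValueError("band must lie strictly above 0 Hz")
    sos = _butter_sos(center - halfwidth, center + halfwidth, x.fs)
    filtered = sps.sosfiltfilt(sos, x.values - np.mean(x.values))
    return AnalyticBandSignal(sps.hilbert(filtered), x.fs, center, halfwidth)


def phase_2d(s: AnalyticBandSignal) -> PhaseRepr:
    """Normalize an analytic signal by its amplitude: phase on the unit circle."""
    amp = np.abs(s.values)
    defined = amp > 0
    safe = np.where(defined, amp, 1.0)
    return PhaseRepr(x=np.real(s.values) / safe, y=np.imag(s.values) / safe, defined=defined)


def lag_align(
    stimulus: np.ndarray, neural: np.ndarray, lag_ms: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Align a stimulus with neural activity that lags it by ``lag_ms``.

    Pairs ``stimulus[t]`` with ``neural[t + lag]`` and truncates the
    non-overlapping ends, so both outputs have equal length.
    """
    stimulus = np.asarray(stimulus)
    neural = np.asarray(neural)
    if lag_ms < 0:
        raise ValueError("lag must be non-negative (neural activity follows the stimulus)")
    k = int(round(lag_ms * fs / 1000.0))
    n = min(stimulus.shape[0], neural.shape[0])
    if k >= n:
        raise ValueError(f"lag of {k} samples exceeds series length {n}")
    if k == 0:
        return stimulus[:n], neural[:n]
    return stimulus[: n - k], neural[k:n]


def trim_edges(values: np.ndarray, fs: float, trim_s: float = 1.0) -> np.ndarray:
    """Drop ``trim_s`` seconds from each end (filter edge effects)."""
    k = int(round(trim_s * fs))
    if 2 * k >= values.shape[0]:
        raise ValueError("series too short to trim")
    return values[k : values.shape[0] - k]
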
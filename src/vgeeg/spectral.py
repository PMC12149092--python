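"""Welch power spectral density estimation and canonical band decomposition.

Every analysis window is decomposed into the five canonical EEG frequency
bands — delta (0.5–4 Hz), theta (4–8 Hz), alpha (8–12 Hz), beta (12–30 Hz)
and gamma (30–100 Hz) — and each band's ordered (frequency, power) sequence
is the object the visibility graph is later built on.

The default Welch configuration uses segments of ``2 * sampling_rate``
samples (0.5 Hz resolution), 50% overlap and a Hann taper.  At 0.5 Hz
resolution even the narrow delta band retains 8 bins, enough for a
non-degenerate visibility graph.  Band slicing operates on the Welch PSD of
the broadband signal by default; a zero-phase 4th-order Butterworth
band-pass applied in the time domain before Welch is available via
``time_domain_bandpass=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .eeg_io import Window

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BAND_ORDER",
    "PSDSequence",
    "WelchParams",
    "BandResolutionError",
    "welch_psd",
    "band_slice",
    "band_power",
    "band_psd_sequences",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float  # Hz, inclusive
    high: float  # Hz, inclusive

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    @property
    def center(self) -> float:
        """Geometric-mean frequency of the band edges."""
        return float(np.sqrt(self.low * self.high))


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)
BAND_ORDER = tuple(b.name for b in DEFAULT_BANDS)
_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def band_by_name(name: str) -> BandDefinition:
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown band {name!r}; choose from {BAND_ORDER}") from None


@dataclass(frozen=True)
class PSDSequence:
    """Ordered (frequency, power) pairs of one band, channel and window."""

    band: BandDefinition
    channel_label: str
    frequencies: np.ndarray  # Hz, strictly increasing
    powers: np.ndarray  # µV²/Hz, same length, nonnegative
    window_index: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.powers, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "powers", p)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and powers must be 1-D and equal length")
        if len(f) < 2:
            raise ValueError("PSD sequence needs at least 2 points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator configuration.

    Frequency resolution is ``sampling_rate / segment_length``.
    """

    segment_length: int
    overlap_fraction: float = 0.5
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2 samples")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.taper not in ("hann", "hamming", "boxcar"):
            raise ValueError(f"unknown taper {self.taper!r}")

    @classmethod
    def default(cls, sampling_rate: float) -> "WelchParams":
        return cls(segment_length=int(round(2 * sampling_rate)))


class BandResolutionError(ValueError):
    """Raised when a band retains fewer than 2 frequency bins."""


def welch_psd(
    window: Window, channel: int, params: WelchParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (density scaling, mean-detrended segments) of one
    channel of a window.  Returns ``(frequencies, powers)`` over 0..Nyquist."""
    params = params or WelchParams.default(window.sampling_rate)
    x = window.signal[channel]
    if params.segment_length > x.shape[-1]:
        raise ValueError(
            f"segment_length {params.segment_length} exceeds window length "
            f"{x.shape[-1]} samples"
        )
    freqs, psd = sps.welch(
        x,
        fs=window.sampling_rate,
        window=params.taper,
        nperseg=params.segment_length,
        noverlap=int(params.overlap_fraction * params.segment_length),
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def welch_psd_all_channels(
    window: Window, params: WelchParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of every channel at once; returns (freqs, (n_channels, n_freqs))."""
    params = params or WelchParams.default(window.sampling_rate)
    if params.segment_length > window.n_samples:
        raise ValueError(
            f"segment_length {params.segment_length} exceeds window length "
            f"{window.n_samples} samples"
        )
    freqs, psd = sps.welch(
        window.signal,
        fs=window.sampling_rate,
        window=params.taper,
        nperseg=params.segment_length,
        noverlap=int(params.overlap_fraction * params.segment_length),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_slice(
    freqs: np.ndarray,
    powers: np.ndarray,
    band: BandDefinition,
    channel_label: str = "",
    window_index: int = 0,
) -> PSDSequence:
    """Restrict a full-spectrum PSD to one band (edges inclusive; the upper
    edge is clipped to the Nyquist frequency of the estimate)."""
    nyquist = float(freqs[-1])
    high = min(band.high, nyquist)
    mask = (freqs >= band.low - 1e-12) & (freqs <= high + 1e-12)
    if int(mask.sum()) < 2:
        df = float(freqs[1] - freqs[0]) if len(freqs) > 1 else float("nan")
        raise BandResolutionError(
            f"band {band.name} ({band.low}-{band.high} Hz) retains "
            f"{int(mask.sum())} bins at resolution {df:g} Hz; "
            "increase segment_length"
        )
    return PSDSequence(band, channel_label, freqs[mask], powers[mask], window_index)


def band_power(seq: PSDSequence) -> float:
    """Integrated band power (µV²): trapezoidal integral of the PSD."""
    return float(np.trapezoid(seq.powers, seq.frequencies))


def bandpass_filter(
    x: np.ndarray, sampling_rate: float, band: BandDefinition, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``x`` along the last axis."""
    nyq = sampling_rate / 2
    low = band.low / nyq
    high = min(band.high, 0.99 * nyq) / nyq
    sos = sps.butter(order, [low, high], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def band_psd_sequences(
    window: Window,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    params: WelchParams | None = None,
    time_domain_bandpass: bool = False,
) -> dict[tuple[str, str], PSDSequence]:
    """PSD sequences for every (channel, band) of a window.

    Returns a dict keyed by ``(channel_label, band_name)``.  By default the
    broadband Welch spectrum is computed once per channel and sliced per
    band; with ``time_domain_bandpass`` each band is Butterworth-filtered in
    the time domain before its own Welch estimate.
    """
    params = params or WelchParams.default(window.sampling_rate)
    out: dict[tuple[str, str], PSDSequence] = {}
    if not time_domain_bandpass:
        freqs, psd = welch_psd_all_channels(window, params)
        for ci, clab in enumerate(window.channel_labels):
            for band in bands:
                out[(clab, band.name)] = band_slice(
                    freqs, psd[ci], band, clab, window.window_index
                )
        return out
    for band in bands:
        filtered = bandpass_filter(window.signal, window.sampling_rate, band)
        freqs, psd = sps.welch(
            filtered,
            fs=window.sampling_rate,
            window=params.taper,
            nperseg=params.segment_length,
            noverlap=int(params.overlap_fraction * params.segment_length),
            detrend="constant",
            scaling="density",
            axis=-1,
        )
        for ci, clab in enumerate(window.channel_labels):
            out[(clab, band.name)] = band_slice(
                freqs, psd[ci], band, clab, window.window_index
            )
    return out
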
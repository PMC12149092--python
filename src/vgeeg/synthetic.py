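"""Synthetic EEG cohort generator.

Emulates the structure of small clinical resting-state EEG cohorts: a
balanced (or user-sized) two-class set of multi-channel recordings in which
each channel is a sum of band-limited oscillations — one sinusoid per
canonical band, at the band's geometric-mean frequency, with class-dependent
amplitude — on top of 1/f^beta Gaussian background noise.  Class membership
is encoded purely in the per-band oscillation amplitudes, so the expected
band-power contrast between classes is the squared amplitude ratio.

The generator is fully deterministic: the same :class:`CohortSpec` (which
includes the seed) always produces bit-identical cohorts, and each
(class, subject) pair draws from its own independent random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eeg_io import Recording
from .spectral import BAND_ORDER, DEFAULT_BANDS, band_by_name

__all__ = ["CohortSpec", "generate_recording", "generate_cohort",
           "alpha_contrast_spec", "shape_contrast_spec"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-class synthetic EEG cohort.

    ``band_amplitudes_per_class`` maps a band name to its oscillation
    amplitude (µV) in each class, ``(class 0, class 1)``.  Bands absent from
    the map carry no oscillation.  ``noise_exponent`` is the power-law
    exponent beta of the 1/f^beta background; ``noise_scale`` is its
    standard deviation in µV.
    """

    n_subjects_per_class: int = 7
    n_channels: int = 14
    sampling_rate: float = 128.0
    duration: float = 120.0  # seconds
    band_amplitudes_per_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (1.0, 1.0)}
    )
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration x sampling_rate = {n} is not an integer sample count"
            )
        for name, amps in self.band_amplitudes_per_class.items():
            band = band_by_name(name)
            if len(amps) != 2:
                raise ValueError(f"band {name!r}: need (class0, class1) amplitudes")
            if any(a < 0 for a in amps):
                raise ValueError(f"band {name!r}: amplitudes must be >= 0")
            if max(amps) > 0 and self.sampling_rate <= 2 * band.high:
                raise ValueError(
                    f"sampling rate {self.sampling_rate} Hz is below the Nyquist "
                    f"requirement for band {name!r} (upper edge {band.high} Hz); "
                    f"need > {2 * band.high} Hz"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))


def _one_over_f_noise(
    rng: np.random.Generator, n: int, beta: float, scale: float
) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f^beta.

    White Gaussian noise is shaped in the frequency domain by f^(-beta/2)
    (the DC bin is zeroed) and renormalized to standard deviation ``scale``.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-beta / 2)
    shaped = np.fft.irfft(spec * shaping, n=n)
    sd = shaped.std()
    if sd > 0:
        shaped *= scale / sd
    return shaped


def generate_recording(
    spec: CohortSpec, class_index: int, subject_index: int
) -> Recording:
    """Generate one subject's recording.

    Each channel is the sum, over bands with nonzero amplitude for this
    class, of a sinusoid at the band's geometric-mean frequency with an
    independent uniform random phase, plus 1/f background noise.
    """
    if class_index not in (0, 1):
        raise ValueError(f"class_index must be 0 or 1, got {class_index}")
    if not 0 <= subject_index < spec.n_subjects_per_class:
        raise ValueError(
            f"subject_index {subject_index} out of range "
            f"[0, {spec.n_subjects_per_class})"
        )
    ss = np.random.SeedSequence([spec.seed, class_index, subject_index])
    rng = np.random.default_rng(ss)
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate
    sig = np.zeros((spec.n_channels, n))
    for name in BAND_ORDER:
        amps = spec.band_amplitudes_per_class.get(name)
        if amps is None:
            continue
        a = amps[class_index]
        f0 = band_by_name(name).center
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        if a > 0:
            sig += a * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])
    if spec.noise_scale > 0:
        for ch in range(spec.n_channels):
            sig[ch] += _one_over_f_noise(
                rng, n, spec.noise_exponent, spec.noise_scale
            )
    return Recording(
        sig,
        spec.sampling_rate,
        spec.channel_labels,
        subject_id=f"class{class_index}_s{subject_index:03d}",
        label=class_index,
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate the full balanced cohort: class 0 subjects then class 1."""
    return [
        generate_recording(spec, c, s)
        for c in (0, 1)
        for s in range(spec.n_subjects_per_class)
    ]


# ---------------------------------------------------------------------------
# Named study conditions used by the examples and evaluation scripts.


def alpha_contrast_spec(
    n_subjects_per_class: int = 20,
    ratio: float = 3.0,
    seed: int = 0,
    duration: float = 120.0,
) -> CohortSpec:
    """Two-class cohort whose classes differ only in alpha amplitude.

    Consumer-headset-like geometry (14 channels at 128 Hz) with a resting
    1/f background; class 1 carries ``ratio`` times the alpha amplitude of
    class 0, so its expected alpha band power is ``ratio**2`` times larger.
    """
    return CohortSpec(
        n_subjects_per_class=n_subjects_per_class,
        n_channels=14,
        sampling_rate=128.0,
        duration=duration,
        band_amplitudes_per_class={
            "delta": (1.0, 1.0),
            "theta": (0.8, 0.8),
            "alpha": (1.0, ratio),
            "beta": (0.6, 0.6),
        },
        noise_exponent=1.0,
        noise_scale=1.0,
        seed=seed,
    )


def shape_contrast_spec(
    n_subjects_per_class: int = 10, seed: int = 0, duration: float = 60.0
) -> CohortSpec:
    """Two-class cohort whose classes differ in both band power and
    spectral shape: class 1 shifts power from alpha into theta and beta,
    changing the profile of the spectrum as well as individual band powers."""
    return CohortSpec(
        n_subjects_per_class=n_subjects_per_class,
        n_channels=14,
        sampling_rate=128.0,
        duration=duration,
        band_amplitudes_per_class={
            "delta": (1.0, 1.0),
            "theta": (0.5, 1.5),
            "alpha": (1.5, 0.5),
            "beta": (0.4, 1.2),
        },
        noise_exponent=1.0,
        noise_scale=1.0,
        seed=seed,
    )
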
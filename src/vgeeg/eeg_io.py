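"""Reading, referencing and windowing of multi-channel EEG recordings.

A :class:`Recording` is the package's in-memory representation of one
subject's continuous EEG: a ``(n_channels, n_samples)`` float matrix in
microvolts plus sampling rate, channel labels and a binary class label.
Recordings are cut into contiguous non-overlapping :class:`Window` objects
before any spectral analysis.

Supported on-disk formats:

* ``edf`` — European Data Format, read through :mod:`mne`; written by a
  minimal 16-bit EDF writer in this module.
* ``delimited`` — plain-text table, channels as columns under a header line
  of channel labels, or channels as rows when no header is present.
  Metadata (sampling rate, labels, subject id, class label) lives in a JSON
  sidecar ``<file>.json``; explicit arguments override the sidecar.
* ``array`` — NumPy ``.npy`` matrix of shape (n_channels, n_samples) with
  the same JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "Window",
    "read_recording",
    "write_recording",
    "apply_reference",
    "segment_windows",
]


@dataclass(frozen=True)
class Recording:
    """One continuous multi-channel EEG recording with its class label."""

    signal: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate: float  # Hz
    channel_labels: tuple[str, ...]
    subject_id: str
    label: int  # binary class

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValueError("signal must be a (n_channels, n_samples) matrix")
        if len(self.channel_labels) != sig.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{sig.shape[0]} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(sig)):
            bad = np.argwhere(~np.isfinite(sig))[0]
            raise ValueError(
                f"non-finite sample at channel "
                f"{self.channel_labels[bad[0]]!r}, sample {bad[1]}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class Window:
    """One fixed-length segment of a recording; inherits the parent label."""

    signal: np.ndarray  # (n_channels, window_samples)
    sampling_rate: float
    channel_labels: tuple[str, ...]
    window_index: int
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _write_sidecar(path: Path, rec: Recording) -> None:
    meta = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "label": int(rec.label),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# reading


def read_recording(
    path: str | Path,
    format: str | None = None,
    label: int | None = None,
    subject_id: str | None = None,
    sampling_rate: float | None = None,
    channel_labels: Sequence[str] | None = None,
) -> Recording:
    """Read a recording from ``path``.

    ``format`` is one of ``edf``, ``delimited``, ``array``; when omitted it
    is inferred from the file suffix.  Explicit arguments override the JSON
    sidecar (delimited/array) or the file header (EDF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if format is None:
        format = {
            ".edf": "edf",
            ".npy": "array",
        }.get(path.suffix.lower(), "delimited")
    if format == "edf":
        return _read_edf(path, label=label, subject_id=subject_id)
    if format == "delimited":
        return _read_delimited(
            path, label, subject_id, sampling_rate, channel_labels
        )
    if format == "array":
        return _read_array(path, label, subject_id, sampling_rate, channel_labels)
    raise ValueError(f"unknown format {format!r}")


def _meta_from(
    sidecar: dict,
    label: int | None,
    subject_id: str | None,
    sampling_rate: float | None,
    channel_labels: Sequence[str] | None,
    n_channels: int,
    path: Path,
) -> tuple[int, str, float, tuple[str, ...]]:
    label = label if label is not None else sidecar.get("label")
    subject_id = subject_id or sidecar.get("subject_id") or path.stem
    sampling_rate = (
        sampling_rate if sampling_rate is not None else sidecar.get("sampling_rate")
    )
    channel_labels = channel_labels or sidecar.get("channel_labels")
    if sampling_rate is None:
        raise ValueError(
            f"{path}: sampling_rate not given and no JSON sidecar found"
        )
    if label is None:
        raise ValueError(f"{path}: class label not given and not in sidecar")
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_channels))
    return int(label), str(subject_id), float(sampling_rate), tuple(channel_labels)


def _read_delimited(
    path: Path,
    label: int | None,
    subject_id: str | None,
    sampling_rate: float | None,
    channel_labels: Sequence[str] | None,
) -> Recording:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = "," if "," in lines[0] else ("\t" if "\t" in lines[0] else None)

    def _tokens(line: str) -> list[str]:
        return [t.strip() for t in (line.split(delim) if delim else line.split())]

    head = _tokens(lines[0])
    has_header = not all(_is_number(t) for t in head)
    rows: list[list[float]] = []
    for ln_no, line in enumerate(lines[1:] if has_header else lines):
        toks = _tokens(line)
        vals = []
        for col, t in enumerate(toks):
            try:
                v = float(t)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample {t!r} at row {ln_no}, column {col}"
                ) from None
            vals.append(v)
        rows.append(vals)
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: ragged rows")
    mat = np.asarray(rows, dtype=float)
    if has_header:
        # header names the channels; channels are columns
        mat = mat.T
        if channel_labels is None:
            channel_labels = tuple(head)
    if not np.all(np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite sample at channel row {bad[0]}, sample {bad[1]}"
        )
    sidecar = _read_sidecar(path)
    label, subject_id, sampling_rate, channel_labels = _meta_from(
        sidecar, label, subject_id, sampling_rate, channel_labels, mat.shape[0], path
    )
    return Recording(mat, sampling_rate, channel_labels, subject_id, label)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_array(
    path: Path,
    label: int | None,
    subject_id: str | None,
    sampling_rate: float | None,
    channel_labels: Sequence[str] | None,
) -> Recording:
    mat = np.load(path)
    sidecar = _read_sidecar(path)
    label, subject_id, sampling_rate, channel_labels = _meta_from(
        sidecar, label, subject_id, sampling_rate, channel_labels, mat.shape[0], path
    )
    return Recording(mat, sampling_rate, channel_labels, subject_id, label)


def _read_edf(path: Path, label: int | None, subject_id: str | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {info["sfreq"] for info in [raw.info]}
    if len(rates) != 1:
        raise ValueError(f"{path}: mixed sampling rates")
    data = raw.get_data()  # volts
    sidecar = _read_sidecar(path)
    if label is None:
        label = sidecar.get("label")
    if label is None:
        raise ValueError(f"{path}: class label not given and not in sidecar")
    subject_id = subject_id or sidecar.get("subject_id") or path.stem
    return Recording(
        data * 1e6,  # mne returns SI volts; Recording stores microvolts
        float(raw.info["sfreq"]),
        tuple(raw.ch_names),
        str(subject_id),
        int(label),
    )


# ---------------------------------------------------------------------------
# writing


def write_recording(rec: Recording, path: str | Path, format: str = "delimited") -> Path:
    """Write ``rec`` to ``path`` in the requested format (with JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        header = ",".join(rec.channel_labels)
        body = "\n".join(
            ",".join(f"{v:.10g}" for v in col) for col in rec.signal.T
        )
        path.write_text(header + "\n" + body + "\n")
    elif format == "array":
        np.save(path, rec.signal)
        path = path if path.suffix == ".npy" else path.with_suffix(".npy")
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _write_sidecar(path, rec)
    return path


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit samples, one data record per second.

    Requires an integer sampling rate.  Physical range is taken per channel
    from the data, so quantization error is (max-min)/2^16 per channel.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    total = n_rec * fs
    sig = np.zeros((ns, total))
    sig[:, : rec.n_samples] = rec.signal

    pmin = sig.min(axis=1)
    pmax = sig.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((sig - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b""
    hdr += pad("0", 8)  # version
    hdr += pad(f"subject {rec.subject_id}", 80)
    hdr += pad("vgeeg synthetic recording", 80)
    hdr += pad("01.01.00", 8)  # start date (placeholder epoch)
    hdr += pad("00.00.00", 8)  # start time
    hdr += pad(str(256 * (ns + 1)), 8)
    hdr += pad("", 44)
    hdr += pad(str(n_rec), 8)
    hdr += pad("1", 8)  # record duration, seconds
    hdr += pad(str(ns), 4)
    for lab in rec.channel_labels:
        hdr += pad(lab, 16)
    hdr += b"".join(pad("EEG", 80) for _ in range(ns))
    hdr += b"".join(pad("uV", 8) for _ in range(ns))
    hdr += b"".join(pad(f"{v:.6g}"[:8], 8) for v in pmin)
    hdr += b"".join(pad(f"{v:.6g}"[:8], 8) for v in pmax)
    hdr += b"".join(pad(str(dmin), 8) for _ in range(ns))
    hdr += b"".join(pad(str(dmax), 8) for _ in range(ns))
    hdr += b"".join(pad("", 80) for _ in range(ns))  # prefiltering
    hdr += b"".join(pad(str(fs), 8) for _ in range(ns))
    hdr += b"".join(pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            chunk = digital[:, r * fs : (r + 1) * fs]
            fh.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# referencing and windowing


def apply_reference(rec: Recording, scheme: str = "common_average") -> Recording:
    """Re-reference a recording.

    ``scheme`` is either ``"common_average"`` (subtract the instantaneous
    cross-channel mean from every channel) or ``"channel:<label>"`` /
    ``"channel(<label>)"`` (subtract the named channel from every channel).
    """
    if scheme == "common_average":
        ref = rec.signal.mean(axis=0, keepdims=True)
    elif scheme.startswith("channel"):
        lab = scheme.split(":", 1)[1] if ":" in scheme else scheme[len("channel") :].strip("()")
        if lab not in rec.channel_labels:
            raise ValueError(
                f"unknown reference channel {lab!r}; available: "
                f"{', '.join(rec.channel_labels)}"
            )
        ref = rec.signal[rec.channel_labels.index(lab)][None, :]
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return replace(rec, signal=rec.signal - ref)


def segment_windows(rec: Recording, window_length: float) -> list[Window]:
    """Cut ``rec`` into contiguous non-overlapping windows of
    ``window_length`` seconds; trailing samples that do not fill a whole
    window are discarded."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    w = int(round(window_length * rec.sampling_rate))
    if w < 2:
        raise ValueError("window too short: fewer than 2 samples")
    n_win = rec.n_samples // w
    if n_win == 0:
        logger.warning(
            "window of %g s (%d samples) longer than recording %s (%d samples); "
            "no windows produced",
            window_length,
            w,
            rec.subject_id,
            rec.n_samples,
        )
        return []
    return [
        Window(
            rec.signal[:, i * w : (i + 1) * w],
            rec.sampling_rate,
            rec.channel_labels,
            i,
            rec.subject_id,
            rec.label,
        )
        for i in range(n_win)
    ]
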
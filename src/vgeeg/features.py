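"""Per-window classifier input assembly.

Three feature modes are supported for each analysis window:

* ``vg_only``   — the eight visibility-graph features per (channel, band);
* ``psd_only``  — one integrated band power per (channel, band),
  log(1 + power)-transformed (band powers are heavy-tailed);
* ``combined``  — the vg_only block followed by the psd_only block.

The layout is deterministic: channels in recording order, bands in
canonical order (delta..gamma), features in fixed order.  Standardization
(z-scoring) is always fitted on training rows only and applied to held-out
rows, so no information leaks across cross-validation folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .eeg_io import Window
from .graph_features import FEATURE_NAMES, feature_vector
from .spectral import (
    BandDefinition,
    DEFAULT_BANDS,
    WelchParams,
    band_power,
    band_psd_sequences,
)
from .visibility import build_visibility_graph

__all__ = ["FeatureRow", "assemble", "standardize", "rows_to_frame",
           "frame_to_rows", "write_feature_matrix", "read_feature_matrix"]

MODES = ("combined", "vg_only", "psd_only")


@dataclass(frozen=True)
class FeatureRow:
    """One window's flat feature vector with its provenance."""

    subject_id: str
    window_index: int
    values: np.ndarray
    label: int
    mode: str
    layout: tuple[tuple[str, str, str], ...]  # (channel, band, feature-name)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "layout", tuple(map(tuple, self.layout)))
        if len(v) != len(self.layout):
            raise ValueError("values length must equal layout length")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")


def _layout(
    channel_labels: Sequence[str], bands: Sequence[BandDefinition], mode: str
) -> tuple[tuple[str, str, str], ...]:
    vg = [
        (ch, b.name, feat)
        for ch in channel_labels
        for b in bands
        for feat in FEATURE_NAMES
    ]
    psd = [(ch, b.name, "log_band_power") for ch in channel_labels for b in bands]
    if mode == "vg_only":
        return tuple(vg)
    if mode == "psd_only":
        return tuple(psd)
    if mode == "combined":
        return tuple(vg + psd)
    raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")


def assemble(
    windows: Iterable[Window],
    mode: str = "combined",
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    welch: WelchParams | None = None,
    time_domain_bandpass: bool = False,
) -> list[FeatureRow]:
    """Compute one :class:`FeatureRow` per window.

    All windows must share sampling rate and channel labels (one cohort).
    """
    windows = list(windows)
    if not windows:
        return []
    ref = windows[0]
    for w in windows[1:]:
        if w.sampling_rate != ref.sampling_rate or w.channel_labels != ref.channel_labels:
            raise ValueError("all windows must share sampling rate and channels")
    bands = tuple(bands)
    layout = _layout(ref.channel_labels, bands, mode)
    rows: list[FeatureRow] = []
    for w in windows:
        seqs = band_psd_sequences(w, bands, welch, time_domain_bandpass)
        vg_vals: list[float] = []
        psd_vals: list[float] = []
        for ch in w.channel_labels:
            for b in bands:
                seq = seqs[(ch, b.name)]
                if mode in ("combined", "vg_only"):
                    fv = feature_vector(build_visibility_graph(seq))
                    vg_vals.extend(fv.as_array())
                if mode in ("combined", "psd_only"):
                    psd_vals.append(np.log1p(band_power(seq)))
        values = np.array(vg_vals + psd_vals)
        rows.append(
            FeatureRow(w.subject_id, w.window_index, values, w.label, mode, layout)
        )
    return rows


def standardize(
    train_rows: Sequence[FeatureRow], other_rows: Sequence[FeatureRow] = ()
) -> tuple[list[FeatureRow], list[FeatureRow]]:
    """Column-wise z-scoring with statistics estimated on ``train_rows`` only.

    Zero-variance columns are centered but not scaled.
    """
    if not train_rows:
        raise ValueError("train_rows must be non-empty")
    x = np.stack([r.values for r in train_rows])
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)

    def apply(rows: Sequence[FeatureRow]) -> list[FeatureRow]:
        return [replace(r, values=(r.values - mean) / std) for r in rows]

    return apply(train_rows), apply(other_rows)


# ---------------------------------------------------------------------------
# tabular persistence


def rows_to_frame(rows: Sequence[FeatureRow]) -> pd.DataFrame:
    """Wide table: one row per window, one column per layout entry."""
    if not rows:
        return pd.DataFrame()
    cols = ["__".join(entry) for entry in rows[0].layout]
    df = pd.DataFrame(
        np.stack([r.values for r in rows]), columns=cols
    )
    df.insert(0, "subject_id", [r.subject_id for r in rows])
    df.insert(1, "window_index", [r.window_index for r in rows])
    df.insert(2, "label", [r.label for r in rows])
    return df


def frame_to_rows(df: pd.DataFrame, mode: str) -> list[FeatureRow]:
    meta = ("subject_id", "window_index", "label")
    feat_cols = [c for c in df.columns if c not in meta]
    layout = tuple(tuple(c.split("__")) for c in feat_cols)
    return [
        FeatureRow(
            str(rec["subject_id"]),
            int(rec["window_index"]),
            np.array([rec[c] for c in feat_cols], dtype=float),
            int(rec["label"]),
            mode,
            layout,
        )
        for rec in df.to_dict("records")
    ]


def write_feature_matrix(rows: Sequence[FeatureRow], path: str | Path) -> Path:
    """CSV feature matrix plus a JSON sidecar recording mode and layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows_to_frame(rows).to_csv(path, index=False)
    sidecar = {
        "mode": rows[0].mode if rows else None,
        "layout": [list(e) for e in rows[0].layout] if rows else [],
        "n_rows": len(rows),
    }
    path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_feature_matrix(path: str | Path) -> list[FeatureRow]:
    path = Path(path)
    sidecar = json.loads(path.with_name(path.name + ".json").read_text())
    return frame_to_rows(pd.read_csv(path), sidecar["mode"])
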
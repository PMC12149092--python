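"""Run configuration: a single YAML file drives the whole pipeline.

Unknown keys anywhere in the file are errors (typo protection).  A minimal
config needs only an input block; everything else has defaults.

Example::

    input:
      synthetic:
        n_subjects_per_class: 7
        n_channels: 14
        sampling_rate: 128
        duration: 120
        band_amplitudes_per_class:
          alpha: [1.0, 3.0]
    reference: common_average
    window_length: 5.0
    mode: combined
    model:
      architecture: mlp
      epochs: 100
    evaluation:
      folds: 5
      repeats: 10
      grouping: by_window
    seed: 0
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .models import ModelSpec, TrainingParams
from .spectral import WelchParams
from .synthetic import CohortSpec

__all__ = ["RunConfig", "load_config"]


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    input_paths: list[str] = field(default_factory=list)
    input_format: str | None = None
    input_labels: dict[str, int] = field(default_factory=dict)
    synthetic: CohortSpec | None = None
    reference: str = "common_average"
    window_length: float = 5.0
    mode: str = "combined"
    welch: dict = field(default_factory=dict)  # overrides of WelchParams
    model: ModelSpec = field(default_factory=ModelSpec)
    folds: int = 5
    repeats: int = 10
    grouping: str = "by_window"
    seed: int = 0
    output_dir: str = "vgeeg_output"
    raw: dict = field(default_factory=dict)

    def welch_params(self, sampling_rate: float) -> WelchParams:
        base = WelchParams.default(sampling_rate)
        return WelchParams(
            segment_length=int(self.welch.get("segment_length", base.segment_length)),
            overlap_fraction=float(
                self.welch.get("overlap_fraction", base.overlap_fraction)
            ),
            taper=self.welch.get("taper", base.taper),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys(
        raw,
        {
            "input",
            "reference",
            "window_length",
            "mode",
            "welch",
            "model",
            "evaluation",
            "seed",
            "output_dir",
        },
        "top level",
    )
    cfg = RunConfig(raw=raw)
    cfg.seed = int(raw.get("seed", 0))
    if seed_override is not None:
        cfg.seed = int(seed_override)
    cfg.reference = raw.get("reference", cfg.reference)
    cfg.window_length = float(raw.get("window_length", cfg.window_length))
    cfg.mode = raw.get("mode", cfg.mode)
    cfg.output_dir = raw.get("output_dir", cfg.output_dir)

    inp = raw.get("input", {})
    _check_keys(inp, {"paths", "format", "labels", "synthetic"}, "input")
    if "synthetic" in inp:
        syn = dict(inp["synthetic"])
        _check_keys(
            syn,
            {
                "n_subjects_per_class",
                "n_channels",
                "sampling_rate",
                "duration",
                "band_amplitudes_per_class",
                "noise_exponent",
                "noise_scale",
                "seed",
            },
            "input.synthetic",
        )
        amps = {
            k: tuple(v)
            for k, v in dict(syn.pop("band_amplitudes_per_class", {"alpha": (1, 1)})).items()
        }
        syn.setdefault("seed", cfg.seed)
        cfg.synthetic = CohortSpec(band_amplitudes_per_class=amps, **syn)
    else:
        cfg.input_paths = list(inp.get("paths", []))
        cfg.input_format = inp.get("format")
        cfg.input_labels = {str(k): int(v) for k, v in dict(inp.get("labels", {})).items()}
        if not cfg.input_paths:
            raise ValueError("config needs input.paths or input.synthetic")

    welch = raw.get("welch", {})
    _check_keys(welch, {"segment_length", "overlap_fraction", "taper"}, "welch")
    cfg.welch = dict(welch)

    model = dict(raw.get("model", {}))
    _check_keys(
        model,
        {"architecture", "epochs", "batch_size", "learning_rate", "seed"},
        "model",
    )
    arch = model.pop("architecture", "mlp")
    model.setdefault("seed", cfg.seed)
    cfg.model = ModelSpec(architecture=arch, training=TrainingParams(**model))

    ev = dict(raw.get("evaluation", {}))
    _check_keys(ev, {"folds", "repeats", "grouping", "seed"}, "evaluation")
    cfg.folds = int(ev.get("folds", cfg.folds))
    cfg.repeats = int(ev.get("repeats", cfg.repeats))
    cfg.grouping = ev.get("grouping", cfg.grouping)
    if "seed" in ev:
        cfg.seed = int(ev["seed"]) if seed_override is None else cfg.seed
    return cfg
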
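"""Declarative analysis configuration and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "RunManifest"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Single declarative configuration for an end-to-end run.

    Defaults match the module-level defaults: 10-min sampling, 12-h burn-in,
    72-h analysis window, centered 24-h rolling normalization, 1-h binning,
    a 20-28 h period grid, permutation null (20,000 draws) for long series,
    vendor stress-test summarizers, alpha 0.05, amplitude-outlier Z > 2 and
    a 25% QC RSD threshold.
    """

    burn_in_h: float = 12.0
    window_h: float = 72.0
    rolling_window_h: float = 24.0
    rolling_align: str = "centered"
    norm_mode: str = "self"
    control_label: str = "DMSO"
    bin_h: float = 1.0
    period_min_h: float = 20.0
    period_max_h: float = 28.0
    period_step_h: float | None = None  # default: bin width
    null_method: str = "auto"
    n_perm: int = 20_000
    seed: int = 0
    summarizer: str = "vendor"
    alpha: float = 0.05
    z_threshold: float = 2.0
    qc_threshold_pct: float = 25.0
    n_wells_per_condition: int = 12
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record written on every run; identical inputs reproduce outputs."""

    config: dict
    seed: int
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
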
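"""YAML-backed pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotations import AgeGroup
from .rr import FastBreathingCutoffs

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the annotation -> RR -> agreement pipeline.

    YAML layout::

        cutoffs_bpm: {lt2m: 60, 2-11m: 50, 12-59m: 40}
        fraction_warn_threshold: 1.5
        dialect: paired          # or: moment
        pairing_policy: strict   # or: lenient
        qc_max_distortion_s: 30
        kappa_policy: exclude    # or: reduce
    """

    cutoffs: FastBreathingCutoffs = field(default_factory=FastBreathingCutoffs)
    fraction_warn_threshold: float = 1.5
    dialect: str = "paired"
    pairing_policy: str = "strict"
    qc_max_distortion_s: float = 30.0
    kappa_policy: str = "exclude"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cutoffs_bpm" in raw:
            kwargs["cutoffs"] = FastBreathingCutoffs(
                {AgeGroup(k): float(v) for k, v in raw.pop("cutoffs_bpm").items()}
            )
        known = {
            "fraction_warn_threshold", "dialect", "pairing_policy",
            "qc_max_distortion_s", "kappa_policy",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)
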
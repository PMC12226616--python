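"""Run configuration with the method's published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .volume import DEFAULT_ORGAN_LABELS, DEFAULT_VERTEBRA_LABELS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults reproduce the method's stated settings: 15% low-density
    removal, SAT erosion to 20% area, NSD tolerance 2 mm, 1.5 mm isotropic
    resampling."""

    pd_percentile: float = 0.15
    erosion_fraction: float = 0.20
    structure: str = "cross"  # cross | square
    fit_on_volume: bool = False
    scale_by_std: bool = True
    organ_labels: tuple[str, ...] = field(default_factory=lambda: DEFAULT_ORGAN_LABELS)
    vertebra_labels: tuple[str, ...] = field(default_factory=lambda: DEFAULT_VERTEBRA_LABELS)
    tau_mm: float = 2.0
    resample_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
        for key in ("organ_labels", "vertebra_labels", "resample_spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("organ_labels", "vertebra_labels", "resample_spacing"):
            d[key] = list(d[key])
        return d
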
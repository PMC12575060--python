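"""Run configuration and dose arithmetic.

A :class:`PipelineConfig` gathers every stage's parameters under one seed
so a whole run is reproducible from a single YAML/JSON document; the full
config is echoed into each run's manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "irradiation_duration", "DEFAULT_DOSE_RATE_GY_PER_MIN"]

#: Cs-137 gamma irradiator dose rate (Gy/min) used throughout
DEFAULT_DOSE_RATE_GY_PER_MIN = 4.82

#: default treatment arms: sEV dose per cell and the hazard scaling
#: (protection factor) each dose confers
DEFAULT_ARMS = (
    {"group": "control", "protection_factor": 1.0, "sev_dose_per_cell": 0},
    {"group": "low", "protection_factor": 0.7, "sev_dose_per_cell": 2500},
    {"group": "medium", "protection_factor": 0.5, "sev_dose_per_cell": 5000},
    {"group": "high", "protection_factor": 0.4, "sev_dose_per_cell": 15000},
)


def irradiation_duration(
    dose_Gy: float, dose_rate_Gy_per_min: float = DEFAULT_DOSE_RATE_GY_PER_MIN
) -> float:
    """Exposure time in minutes to deliver ``dose_Gy`` at the given rate.

    At the default 4.82 Gy/min, an 8 Gy dose takes ~1.66 min.
    """
    if dose_rate_Gy_per_min <= 0:
        raise ValueError("dose rate must be positive")
    if dose_Gy < 0:
        raise ValueError("dose must be nonnegative")
    return dose_Gy / dose_rate_Gy_per_min


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs, under a single seed."""

    seed: int = 0
    output_dir: str = "runs/demo"
    stages: list[str] = field(default_factory=lambda: ["gedi"])
    dose_Gy: float = 8.0
    dose_rate_Gy_per_min: float = DEFAULT_DOSE_RATE_GY_PER_MIN

    simulation: dict = field(default_factory=dict)
    arms: list[dict] = field(default_factory=lambda: [dict(a) for a in DEFAULT_ARMS])
    calibration: dict | None = field(
        default_factory=lambda: {"n_cells": 150, "lethal_dose_Gy": 25.0}
    )
    segmentation: dict = field(
        default_factory=lambda: {"method": "otsu", "min_area_px": 20}
    )
    tracking: dict = field(default_factory=lambda: {"max_displacement_px": 30.0})
    foci: dict = field(
        default_factory=lambda: {"fold_over_background": 10.0, "min_separation_px": 3}
    )
    gating: dict = field(default_factory=lambda: {"percentile": 99.5})
    flow: dict = field(
        default_factory=lambda: {
            "n_events": 20000,
            "positive_fraction": 0.95,
            "neg_mu": 100.0,
            "pos_mu": 1000.0,
            "sigma_log": 0.3,
        }
    )
    colony: dict = field(default_factory=dict)

    KNOWN_STAGES = ("simulate", "gedi", "foci", "colony", "flow")

    def validate(self) -> None:
        """Check cross-stage consistency before any work starts."""
        unknown = set(self.stages) - set(self.KNOWN_STAGES) - {"all"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        resolved = self.resolved_stages()
        if "gedi" in resolved and not self.calibration:
            raise ValueError(
                "a GEDI run requires a calibration block (lethal-dose "
                "ratio calibration)"
            )
        if self.dose_Gy < 0 or self.dose_rate_Gy_per_min <= 0:
            raise ValueError("invalid dose configuration")
        if "gedi" in resolved and not self.arms:
            raise ValueError("a GEDI run requires at least one treatment arm")

    def resolved_stages(self) -> list[str]:
        if "all" in self.stages:
            return ["gedi", "foci", "colony", "flow"]
        return list(self.stages)

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
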
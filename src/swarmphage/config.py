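"""Run configuration: a validated key-value file shared by all CLI subcommands."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .containers import Calibration

__all__ = ["RunConfig", "load_config"]

_ALLOWED_KEYS = {
    "pixel_size",
    "frame_interval",
    "z_step",
    "seed",
    "min_object_px",
    "front_fraction",
    "diffusive_band",
    "msd_max_lag_fraction",
}


@dataclass
class RunConfig:
    """Defaults for calibration, segmentation and model parameters.

    Units: pixel_size μm/px, frame_interval s, z_step μm. The movie
    calibration is deliberately config-driven — it is acquisition
    metadata, never assumed.
    """

    pixel_size: float = 1.0
    frame_interval: float = 1.0
    z_step: float = 3.0
    seed: int = 0
    min_object_px: int = 9
    front_fraction: float = 0.01
    diffusive_band: tuple[float, float] = (0.9, 1.1)
    msd_max_lag_fraction: float = 0.25

    def __post_init__(self) -> None:
        self.diffusive_band = tuple(float(v) for v in self.diffusive_band)
        low, high = self.diffusive_band
        if not low < 1 < high:
            raise ValueError(f"diffusive_band must bracket 1, got {self.diffusive_band}")
        if not 0 < self.msd_max_lag_fraction <= 1:
            raise ValueError("msd_max_lag_fraction must be in (0, 1]")
        if not 0 < self.front_fraction < 1:
            raise ValueError("front_fraction must be in (0, 1)")
        self.calibration()  # validates positivity of the calibration triple

    def calibration(self) -> Calibration:
        return Calibration(
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            z_step=self.z_step,
        )

    def digest(self) -> str:
        """Stable short hash of the configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, missing ones default."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)
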
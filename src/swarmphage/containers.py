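"""Core in-memory containers: calibrated trajectories and image stacks.

All positions are stored in physical units (micrometres) and times in
seconds; conversion from pixels/frames happens once, at load time, via a
:class:`Calibration`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Calibration",
    "Trajectory",
    "TrajectoryEnsemble",
    "ImageStack",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a tracking movie or image stack.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames in seconds.
    z_step : float, optional
        Axial distance between consecutive z-slices in micrometres
        (used for depth stacks only). Default 3.0.
    """

    pixel_size: float
    frame_interval: float
    z_step: float = 3.0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "z_step"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Calibration.{name} must be strictly positive, got {v!r}")

    def px_to_um(self, value_px: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(value_px) * self.pixel_size

    def um_to_px(self, value_um: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(value_um) / self.pixel_size


@dataclass
class Trajectory:
    """A single particle track: time-ordered positions in micrometres.

    Frames are 0-based integers on a uniform grid; missing frames are
    allowed (``has_gaps``) but never silently interpolated — downstream
    lag statistics skip pairs spanning a gap.
    """

    track_id: str
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError(f"track {self.track_id}: coordinate arrays have unequal lengths")
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs at least 2 points, got {n}")
        if np.any(self.frames < 0):
            raise ValueError(f"track {self.track_id}: negative frame index")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames must be strictly increasing")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def span_frames(self) -> int:
        """Number of frame intervals between first and last detection."""
        return int(self.frames[-1] - self.frames[0])


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one spatial/temporal calibration."""

    trajectories: list[Trajectory]
    calibration: Calibration
    n_dropped: int = 0  # particles discarded at load (fewer than 2 detections)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]


@dataclass
class ImageStack:
    """A calibrated fluorescence stack: timelapse or z-stack.

    ``axis_kind`` distinguishes the meaning of the leading axis:
    ``"time"`` (frames, spaced by ``calibration.frame_interval`` seconds)
    or ``"depth"`` (slices, spaced by ``calibration.z_step`` micrometres).
    """

    data: np.ndarray
    axis_kind: str
    calibration: Calibration
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be (planes, h, w), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if self.axis_kind not in ("time", "depth"):
            raise ValueError(f"axis_kind must be 'time' or 'depth', got {self.axis_kind!r}")
        if np.any(np.asarray(self.data, dtype=float) < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def axis_values(self) -> np.ndarray:
        """Physical coordinate of each plane: seconds (time) or μm (depth)."""
        n = np.arange(self.n_planes)
        if self.axis_kind == "time":
            return n * self.calibration.frame_interval
        return n * self.calibration.z_step
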
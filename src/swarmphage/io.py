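"""Readers and writers for trajectories (tracker XML, CSV) and TIFF stacks.

The XML dialect is the simplified per-particle "exported tracks" format
produced by ImageJ/TrackMate's *Export tracks to XML* action::

    <Tracks nTracks="2" spaceUnits="micron" frameInterval="3.0">
      <particle nSpots="3">
        <detection t="0" x="1.5" y="2.0" z="0"/>
        ...
      </particle>
    </Tracks>

where ``t`` is the 0-based frame index and ``x``/``y`` are positions,
either already calibrated (micrometres, the TrackMate default) or raw
pixels (``coords="px"``).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

from .containers import Calibration, ImageStack, Trajectory, TrajectoryEnsemble

__all__ = [
    "read_tracker_xml",
    "write_tracker_xml",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_stack",
    "write_stack",
]

CSV_COLUMNS = ("track_id", "frame", "x", "y")


def _build_trajectory(track_id: str, frames, xs, ys, calibration: Calibration) -> Trajectory:
    order = np.argsort(frames, kind="stable")
    frames = np.asarray(frames, dtype=np.int64)[order]
    xs = np.asarray(xs, dtype=float)[order]
    ys = np.asarray(ys, dtype=float)[order]
    t = frames * calibration.frame_interval
    return Trajectory(track_id=track_id, frames=frames, t=t, x=xs, y=ys)


def read_tracker_xml(
    path: str | Path,
    calibration: Calibration,
    coords: str = "um",
) -> TrajectoryEnsemble:
    """Read a tracker "exported tracks" XML file into an ensemble.

    Parameters
    ----------
    path : path
        XML file in the per-particle detection-list dialect.
    calibration : Calibration
        Pixel size and frame interval of the movie.
    coords : {"um", "px"}
        Unit of the stored x/y attributes. With ``"px"`` the coordinates
        are multiplied by ``calibration.pixel_size`` on load.

    Particles with fewer than 2 detections are dropped; the number of
    dropped particles is recorded on the returned ensemble
    (``n_dropped``) and reported as a warning.
    """
    if coords not in ("um", "px"):
        raise ValueError(f"coords must be 'um' or 'px', got {coords!r}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed tracker XML {path} (line {exc.lineno}): {exc.msg}") from exc
    root = tree.getroot()
    scale = calibration.pixel_size if coords == "px" else 1.0

    trajectories: list[Trajectory] = []
    n_dropped = 0
    for i, particle in enumerate(root.iter("particle")):
        detections = particle.findall("detection")
        if len(detections) < 2:
            n_dropped += 1
            continue
        frames = [int(float(d.get("t"))) for d in detections]
        xs = [float(d.get("x")) * scale for d in detections]
        ys = [float(d.get("y")) * scale for d in detections]
        trajectories.append(_build_trajectory(str(i), frames, xs, ys, calibration))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} particle(s) with fewer than 2 detections", stacklevel=2)
    if not trajectories:
        raise ValueError(f"no trajectories with >= 2 detections in {path}")
    return TrajectoryEnsemble(trajectories, calibration, n_dropped=n_dropped)


def write_tracker_xml(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble in the per-particle XML dialect (μm coordinates)."""
    root = etree.Element(
        "Tracks",
        nTracks=str(len(ensemble)),
        spaceUnits="micron",
        frameInterval=repr(ensemble.calibration.frame_interval),
        timeUnits="s",
    )
    for traj in ensemble:
        particle = etree.SubElement(root, "particle", nSpots=str(traj.n_points))
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            etree.SubElement(particle, "detection", t=str(int(f)), x=repr(float(x)), y=repr(float(y)), z="0.0")
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_trajectories_csv(path: str | Path, calibration: Calibration) -> TrajectoryEnsemble:
    """Read trajectories from CSV with columns track_id, frame, x, y [, t].

    ``x``/``y`` are micrometres. ``t`` (seconds), when absent, is derived
    as ``frame * calibration.frame_interval``.
    """
    df = pd.read_csv(path)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"CSV {path} is missing required column {col!r}")
    if df.empty:
        raise ValueError(f"no trajectories in {path}")
    trajectories: list[Trajectory] = []
    n_dropped = 0
    for track_id, group in df.groupby("track_id", sort=False):
        if len(group) < 2:
            n_dropped += 1
            continue
        frames = group["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {track_id}: frames are not strictly increasing")
        t = (
            group["t"].to_numpy(dtype=float)
            if "t" in group.columns
            else frames * calibration.frame_interval
        )
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                frames=frames,
                t=t,
                x=group["x"].to_numpy(dtype=float),
                y=group["y"].to_numpy(dtype=float),
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} track(s) with fewer than 2 points", stacklevel=2)
    if not trajectories:
        raise ValueError(f"no trajectories in {path}")
    return TrajectoryEnsemble(trajectories, calibration, n_dropped=n_dropped)


def write_trajectories_csv(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as CSV (track_id, frame, x, y, t); read∘write is identity."""
    rows = []
    for traj in ensemble:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": traj.track_id,
                    "frame": traj.frames,
                    "x": traj.x,
                    "y": traj.y,
                    "t": traj.t,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_stack(path: str | Path, calibration: Calibration, axis_kind: str) -> ImageStack:
    """Read a (multi-page) TIFF into an :class:`ImageStack`."""
    try:
        data = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if axis_kind == "depth" and data.shape[0] == 1:
        warnings.warn(f"{path}: single-plane file loaded as a depth stack", stacklevel=2)
    return ImageStack(data=data, axis_kind=axis_kind, calibration=calibration)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")
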
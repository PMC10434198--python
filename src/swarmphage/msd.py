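"""Mean-squared-displacement statistics for particle ensembles.

This module implements the motion read-outs used to classify how phages
move on a swarm: the ensemble MSD curve, a power-law fit of MSD against
lag time whose exponent α separates subdiffusive (α < 1), diffusive
(α ≈ 1) and superdiffusive (α > 1) motion, the Einstein-relation
diffusion coefficient, and per-track path-length speeds.

Conventions
-----------
For a particle in ``dim`` spatial dimensions with diffusion coefficient
``D`` the Brownian expectation is ``MSD(τ) = 2·dim·D·τ``, so in the
planar-tracking case ``D = MSD/(4τ)``. Some authors write the Einstein
relation as ``D = MSD/(n·Δt)`` with ``n`` the dimensionality; that
"literal" convention is selectable but not the default, because only the
``2·dim`` form matches the 2-D Brownian closed form.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TrajectoryEnsemble

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "DiffusionEstimate",
    "SpeedStats",
    "MotionClass",
    "ensemble_msd",
    "fit_msd_power_law",
    "classify_motion",
    "diffusion_from_msd",
    "speed_stats",
]

#: Default α band within which motion is called (ordinarily) diffusive.
DEFAULT_DIFFUSIVE_BAND = (0.9, 1.1)


@dataclass
class MSDCurve:
    """Mean squared displacement per lag time.

    Attributes
    ----------
    lags : ndarray
        Lag times in seconds (multiples of the frame interval).
    msd : ndarray
        ⟨|Δr|²⟩ in μm² at each lag.
    n_pairs : ndarray
        Number of displacement pairs contributing to each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    mode: str = "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs at least one pair")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "msd_um2": self.msd, "n_pairs": self.n_pairs})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Log-log MSD plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.lags, self.msd, marker="o", **kwargs)
        ax.set_xlabel("lag time τ (s)")
        ax.set_ylabel("MSD (μm²)")
        return ax


@dataclass
class PowerLawFit:
    """Least-squares fit of log MSD on log lag: MSD = exp(log_prefactor)·τ^α."""

    alpha: float
    log_prefactor: float
    r_squared: float
    fit_lag_range: tuple[float, float]
    n_points: int

    def predict(self, lags: np.ndarray) -> np.ndarray:
        return np.exp(self.log_prefactor) * np.asarray(lags, dtype=float) ** self.alpha

    def summary(self) -> str:
        lo, hi = self.fit_lag_range
        return (
            f"Power-law MSD fit over lags [{lo:g}, {hi:g}] s ({self.n_points} points)\n"
            f"  alpha         = {self.alpha:.4f}\n"
            f"  prefactor     = {np.exp(self.log_prefactor):.4g} um^2/s^alpha\n"
            f"  r-squared     = {self.r_squared:.4f}"
        )


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient from the linear (through-origin) MSD slope."""

    D: float
    dimensionality: int
    fit_lag_range: tuple[float, float]
    convention: str = "standard"


@dataclass
class SpeedStats:
    """Per-track path-length speeds, in μm/min."""

    per_track_speed: np.ndarray
    mean: float
    sd: float


@dataclass
class MotionClass:
    label: str  # subdiffusive | diffusive | superdiffusive
    alpha: float
    band: tuple[float, float]


def _dense_positions(traj) -> tuple[np.ndarray, np.ndarray]:
    """Positions on the uniform frame grid, NaN where the track has a gap."""
    offset = traj.frames - traj.frames[0]
    size = int(offset[-1]) + 1
    xs = np.full(size, np.nan)
    ys = np.full(size, np.nan)
    xs[offset] = traj.x
    ys[offset] = traj.y
    return xs, ys


def ensemble_msd(
    ensemble: TrajectoryEnsemble,
    max_lag_fraction: float = 0.25,
    mode: str = "ensemble",
) -> MSDCurve:
    """Compute the MSD curve of an ensemble.

    Parameters
    ----------
    ensemble : TrajectoryEnsemble
    max_lag_fraction : float
        Lags are limited to this fraction of the shortest track duration;
        longer lags average too few pairs to be informative.
    mode : {"ensemble", "time_averaged"}
        ``"ensemble"`` measures displacements from each particle's first
        point (one pair per particle per lag); ``"time_averaged"``
        additionally averages over all start times within each track.

    Displacement pairs spanning tracking gaps are excluded rather than
    interpolated.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError(f"max_lag_fraction must be in (0, 1], got {max_lag_fraction}")
    if mode not in ("ensemble", "time_averaged"):
        raise ValueError(f"mode must be 'ensemble' or 'time_averaged', got {mode!r}")
    dt = ensemble.calibration.frame_interval
    min_span = min(traj.span_frames for traj in ensemble)
    max_k = int(np.floor(max_lag_fraction * min_span))
    if max_k < 1:
        raise ValueError("tracks too short: no valid lag pairs at the requested fraction")

    sums = np.zeros(max_k)
    counts = np.zeros(max_k, dtype=np.int64)
    for traj in ensemble:
        xs, ys = _dense_positions(traj)
        for k in range(1, min(max_k, len(xs) - 1) + 1):
            if mode == "ensemble":
                dx = xs[k] - xs[0]
                dy = ys[k] - ys[0]
                sq = np.array([dx * dx + dy * dy])
            else:
                dx = xs[k:] - xs[:-k]
                dy = ys[k:] - ys[:-k]
                sq = dx * dx + dy * dy
            valid = np.isfinite(sq)
            sums[k - 1] += np.sum(sq[valid])
            counts[k - 1] += int(np.sum(valid))

    keep = counts >= 1
    if not np.any(keep):
        raise ValueError("tracks too short: no valid lag pairs (gaps exclude all pairs)")
    ks = np.arange(1, max_k + 1)[keep]
    return MSDCurve(lags=ks * dt, msd=sums[keep] / counts[keep], n_pairs=counts[keep], mode=mode)


def _range_mask(lags: np.ndarray, fit_lag_range: tuple[float, float] | None) -> np.ndarray:
    if fit_lag_range is None:
        return np.ones_like(lags, dtype=bool)
    lo, hi = fit_lag_range
    return (lags >= lo) & (lags <= hi)


def fit_msd_power_law(
    curve: MSDCurve,
    fit_lag_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit MSD = c·τ^α by least squares on log–log axes.

    The exponent α is the anomalous-diffusion exponent: α < 1
    subdiffusive, α ≈ 1 diffusive, α > 1 superdiffusive (active).
    """
    mask = _range_mask(curve.lags, fit_lag_range)
    lags = curve.lags[mask]
    msd = curve.msd[mask]
    if len(lags) < 3:
        raise ValueError(f"power-law fit needs >= 3 lag points in range, got {len(lags)}")
    if np.any(msd <= 0):
        raise ValueError("power-law fit undefined: zero MSD value in fit range")
    res = stats.linregress(np.log(lags), np.log(msd))
    return PowerLawFit(
        alpha=float(res.slope),
        log_prefactor=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_lag_range=(float(lags[0]), float(lags[-1])),
        n_points=len(lags),
    )


def classify_motion(
    fit: PowerLawFit | float,
    band: tuple[float, float] = DEFAULT_DIFFUSIVE_BAND,
) -> MotionClass:
    """Classify motion by α against a diffusive band (low < 1 < high)."""
    low, high = band
    if not low < 1 < high:
        raise ValueError(f"band must bracket 1, got {band}")
    alpha = fit.alpha if isinstance(fit, PowerLawFit) else float(fit)
    if alpha < low:
        label = "subdiffusive"
    elif alpha > high:
        label = "superdiffusive"
    else:
        label = "diffusive"
    return MotionClass(label=label, alpha=alpha, band=(float(low), float(high)))


def diffusion_from_msd(
    curve: MSDCurve,
    dimensionality: int = 2,
    fit_lag_range: tuple[float, float] | None = None,
    convention: str = "standard",
) -> DiffusionEstimate:
    """Diffusion coefficient from the through-origin linear MSD slope.

    ``convention="standard"`` uses MSD = 2·dim·D·τ (divide the slope by
    4 in 2-D); ``convention="literal"`` uses MSD = dim·D·τ, the form
    sometimes written as D = ⟨Δr²⟩/(nΔt).
    """
    if dimensionality not in (1, 2, 3):
        raise ValueError(f"dimensionality must be 1, 2 or 3, got {dimensionality}")
    if convention not in ("standard", "literal"):
        raise ValueError(f"convention must be 'standard' or 'literal', got {convention!r}")
    mask = _range_mask(curve.lags, fit_lag_range)
    lags = curve.lags[mask]
    msd = curve.msd[mask]
    if len(lags) < 2:
        raise ValueError(f"diffusion fit needs >= 2 lag points in range, got {len(lags)}")
    slope = float(np.sum(msd * lags) / np.sum(lags * lags))
    if slope < 0:
        warnings.warn("negative MSD slope; clamping D to 0", stacklevel=2)
        slope = 0.0
    divisor = 2 * dimensionality if convention == "standard" else dimensionality
    return DiffusionEstimate(
        D=slope / divisor,
        dimensionality=dimensionality,
        fit_lag_range=(float(lags[0]), float(lags[-1])),
        convention=convention,
    )


def _boxcar(a: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(a, kernel, mode="valid")


def speed_stats(ensemble: TrajectoryEnsemble, smoothing_window: int = 1) -> SpeedStats:
    """Per-track mean speed: total path length / duration, in μm/min.

    An optional boxcar smoothing of the positions (window in frames)
    suppresses localization jitter before the path length is summed.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    speeds = []
    for traj in ensemble:
        x, y, t = traj.x, traj.y, traj.t
        if smoothing_window > 1 and len(x) > smoothing_window:
            x = _boxcar(x, smoothing_window)
            y = _boxcar(y, smoothing_window)
            t = _boxcar(t, smoothing_window)
        path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        duration = float(t[-1] - t[0])
        speeds.append(path / duration * 60.0)
    speeds = np.asarray(speeds)
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return SpeedStats(per_track_speed=speeds, mean=float(np.mean(speeds)), sd=sd)
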
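"""Synthetic trajectories and fluorescence scenes with known ground truth.

Every analysis stage in this package can be exercised without the raw
microscopy by generating data whose governing parameters are retained as
a sidecar ground-truth record:

* trajectories — 2-D Brownian motion, fractional Brownian motion with a
  prescribed MSD exponent (the subdiffusive α ≈ 0.68 on agar and the
  superdiffusive α ≈ 1.22 on a swarm are both reachable), and advective
  drift at a swarm-like ~20.71 μm/min;
* a shrinking fluorescent colony disc (quadratic normalized-area decay),
  emulating prey-biomass clearance timelapses;
* a biofilm z-stack (36 slices × 3 μm = 105 μm) with phage spots whose
  density along depth follows a Gaussian law peaked mid-biofilm or a
  surface-exponential law (the diffusion-only control geometry).

All generators are bit-reproducible given (parameters, seed).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .containers import Calibration, ImageStack, Trajectory, TrajectoryEnsemble
from .imaging import BiomassSeries, DepthProfile

__all__ = [
    "TrajectoryGenParams",
    "ColonySceneParams",
    "BiofilmSceneParams",
    "gen_trajectories",
    "gen_colony_timelapse",
    "gen_biofilm_zstack",
]


@dataclass(frozen=True)
class TrajectoryGenParams:
    """Parameters of the trajectory generator.

    model : {"brownian", "fbm", "advective"}
    D : μm²/s — diffusion coefficient of the Brownian component
        (default 0.041, phage diffusion on wet agar).
    v : μm/min — drift speed for the advective model (default 20.71,
        the mean phage transport speed on a swarm).
    heading : rad or "swarm-circular" — drift direction; the circular
        option rotates the heading at ``v / vortex_radius`` rad/s,
        mimicking a vortexing swarm.
    alpha_target : MSD exponent for the fbm model (0 < α < 2);
        the Hurst exponent is H = α/2.
    msd_prefactor : μm²/s^α — MSD(τ) = msd_prefactor · τ^α for fbm.
    dt : s — frame interval. n_steps — steps per track (track length is
        n_steps + 1 points). n_particles — number of tracks.
    """

    model: str = "brownian"
    D: float = 0.041
    v: float = 20.71
    heading: float | str = 0.0
    vortex_radius: float = 50.0
    alpha_target: float | None = None
    msd_prefactor: float = 0.164
    dt: float = 1.0
    n_steps: int = 200
    n_particles: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "fbm", "advective"):
            raise ValueError(f"unknown trajectory model {self.model!r}")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.model == "fbm":
            if self.alpha_target is None or not 0 < self.alpha_target < 2:
                raise ValueError("fbm requires 0 < alpha_target < 2")


def _fbm_cholesky(times: np.ndarray, hurst: float) -> np.ndarray:
    """Cholesky factor of the exact fBm covariance at the given times."""
    t = times[:, None]
    s = times[None, :]
    cov = 0.5 * (t ** (2 * hurst) + s ** (2 * hurst) - np.abs(t - s) ** (2 * hurst))
    # tiny jitter guards rank deficiency at machine precision
    cov[np.diag_indices_from(cov)] *= 1 + 1e-12
    return np.linalg.cholesky(cov)


def gen_trajectories(params: TrajectoryGenParams) -> tuple[TrajectoryEnsemble, dict]:
    """Generate a trajectory ensemble plus its ground-truth record.

    Brownian steps are i.i.d. Gaussian with per-axis variance 2·D·dt;
    the advective model adds a deterministic drift v·dt along the
    heading; fbm synthesizes exact-covariance fractional Brownian motion
    per axis with H = α/2, scaled so the 2-D MSD is
    ``msd_prefactor · τ^α``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_pts = p.n_steps + 1
    t = np.arange(n_pts) * p.dt
    frames = np.arange(n_pts)

    if p.model == "fbm":
        hurst = p.alpha_target / 2.0
        L = _fbm_cholesky(t[1:], hurst)
        # per-axis variance at time τ is (prefactor/2)·τ^α
        scale = np.sqrt(p.msd_prefactor / 2.0)
        z = rng.standard_normal((p.n_particles, 2, p.n_steps))
        paths = scale * np.einsum("ij,pkj->pki", L, z)
        xs = np.concatenate([np.zeros((p.n_particles, 1)), paths[:, 0, :]], axis=1)
        ys = np.concatenate([np.zeros((p.n_particles, 1)), paths[:, 1, :]], axis=1)
    else:
        step_sd = np.sqrt(2.0 * p.D * p.dt)
        steps = step_sd * rng.standard_normal((p.n_particles, 2, p.n_steps))
        if p.model == "advective":
            v_um_s = p.v / 60.0
            if isinstance(p.heading, str):
                if p.heading != "swarm-circular":
                    raise ValueError(f"unknown heading {p.heading!r}")
                omega = v_um_s / p.vortex_radius  # rad/s along the vortex circle
                theta = omega * t[:-1]
            else:
                theta = np.full(p.n_steps, float(p.heading))
            steps[:, 0, :] += v_um_s * p.dt * np.cos(theta)
            steps[:, 1, :] += v_um_s * p.dt * np.sin(theta)
        xs = np.concatenate(
            [np.zeros((p.n_particles, 1)), np.cumsum(steps[:, 0, :], axis=1)], axis=1
        )
        ys = np.concatenate(
            [np.zeros((p.n_particles, 1)), np.cumsum(steps[:, 1, :], axis=1)], axis=1
        )

    calibration = Calibration(pixel_size=1.0, frame_interval=p.dt)
    trajectories = [
        Trajectory(track_id=str(i), frames=frames, t=t, x=xs[i], y=ys[i])
        for i in range(p.n_particles)
    ]
    truth = {"kind": "trajectories", **asdict(p)}
    return TrajectoryEnsemble(trajectories, calibration), truth


@dataclass(frozen=True)
class ColonySceneParams:
    """Shrinking-colony timelapse parameters.

    The normalized colony area follows A(t)/A(0) = clip(1 − a1·t − a2·t²)
    with t in hours; the default a1 = 0.025/h halves the area over the
    default 20-h window. Intensities emulate a confocal channel with
    offset background; noise_sd sets the additive Gaussian noise, so the
    default (fg − bg)/noise_sd gives SNR 10.
    """

    size_px: int = 384
    pixel_size: float = 4.0  # μm/px
    initial_radius: float = 560.0  # μm (140 px at the default pixel size)
    n_frames: int = 21
    frame_interval_h: float = 1.0
    a1: float = 0.025  # per hour
    a2: float = 0.0  # per hour²
    fg_intensity: float = 140.0
    bg_intensity: float = 40.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_radius / self.pixel_size > self.size_px / 2:
            raise ValueError("initial radius does not fit in the frame")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("foreground must be brighter than background")


def _render_disc(size_px: int, radius_px: float, fg: float, bg: float) -> np.ndarray:
    """Disc with analytically anti-aliased (1-px ramp) edge."""
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    dist = np.hypot(xx - c, yy - c)
    coverage = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    return bg + (fg - bg) * coverage


def gen_colony_timelapse(params: ColonySceneParams) -> tuple[ImageStack, BiomassSeries, dict]:
    """Generate a shrinking-disc timelapse plus the true area series."""
    p = params
    rng = np.random.default_rng(p.seed)
    times = np.arange(p.n_frames) * p.frame_interval_h
    norm_area = np.clip(1.0 - p.a1 * times - p.a2 * times**2, 0.0, 1.0)
    radii_um = p.initial_radius * np.sqrt(norm_area)

    frames = []
    for r_um in radii_um:
        img = _render_disc(p.size_px, r_um / p.pixel_size, p.fg_intensity, p.bg_intensity)
        img = img + p.noise_sd * rng.standard_normal(img.shape)
        frames.append(np.clip(img, 0.0, None))
    data = np.stack(frames).astype(np.float32)

    calibration = Calibration(
        pixel_size=p.pixel_size, frame_interval=p.frame_interval_h * 3600.0
    )
    stack = ImageStack(data=data, axis_kind="time", calibration=calibration,
                       channel_label="prey-biomass")
    truth_series = BiomassSeries(times=times, areas=np.pi * p.initial_radius**2 * norm_area)
    truth = {"kind": "colony_timelapse", **asdict(p)}
    return stack, truth_series, truth


@dataclass(frozen=True)
class BiofilmSceneParams:
    """Biofilm z-stack parameters (36 × 3 μm = 105 μm span by default).

    ``depth_law`` sets the expected phage-spot count per slice:
    ``"gaussian"`` peaks at ``mu_z`` (default 50 μm, the mid-biofilm
    maximum of actively delivered phages) with width ``sigma_z``;
    ``"surface_exponential"`` decays from the top slice with length
    ``decay_length`` — the geometry of passively diffusing control
    phages that stay near the surface.
    """

    size_px: int = 384
    pixel_size: float = 0.5  # μm/px
    n_slices: int = 36
    z_step: float = 3.0  # μm
    depth_law: str = "gaussian"
    mu_z: float = 50.0  # μm
    sigma_z: float = 6.0  # μm
    decay_length: float = 10.0  # μm (surface_exponential)
    spots_at_peak: float = 800.0  # expected spot count in the densest slice
    spot_radius_px: float = 2.0
    spot_intensity: float = 200.0
    bg_intensity: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_law not in ("gaussian", "surface_exponential"):
            raise ValueError(f"unknown depth law {self.depth_law!r}")
        max_z = (self.n_slices - 1) * self.z_step
        if self.depth_law == "gaussian" and not 0 <= self.mu_z <= max_z:
            raise ValueError(f"mu_z must lie within the stack (0..{max_z} μm)")


def _stamp_spots(plane: np.ndarray, centers: np.ndarray, radius: float, amp: float) -> None:
    """Add Gaussian blobs (σ = radius/1.5) at the given (row, col) centers."""
    sigma = radius / 1.5
    half = int(np.ceil(3 * sigma))
    ax = np.arange(-half, half + 1)
    kernel = amp * np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    h, w = plane.shape
    for r, c in centers:
        r, c = int(round(r)), int(round(c))
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        plane[r0:r1, c0:c1] += kernel[r0 - (r - half): r1 - (r - half),
                                      c0 - (c - half): c1 - (c - half)]


def gen_biofilm_zstack(params: BiofilmSceneParams) -> tuple[ImageStack, DepthProfile, dict]:
    """Generate a phage-channel z-stack plus the true expected depth profile.

    Per-slice spot counts are Poisson with mean proportional to the
    depth law; spots are uniformly placed Gaussian blobs.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    z = np.arange(p.n_slices) * p.z_step
    if p.depth_law == "gaussian":
        law = np.exp(-((z - p.mu_z) ** 2) / (2.0 * p.sigma_z**2))
    else:
        law = np.exp(-z / p.decay_length)
    lam = p.spots_at_peak * law / law.max() if law.max() > 0 else np.zeros_like(law)

    planes = []
    for mean_count in lam:
        plane = np.full((p.size_px, p.size_px), p.bg_intensity, dtype=float)
        n_spots = rng.poisson(mean_count)
        if n_spots > 0:
            centers = rng.uniform(0, p.size_px, size=(n_spots, 2))
            _stamp_spots(plane, centers, p.spot_radius_px, p.spot_intensity)
        plane += p.noise_sd * rng.standard_normal(plane.shape)
        planes.append(np.clip(plane, 0.0, None))
    data = np.stack(planes).astype(np.float32)

    calibration = Calibration(pixel_size=p.pixel_size, frame_interval=1.0, z_step=p.z_step)
    stack = ImageStack(data=data, axis_kind="depth", calibration=calibration,
                       channel_label="phage")
    spot_area_frac = min(np.pi * p.spot_radius_px**2 / p.size_px**2, 1.0)
    truth_profile = DepthProfile(
        z=z,
        coverage=np.clip(lam * spot_area_frac, 0.0, 1.0),
        peak_z=float(z[int(np.argmax(lam))]) if lam.max() > 0 else 0.0,
    )
    truth = {"kind": "biofilm_zstack", **asdict(p)}
    return stack, truth_profile, truth
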
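# Methods

## Trajectories and calibration

All motion statistics operate on trajectories in physical units: positions
in μm, times in s, converted once at load time via an explicit
`Calibration` (pixel size μm/px, frame interval s/frame, z-step μm/slice —
all strictly positive). Calibration is acquisition metadata and always comes
from the user's config or flags, never from assumptions. Frames are 0-based
on a uniform grid; missing detections are kept as gaps and flagged, not
interpolated, because interpolation biases displacement statistics. Lag
pairs spanning a gap are simply excluded from the MSD.

## MSD, anomalous exponent and diffusivity

For lag τ = k·Δt the mean squared displacement is the average of
|r(t+τ) − r(t)|² over valid (trajectory, start time) pairs. Two averaging
modes are provided: `ensemble` (displacements from each particle's first
point — one pair per particle per lag, the convention behind ensemble MSD
curves of tracked particle populations) and `time_averaged` (all start
times within each track; lower variance, used for validating estimators on
synthetic data). Lags are limited to a fraction (default 0.25) of the
shortest track's duration: beyond that the averages are carried by too few
pairs to be informative.

The anomalous exponent α is the slope of the ordinary least-squares line of
log MSD on log τ (≥ 3 strictly positive points required). Classification
uses a configurable diffusive band, default (0.9, 1.1): below it
subdiffusive, above it superdiffusive. Only the α = 1 boundary is
physically canonical; the band width is an operational choice.

The diffusion coefficient comes from the through-origin least-squares slope
of MSD on τ: D = slope/(2·dim). A convention toggle (`"literal"`) divides
by dim instead, for comparison with analyses that write the Einstein
relation as D = ⟨Δr²⟩/(nΔt) with n the dimensionality; taken literally that
form doubles D in 2-D relative to the standard ⟨Δr²⟩ = 2·dim·D·τ, which is
the only form consistent with the 2-D Brownian closed form and is therefore
the default. A negative fitted slope is clamped to D = 0 with a warning.

Per-track speed is total path length divided by track duration, reported in
μm/min, with optional boxcar smoothing of positions before the path sum
(localization jitter otherwise inflates path length). Speed is invariant
under global translation and rotation of the field of view.

## Transport model

**Stokes–Einstein.** D = k_B·T/(6π·η·r) for a sphere of radius r in a fluid
of viscosity η. Defaults: η = 1 mPa·s (water), T = 298 K, configurable. The
slow-down ratio of two spheres is r_large/r_small — temperature and
viscosity cancel, so the ~30× ratio between a 30-nm phage capsid and a
~1-nm antibiotic is temperature-independent.

**Swarm geometry.** A colony that vortexes circularly at circumferential
speed s₁ while its front advances one vortex diameter 2r per revolution
moves linearly at s₂ = 2r/(c/s₁) = s₁/π; the radius cancels. 20 μm/min of
vortexing gives 6.37 μm/min (6.3662) of linear advance.

**PDE solver.** ∂C/∂t = D ∂²C/∂x² − v_d ∂C/∂x is integrated explicitly in
conservative flux form: interface flux F = v·C_face − D_eff·ΔC/Δx, F = 0 at
both ends (zero-flux), so total mass is conserved to round-off. The
advective face value is either centered with the Lax–Wendroff correction
(D_eff = D + v²Δt/2, which exactly cancels the −v²Δt/2 anti-diffusion of
forward-Euler centered advection and makes the scheme variance-exact) or
first-order upwind (monotone at any cell Péclet number). The default
`auto` scheme uses the corrected centered flux when Pe = vΔx/D ≤ 2 — the
regime of the swarm-fluid parameters, where it reproduces the translated
Gaussian kernel to < 0.1% of peak at Δx = 1 μm — and upwind otherwise.
Stability requires D_eff·Δt/Δx² ≤ ½ and |v|Δt/Δx ≤ 1; the default Δt is
half the tighter bound, and explicit Δt choices that violate a bound are
rejected with the maximal admissible value named. The initial condition is
unit mass in the first cell (a point release at x = 0) unless a profile is
supplied; no source term is modelled.

**Front read-out.** The front position is the largest x where C ≥ f·max(C),
default f = 0.01. For a Gaussian profile this sits 3.035σ past the center
(σ√(2 ln 100)), so an advected point release reaches
v_d·t + 3.035·√(2Dt) — with D = 0.228 μm²/s and v_d = 6.36 μm/min this is
≈ 1,483 μm after 3.3 h, and the simulated value rounds to 1,500 μm. The
criterion is exposed as a parameter because front "arrival" is inherently a
threshold choice.

*Caveat on diffusion-only distances.* Under pure Fickian spreading any
monotone front criterion gives a distance that increases with D (∝ √(2Dt)
for a point release). Literature values that pair a larger D with a
*shorter* travelled distance can therefore only reflect differing, unstated
read-out criteria, not transport physics; this package does not encode any
such pair as truth and instead always reports the criterion alongside the
distance.

*Which D to use with advection.* The swarm-fluid value D = 0.228 μm²/s is
the default for advective runs (the phage rides the swarm fluid); the
wet-agar value 0.041 μm²/s is appropriate for diffusion-only predictions.
Both are plain parameters. At the 1% criterion the front is dominated by
v_d·t, so the choice shifts the prediction by well under one part in ten.

## Image quantification

**Segmentation.** Foreground = pixels ≥ threshold, with connected
components smaller than `min_object_px` (default 9 px) removed as
sub-diffraction speckle. The threshold is Otsu's by default or a fixed
value. Timelapses are thresholded per frame (illumination drifts over
hours); z-stacks use one global Otsu threshold over all voxels so that
slice coverages remain comparable along depth — per-slice thresholds would
flatten the very depth profile being measured. Otsu on a constant image is
reported as a degenerate histogram, not silently guessed.

**Biomass clearance.** Colony area per frame (μm², pixel count ×
pixel_size²) forms a time series; the trend is an OLS quadratic
A(t) = a₀ + a₁t + a₂t² with the pointwise 95% confidence band of the
predicted mean (t distribution, n − 3 df; the band collapses to zero width
for noiseless input). The clearance *rate* is defined on the normalized
series as the endpoint difference per hour,
(A₀ − A_final)/A₀/Δt — the quadratic initial slope −a₁ is reported as a
secondary definition — and the delivery effect is the ratio of experimental
to control rates. A control that does not lose biomass makes the ratio
undefined (flagged, not infinite).

**Depth profiling.** Per-slice foreground fraction (denominator: all pixels
in the slice; a biofilm mask is deliberately out of scope) against
z = slice × z_step; `peak_z` is the depth of maximum coverage, ties broken
toward the surface and flagged.

## Synthetic data

Generators emit data plus a sidecar ground-truth record so recovery tests
never re-derive the truth. All are bit-reproducible under (params, seed).

* **Trajectories.** Brownian: i.i.d. Gaussian steps, per-axis variance
  2DΔt (default D = 0.041 μm²/s). Advective: Brownian plus vΔt drift
  (default 20.71 μm/min) along a fixed heading or a heading rotating at
  v/r_vortex (a vortexing swarm). Subdiffusive/superdiffusive: fractional
  Brownian motion per axis synthesized from the exact fBm covariance
  (Cholesky of the 0.5·(t^2H + s^2H − |t−s|^2H) matrix) with H = α/2, so
  the ensemble MSD exponent is controlled directly; fBm was chosen over a
  continuous-time random walk because the analysis measures exactly that
  exponent. Track lengths used in tests (≤ 200 steps) keep the Cholesky
  factor small.
* **Colony timelapse.** A disc with analytically anti-aliased edge whose
  normalized area decays as clip(1 − a₁t − a₂t², 0, 1); defaults: 21 hourly
  frames, 384 px at 4 μm/px, initial radius 560 μm, a₁ = 0.025/h (area
  halves over 20 h), background 40 / foreground 140 intensity with Gaussian
  noise σ = 10, i.e. SNR 10. The built-in 10× rate contrast uses
  a₁ = 0.0025/h for the control.
* **Biofilm z-stack.** 36 slices × 3 μm (0–105 μm). Expected spot count per
  slice follows either a Gaussian depth law (default μ_z = 50 μm,
  σ_z = 6 μm — the peak depth is the emulated quantity; the width is set
  within the 20–70 μm mid-biofilm zone such delivery occupies) or a
  surface-exponential law (decay length 10 μm), the passively-diffusing
  control geometry. Counts are Poisson; spots are Gaussian blobs (radius
  2 px, amplitude 200 over background 20, noise σ = 5) at uniform positions
  on a 384-px field at 0.5 μm/px.

**What the synthetic tests do and do not show.** Recovery of α, D, the
clearance-rate ratio and the depth peak on generated data demonstrates that
the estimators are unbiased and correctly wired under the generators'
assumptions: isotropic stationary motion models, a single convex colony
with uniform illumination, isolated diffraction-sized phage spots with
depth-independent brightness. Real microscopy violates these in known ways —
heterogeneous swarm flow, colony fragmentation during lysis, axial
attenuation in deep biofilm slices, spot overlap at high titer — so passing
these tests validates the computational chain, not the segmentation's
robustness to real optics. The Otsu threshold in particular is a stand-in
for an unspecified manual procedure; only synthetic-recovery agreement, not
pixel-identical reproduction, is claimed.

## Problem sizes and tolerances

Estimator-recovery runs use 300 tracks × 200 steps (α within ±0.1, D within
10%), 20 seeds for the image pipeline (rate ratio within 15% at SNR 10,
peak depth within one 3-μm slice), and Δx = 1 μm grids up to 3,000 μm for
the PDE (mass conserved to 1e-6 relative; L∞ within 1% of the Gaussian
kernel; front position invariant to halving Δx and Δt within one cell) —
sizes at which the sampling scatter of each statistic is comfortably inside
the stated tolerance. Degenerate inputs fail loudly by design: tracks
shorter than two points are dropped with a count, all-zero concentration
fields and constant images raise, and undefined ratios are flagged rather
than returned as infinities.
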
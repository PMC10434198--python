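# swarmphage

Motion statistics, transport modelling and fluorescence quantification for
**phage delivery by motile bacterial swarms**.

Bacteriophages are far larger than antibiotic molecules — by Stokes–Einstein,
a ~30-nm lambda capsid diffuses about 30× slower than a ~1-nm drug like
vancomycin — so passive diffusion alone delivers phages to their host
bacteria slowly, and biofilm matrices (e.g. curli-fiber meshes) slow them
further. Swarming bacteria, however, generate fluid flows that can carry
phages as passive cargo, turning delivery into an advective process. This
package implements the computational chain used to quantify that effect:

1. **Single-particle motion statistics** (`swarmphage.msd`) — ensemble mean
   squared displacement MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩, the anomalous-diffusion
   exponent α from the power-law fit MSD ∝ τ^α (α < 1 subdiffusive, α ≈ 1
   diffusive, α > 1 superdiffusive/active), the Einstein-relation diffusion
   coefficient D = MSD/(2·dim·τ), and per-track path-length speeds.
2. **Transport predictions** (`swarmphage.transport`) — Stokes–Einstein
   diffusivity D = k_BT/(6πηr); the linear front speed s₂ = s₁/π of a
   circularly vortexing swarm that advances one vortex diameter per
   revolution; explicit conservative finite-difference solutions of
   ∂C/∂t = D ∂²C/∂x² − v_d ∂C/∂x with zero-flux boundaries; and the
   concentration-front distance (largest x with C ≥ 1% of max).
3. **Image quantification** (`swarmphage.imaging`) — segmented prey-colony
   area over time, a second-order regression trend with a pointwise 95%
   confidence band, endpoint clearance rates and their
   experiment-vs-control ratio, and per-slice phage coverage along a
   confocal z-stack with the depth of maximum coverage.
4. **Synthetic data with ground truth** (`swarmphage.synth`) — seeded
   generators for Brownian / fractional-Brownian / advective trajectories,
   shrinking-colony timelapses, and biofilm z-stacks with a configurable
   phage depth law, so every stage is testable without raw microscopy.

Trajectories load from TrackMate-style "exported tracks" XML or plain CSV
(`track_id,frame,x,y[,t]`); images from multi-page TIFF; all analysis is in
physical units (μm, s) via an explicit calibration.

## Worked example

Generate a superdiffusive ensemble (fractional Brownian motion with target
exponent α = 1.22, 300 tracks × 200 steps) and analyse it:

```sh
swarmphage synth trajectories --model fbm --alpha 1.22 \
    --n-steps 200 --n-particles 300 --seed 1 --out fbm
swarmphage track-stats fbm/tracks.csv --frame-interval 1.0 --out stats
```

```
Power-law MSD fit over lags [1, 50] s (50 points)
  alpha         = 1.2523
  prefactor     = 0.145 um^2/s^alpha
  r-squared     = 0.9992
```

The fitted α = 1.25 recovers the generator's 1.22 within the ±0.1 sampling
scatter of 300 tracks, and `stats/summary.json` classifies the motion as
`superdiffusive` — the signature of active transport rather than diffusion.

Predict how far swarm flow carries phages in 3.3 h, with the swarm-fluid
diffusivity D = 0.228 μm²/s and the swarm's linear speed 6.36 μm/min
(= 20 μm/min vortexing speed ÷ π):

```sh
swarmphage predict --D 0.228 --v 6.36 --t 3.3 --out predict.json
```

```
front distance: 1484 um
```

i.e. ~1,500 μm — an order of magnitude beyond what diffusion alone achieves
over the same interval, and in agreement with the closed-form front position
v_d·t + 3.035·√(2Dt) ≈ 1,483 μm.

Other subcommands: `simulate` (concentration profiles to CSV), `biomass`
(colony-area time series from a timelapse TIFF), `depth` (z-stack coverage
profile and peak depth), `synth colony` / `synth biofilm` (image generators
with ground-truth sidecars). Library use mirrors the CLI:

```python
from swarmphage import ensemble_msd, fit_msd_power_law, read_trajectories_csv, Calibration

ens = read_trajectories_csv("fbm/tracks.csv", Calibration(pixel_size=1.0, frame_interval=1.0))
fit = fit_msd_power_law(ensemble_msd(ens))
print(fit.summary())
```

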
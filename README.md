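# dmbp — delay-compensated Bayesian motion estimation and the flash-lag effect

Visual systems receive sensory input with a delay of the order of 100 ms, yet
track moving objects accurately. `dmbp` implements a Bayesian account of how
this can work — and of the flash-lag effect (FLE), the illusion in which a
moving object is perceived *ahead* of a physically aligned flash — as a
simulation package for computational-neuroscience work on position coding.

The estimator is a particle filter over the joint state
`z = (x, y, u, v)` (position on a toroidal screen, velocity) that

1. assimilates each movie frame pair only after a fixed sensory delay τ,
   using a motion-energy likelihood (the cross-correlation of a local window
   of the current frame with the previous frame back-translated by `(u, v) δt`,
   scaled by the measurement variance `σ_I² + σ_noise²`);
2. propagates its belief with a motion-coherency transition prior

       x' = x + u·Δt + ν_x,   ν_x ~ N(0, D_X·|Δt|)
       u' = γ·u + ν_u,        ν_u ~ N(0, (σ_p⁻² + D_V⁻¹)⁻¹·|Δt|)

   where `γ = (1 + D_V/σ_p²)⁻¹` is the damping induced by a zero-mean
   slow-speed prior of scale `σ_p` (constants on the pixel-and-frame scale of
   the sensor);
3. compensates the delay by *extrapolating* the delayed posterior
   `p(z_{t−τ} | I_{0:t−τ})` (the **source layer**) forward by τ with the same
   transition model, yielding the present-time belief `p(z_t | I_{0:t−τ})`
   (the **target layer**).

Because the extrapolation transports each hypothesis along its own velocity,
a moving dot's estimate is pushed ahead by `u·τ` while a static flash's is
not — the flash-lag effect follows, including its flash-initiated half-cycle
variant, the motion-reversal timing, and contrast/duration dependencies.
A position-based control model (velocity carries no predictive information)
shows no lag. An exact grid filter is included as a test oracle, and both the
"push" ordering above and the equivalent "pull" ordering (evidence transported
to the present time) are available.

## Worked example

```python
import dmbp

stim = dmbp.standard_params("standard")   # moving dot + mid-path flash
model = dmbp.ModelParams()                # τ = 100 ms, 2000 particles
movie = dmbp.render_movie(stim, seed=1)   # 100 noisy 256x256 frames
trace = dmbp.run_dmbp(movie, model, seed=1)

lag, peak = dmbp.measure_lag(trace)
print(f"peak frame {peak}, spatial lead {lag:.3f}")
print(f"flash processing delay {dmbp.processing_delay_ms(trace):.0f} ms")
```

prints

```
peak frame 60, spatial lead 0.240
flash processing delay 20 ms
```

i.e. in this trial the flash is seen most precisely at frame 60 (20 ms after
its delayed input arrives), at which moment the moving dot's estimated
position leads the flash estimate by 0.24 space units — about the distance
the dot travels in one delay τ (0.2 for speed 1), so the delay is fully
compensated. Averaged over 20 seeded trials the lead is 0.19–0.21.

The same pipeline is scriptable from the shell:

```bash
dmbp run --condition standard --ntrials 20 --seed 0 --out runs/
dmbp run --condition reversal --smooth 0.1 --ntrials 20 --seed 0 --out runs/
dmbp sweep --variable speed --values 0.5:3.0:0.5 --ntrials 10 --out runs/
dmbp render --condition flash_terminated --out movie.h5
```

Each run writes a CSV (one row per trial with its seed), per-trial HDF5
traces and a JSON manifest, so every number can be regenerated exactly.

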
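# shoalkit

Quantitative tools for collective fish behaviour: a 3D **inertial Vicsek
model**, trajectory statistics (reorientation time, polarization,
persistence lengths) and an **eigenshape posture analysis** (bending
index), together with synthetic-data generators so the whole pipeline is
testable without recordings.

The package targets the analysis workflow used to compare wildtype
zebrafish with skeletally stiffer mutants: mutants bend their bodies
less while swimming, take longer to reorient, and — counterintuitively —
school *more* orderly, a behaviour captured by modelling them as
self-propelled agents with lower orientational noise.

## The model and the statistics

**Inertial Vicsek model.** N agents move at constant speed v0 in a
periodic cubic box of edge L = (N/ρ)^(1/3). Each step, agent i aligns
with the agents within an interaction radius (set S_i, including
itself), the alignment direction is perturbed uniformly on a spherical
cap of solid angle 4πη, and an inertial weight α mixes it with the
previous velocity:

```
v_i(t+1) = v0 Θ[(1−α) v0 R_η[Θ(Σ_{j∈S_i} v_j(t))] + α v_i(t)]
```

where Θ normalises a vector and R_η applies the cap noise. η = 1 is
completely random; lowering η below ≈ 0.8 at the fish-fitted parameters
(v0 = 0.1, ρ = 0.5, α = 0.63, N = 25) drives an order–disorder
transition.

**Trajectory statistics.** Velocities are forward differences of
positions at fixed frame rate; the heading ACF
C(t) = ⟨ê(s)·ê(s+t)⟩ is fitted with C(t) = A e^(−t/τ) (A ≤ 1) to get the
reorientation time τ. Group order is the polarization
Φ = |Σ_i v_i/|v_i|| / N ∈ [0, 1]; the persistence length l_p = τ·⟨speed⟩
divided by the mean nearest-neighbour distance l_nn gives the
dimensionless reduced persistence length l_p/l_nn that lets experiments
and simulations share one axis.

**Posture analysis.** Single-fish frames are thresholded, the largest
component is kept, and the silhouette is translated/rotated into a
canonical 50×50 grid. Stacking m flattened shapes into X (m × 2500), the
eigenvectors of the uncentered second-moment matrix C = XᵀX are the
shape modes; the second mode typically encodes body bending, and the
*bending index* of a frame is the projection x·b onto that mode.

## Worked example

```python
import numpy as np
from shoalkit.synthetic import WalkGenSpec, gen_persistent_walk
from shoalkit.trajectories import kinematics, orientation_acf, fit_exponential_acf
from shoalkit.vicsek import SimParams, noise_sweep

# a 10-minute synthetic fish with reorientation time 0.38 s at 15 fps
walk = gen_persistent_walk(WalkGenSpec(duration=600.0, frame_rate=15.0,
                                       tau=0.38, seed=0))
kin = kinematics(walk)
acf = orientation_acf(kin.orientations, max_lag=3.0)
fit = fit_exponential_acf(acf)
print(f"fitted tau = {fit.tau:.3f} s (A = {fit.amplitude:.3f})")

# polarization of a 25-agent group across the noise sweep
params = SimParams(n_agents=25, density=0.5, speed=0.1, inertia=0.63,
                   noise=0.65, burn_in_steps=5000, sample_steps=5000, seed=0)
print(noise_sweep(params, [0.65, 0.80, 1.00]).round(3))
```

prints

```
fitted tau = 0.402 s (A = 0.993)
    eta  phi_mean  phi_se  n_samples
0  0.65     0.501   0.010       5000
1  0.80     0.318   0.009       5000
2  1.00     0.183   0.002       5000
```

The fitted τ recovers the 0.38 s target within the Monte-Carlo error of
a 9 000-frame walk. The sweep shows the ordered state at low noise
(Φ ≈ 0.50 at η = 0.65) relaxing to the random baseline for 25 unit
vectors (Φ ≈ 0.184) at η = 1; the standard errors come from batch means
because consecutive frames are correlated.

The same operations are available from the shell:

```sh
shoalkit synth-traj --tau 0.38 --duration 600 --out walk.csv
shoalkit traj-stats --in walk.csv --fps 15 --min-speed 0 --out stats/
shoalkit sweep --config sim.yaml --eta-grid 0.65:1.0:0.05 --out sweep.csv
```

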
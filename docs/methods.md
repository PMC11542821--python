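# Methods

This note records the models, conventions and numerical choices behind
shoalkit, in the spirit of a simulator's model documentation: what is
computed, under which assumptions, and what the synthetic data can and
cannot show.

## Inertial Vicsek model

Agents move at constant speed `v0` in a cubic box of edge
`L = (N/ρ)^(1/3)` with periodic boundaries (minimum-image convention for
all distances). One time step (`Δt = 1`) updates each agent by

1. summing the velocities of all agents within the interaction radius —
   the focal agent is always a member of its own neighbour set, the
   standard Vicsek convention;
2. normalising that sum and resampling it uniformly on the spherical cap
   of solid angle `4πη` centred on it (`cos θ` uniform on `[1−2η, 1]`,
   azimuth uniform);
3. mixing the noisy alignment direction with the previous velocity,
   `(1−α) v0 w + α v`, renormalising to speed `v0`;
4. streaming positions with the *new* velocity and wrapping into
   `[0, L)` (forward/streaming order, the common choice in Vicsek
   implementations).

Parameters that matter and their defaults: interaction radius 1 box
unit (exposed); `α = 0.63`, `v0 = 0.1`, `ρ = 0.5`, `N = 25` are the
values fitted to groups of 25 fish and are used by the tests and the
acceptance script; `ρ = 1` is the corresponding 50-fish density. A
vanishing neighbour sum, or a vanishing mixing vector, is a
measure-zero degeneracy resolved by substituting a uniformly random
direction and logging the event.

One simulation step has no intrinsic physical duration; conversion to
seconds and millimetres is always a user-supplied scale
(`gen_group_trajectories(length_scale, time_scale)`), never hard-coded.

Runs are reproducible from a single seed. Noise sweeps give each grid
entry a fresh child seed (SeedSequence spawn), with an explicit
`sub_seeds` override for callers that need row-level determinism across
repeated grid values.

**Steady-state protocol.** The acceptance runs use 2×10⁴ burn-in and
2×10⁴ sampled steps per noise value. These sizes, chosen as the
package's default desk-scale protocol, give batch-mean standard errors
of Φ below 0.01 everywhere on the 0.65–1.0 noise grid; the qualitative
order–disorder trend is insensitive to longer runs. Standard errors of
time-averaged Φ always use batch means (20 blocks) because consecutive
frames are strongly autocorrelated, especially in the ordered phase.

## Trajectory statistics

Velocities are forward differences over consecutive frames,
`v_k = (x_{k+1} − x_k)·fps`, assigned to the earlier frame; differences
never bridge missing frames, and zero displacement masks the heading.
Filtering keeps samples with `speed ≥ 50 mm/s` (the non-moving
exclusion "speed < 50" keeps the boundary value) and `50 < z < 150 mm`
strictly; both filters can be disabled independently.

The orientational ACF averages `ê(s)·ê(s+t)` over all start times and
individuals, with pairs restricted to maximal runs of consecutive valid
frames, so no pair spans a gap or a masked sample. This is the direct
(non-FFT) definition; series are short enough that the O(lags·frames)
cost is irrelevant.

The exponential fit `C(t) = A e^(−t/τ)` uses bounded least squares
(`0 < A ≤ 1`, `τ > 0`, trust-region reflective). The default window runs
from lag 0 to the first lag where `C < e^(−2)` (or the last lag); both
window and bounds are exposed. An ACF that never decays below 0.95 in
the window is reported as a diagnostic error rather than an unbounded
τ. Group reorientation times default to a fit of the pooled ACF; a
per-individual route (fit each fish, average) is available through the
same functions by passing one series at a time.

Windowed group summaries use non-overlapping windows (default 120 s):
per window, mean Φ (zero-velocity individuals dropped with N adjusted),
mean nearest-neighbour distance, τ from the within-window pooled ACF,
`l_p = τ·⟨speed⟩` and `l_p/l_nn`. Windows whose ACF cannot be fitted
report NaN for the τ-derived columns with a warning instead of failing
the whole summary.

## Posture pipeline

Segmentation thresholds the image (pixels below the threshold are
background) and keeps the largest 8-connected component. Alignment
moves the intensity-weighted centroid to the centre of a `w×w` grid
(`w = 50`) and rotates the major principal axis of the second-moment
tensor onto the horizontal axis with bilinear interpolation; the
remaining 180° ambiguity is resolved by making the third central moment
along the major axis non-negative. For an elongated but head–tail
symmetric silhouette this moment is numerically tiny, so the flip is an
arbitrary deterministic tie — which is why all bending statistics
downstream are based on `|index|` or variances, both flip-invariant.
Isotropic shapes (a disc) skip the rotation and are logged.

The eigenmode decomposition operates on the *uncentered* second-moment
matrix `C = XᵀX` (via SVD of X). Uncentered, the leading mode captures
the mean elongated body, making the second mode the bending mode; this
is the package default, with ordinary mean-centred PCA behind a flag
(cross-checked against scikit-learn's PCA in the tests). Mode signs are
fixed so that a canonical upward C-bend projects positively (upper-half
grid mass rule). The bending mode defaults to the second eigenvector
but is overridable — on datasets with unusual variance structure the
bending mode can appear elsewhere in the spectrum, and the class
attribute makes that explicit rather than guessing.

Bending–speed profiles average per-individual means within speed bins
and report the SE across individuals; bins with no data are reported as
missing (NaN, n=0), never as zero.

## Synthetic data

The generators produce data with exactly the statistical structure the
analysis assumes — no more. Passing tests therefore demonstrate
correctness of the pipeline's mathematics, not robustness to optics,
tracking errors, wall effects or speed–turn coupling of real recordings.

**Silhouettes.** A constant-curvature midline arc of length 30 px with
an elliptically tapering half-width (max width 8 px) on a 50×50 grid,
bright on dark with a ~1 px soft edge and optional additive Gaussian
pixel noise (sd 0.05 of contrast in the test conditions). Curvature κ
is signed; presets: wildtype-like `κ ~ N(0, 0.04 px⁻¹)` (broad,
burst-and-coast-like bending) and mutant-like `κ ~ N(0, 0.012 px⁻¹)`
(narrow, stiff spine). The self-overlap bound `|κ|·length < π` is
enforced. Datasets are pushed through the real segmentation + alignment
pipeline so rows are exactly what the analysis sees.

**Persistent walks.** The heading performs a random walk on the unit
sphere with one isotropic tangential Gaussian step per frame,
renormalised. Because successive rotations are independent and
azimuthally symmetric, the l=1 spherical-harmonic coefficient
multiplies per step, so `⟨ê(0)·ê(n)⟩ = (E[cos θ])ⁿ` exactly; the noise
scale is solved (closed form `√(πa)·erfcx(√a)`, inverted with Brent's
method) so that `E[cos θ] = e^(−Δt/τ)`. The ACF is therefore exactly
`e^(−t/τ)` at every frame lag with no discretisation bias — the
rotational-diffusion law with `D_r = 1/(2τ)`. Per-frame speeds are
drawn independently of heading from a folded-normal mixture: unimodal
(mutant-like) mode 100 mm/s sd 30; bimodal (wildtype-like burst-and-
coast) modes 0 and 150 mm/s, sds 30, weights 0.4/0.6. Speed–posture and
speed–turn coupling are deliberately absent (documented extension
point). Positions integrate forward so that downstream forward
differences recover heading and speed exactly.

**Group trajectories.** Simulator output is exported with *unwrapped*
coordinates (cumulative displacement), so finite-difference velocities
are exact across periodic-boundary crossings; nearest-neighbour
distances on raw simulator frames use the wrapped positions with the
periodic flag instead.

## Numerical choices and degenerate inputs

- Normalisations use explicit `sqrt(Σx²)` row norms; the simulator's
  vectorized step is verified bit-identical to a naive per-agent
  reference over ten steps.
- Histogram edges are padded (datum centred mid-bin) when a data range
  is numerically degenerate, e.g. a perfectly circular orbit.
- The pair polarization baseline has the closed form `E[Φ] = 2/3`
  (`|u₁+u₂| = √(2+2c)`, `c` uniform on `[−1, 1]`), used as an oracle.
- Curve-fit initial values: `A₀ = clip(C(0), 0.5, 1)`, `τ₀` from the
  first `e^(−1)` crossing.
- Desk-scale problem sizes used by tests and the acceptance script:
  10⁴-frame walks for τ recovery (relative errors 1–4 %, bound 10 %);
  300–500 silhouettes per curvature level; 2×10⁴-step simulation
  samples.

## Known limitations

- The simulator models a periodic box only — no bowl-shaped tank, walls
  or refraction; comparisons with confined fish rest on dimensionless
  quantities (Φ, l_p/l_nn).
- The posture analysis is strictly quasi-2d single-fish; multi-fish
  frames and 3D bending are out of scope.
- Folded-normal speed mixtures reproduce uni/bimodality but not the
  detailed burst-and-coast waveform; heading and speed are independent.
- The 180° head–tail tie for symmetric silhouettes makes the *sign* of
  an individual bending index convention-dependent; only magnitudes and
  distributions are comparable across datasets.
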
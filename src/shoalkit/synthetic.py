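"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* bent elongated silhouettes with controlled midline curvature, emulating
  a single fish imaged from above (wildtype-like populations bend over a
  broad curvature range, mutant-like ones over a narrow low range);
* persistent random walks whose heading undergoes rotational diffusion
  with diffusivity ``D_r = 1 / (2 tau)``, so the orientational ACF is
  exactly ``exp(-t / tau)``, with unimodal (mutant-like, single peak near
  100 mm/s) or bimodal (wildtype-like burst-and-coast, preferred speed
  near 150 mm/s) speed models;
* simulator-backed group trajectories converted to physical units.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfcx

from . import vicsek
from .posture import align_shape, segment
from .trajectories import Trajectory

__all__ = [
    "ShapeGenSpec",
    "SpeedModel",
    "WalkGenSpec",
    "gen_bent_shape",
    "gen_shape_dataset",
    "gen_persistent_walk",
    "gen_group_trajectories",
    "wildtype_curvatures",
    "mutant_curvatures",
    "CURVATURE_PRESETS",
]


@dataclass(frozen=True)
class ShapeGenSpec:
    """Parameters of one synthetic bent-fish silhouette.

    The body is a constant-curvature midline arc of ``length`` pixels
    with a tapering elliptical half-width profile, drawn bright on a dark
    background (peak intensity ``contrast``) with optional additive
    Gaussian pixel noise.
    """

    size: int = 50  # grid width w
    length: float = 30.0  # body length, px
    width: float = 8.0  # maximal body width, px
    curvature: float = 0.0  # midline curvature kappa, 1/px
    contrast: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.length < self.size:
            raise ValueError("body length must be positive and smaller than the grid")
        if abs(self.curvature) * self.length >= np.pi:
            raise ValueError(
                f"self-overlapping body: |kappa| * length = "
                f"{abs(self.curvature) * self.length:.3f} >= pi"
            )
        if self.width <= 0 or self.contrast <= 0 or self.noise_sd < 0:
            raise ValueError("width and contrast must be positive, noise_sd >= 0")


@dataclass(frozen=True)
class SpeedModel:
    """Mixture-of-folded-normals per-frame speed distribution (mm/s).

    ``abs(Normal(mode, sd))`` per component keeps speeds non-negative; a
    mode at 0 yields the half-normal burst-and-coast "coast" peak.
    """

    modes: tuple[float, ...] = (100.0,)
    sds: tuple[float, ...] = (30.0,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not len(self.modes) == len(self.sds) == len(self.weights):
            raise ValueError("modes, sds and weights must have equal length")
        if any(m < 0 for m in self.modes) or any(s <= 0 for s in self.sds):
            raise ValueError("modes must be >= 0 and sds > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        comp = rng.choice(len(self.modes), size=n, p=w / w.sum())
        draws = rng.normal(np.asarray(self.modes)[comp], np.asarray(self.sds)[comp])
        return np.abs(draws)


#: mutant-like: single peak around 100 mm/s
UNIMODAL_DEFAULT = SpeedModel(modes=(100.0,), sds=(30.0,), weights=(1.0,))
#: wildtype-like burst-and-coast: slow coast peak plus preferred ~150 mm/s burst
BIMODAL_DEFAULT = SpeedModel(modes=(0.0, 150.0), sds=(30.0, 30.0), weights=(0.4, 0.6))


@dataclass(frozen=True)
class WalkGenSpec:
    """Parameters of one persistent-random-walk trajectory."""

    duration: float = 60.0  # s
    frame_rate: float = 15.0  # fps
    tau: float = 0.38  # target reorientation time, s
    speed_model: SpeedModel = field(default_factory=lambda: UNIMODAL_DEFAULT)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if self.tau <= 0 and not np.isinf(self.tau):
            raise ValueError("tau must be positive (inf allowed for a straight walk)")


def gen_bent_shape(spec: ShapeGenSpec) -> np.ndarray:
    """Render one bent silhouette; reproducible from the spec seed.

    The midline is an arc of curvature kappa through the grid centre with
    its chord horizontal (positive kappa bulges toward smaller row
    indices, i.e. "up" in image display).  Pixel intensity falls off
    linearly over ~1 px beyond the local half-width, giving a soft edge.
    """
    rng = np.random.default_rng(spec.seed)
    w, ell, kappa = spec.size, spec.length, spec.curvature
    s = np.linspace(-ell / 2, ell / 2, 256)
    if kappa == 0.0:
        mx, my = s, np.zeros_like(s)
    else:
        mx = np.sin(kappa * s) / kappa
        my = (1.0 - np.cos(kappa * s)) / kappa
    # half-width: elliptical taper to points at both ends
    half_w = (spec.width / 2.0) * np.sqrt(np.clip(1.0 - (2 * s / ell) ** 2, 0.0, None))
    c = (w - 1) / 2.0
    ys, xs = np.mgrid[0:w, 0:w]
    # image rows increase downward; negate the midline y so +kappa bends "up"
    px = xs - c
    py = c - ys
    d = np.sqrt((px[..., None] - mx) ** 2 + (py[..., None] - my) ** 2) - half_w
    dist = d.min(axis=-1)
    img = spec.contrast * np.clip(1.0 - np.maximum(dist, 0.0), 0.0, 1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def wildtype_curvatures(rng: np.random.Generator, m: int) -> np.ndarray:
    """Broad signed curvature distribution, Normal(0, 0.04 1/px).

    Bends to either side are equally likely, as for a real fish; the
    broad spread emulates the pronounced intermittent bending of the
    burst-and-coast swimming style.
    """
    return rng.normal(0.0, 0.04, size=m)


def mutant_curvatures(rng: np.random.Generator, m: int) -> np.ndarray:
    """Narrow signed curvature distribution, Normal(0, 0.012 1/px) (stiff spine)."""
    return rng.normal(0.0, 0.012, size=m)


CURVATURE_PRESETS: dict[str, Callable[[np.random.Generator, int], np.ndarray]] = {
    "wildtype": wildtype_curvatures,
    "mutant": mutant_curvatures,
}


def gen_shape_dataset(
    m: int,
    curvature_sampler: str | Callable[[np.random.Generator, int], np.ndarray],
    template: ShapeGenSpec = ShapeGenSpec(),
    rng: np.random.Generator | None = None,
    threshold: float | None = None,
    binary: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate m aligned shapes with recorded true curvatures.

    Each shape is rendered from the template with a sampled curvature and
    a random whole-image rotation/offset jitter, then pushed through the
    segmentation + alignment pipeline, so the rows of the returned matrix
    are exactly what the analysis would see.  Returns ``(X, kappas)``
    where X has shape (m, w**2).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if isinstance(curvature_sampler, str):
        curvature_sampler = CURVATURE_PRESETS[curvature_sampler]
    rng = np.random.default_rng(0) if rng is None else rng
    if threshold is None:
        threshold = 0.5 * template.contrast
    kappas = np.clip(
        curvature_sampler(rng, m),
        -0.95 * np.pi / template.length,
        0.95 * np.pi / template.length,
    )
    from dataclasses import replace

    rows = []
    for k in kappas:
        spec = replace(template, curvature=float(k), seed=int(rng.integers(2**31)))
        img = gen_bent_shape(spec)
        mask = segment(img, threshold)
        source = mask.astype(float) if binary else np.where(mask, img, 0.0)
        rows.append(align_shape(source, w=template.size).vector)
    return np.array(rows), kappas


def _tangent_sigma(decay: float) -> float:
    """Tangent-noise scale whose renormalised step has E[cos(step angle)] = decay.

    One step perturbs the heading by two i.i.d. N(0, sigma^2) tangential
    components and renormalises, so ``cos(theta) = 1 / sqrt(1 + r^2)``
    with ``r^2`` exponential of mean ``2 sigma^2``.  Its expectation has
    the closed form ``sqrt(pi a) * erfcx(sqrt(a))`` with
    ``a = 1 / (2 sigma^2)``; this inverts it numerically.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError("decay factor must lie in (0, 1)")

    def mean_cos(log_a: float) -> float:
        a = np.exp(log_a)
        return float(np.sqrt(np.pi * a) * erfcx(np.sqrt(a)))

    log_a = brentq(lambda la: mean_cos(la) - decay, -30.0, 30.0)
    return float(np.sqrt(0.5 * np.exp(-log_a)))


def _diffuse_headings(
    n_frames: int, tau: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Persistent heading sequence with exactly exponential orientational ACF.

    The heading performs a random walk on the unit sphere: one isotropic
    tangential Gaussian perturbation per frame, renormalised.  Because
    consecutive rotations are independent and azimuthally symmetric, the
    first spherical-harmonic coefficient multiplies per step, so
    ``<e(0) . e(n)> = (E[cos theta])**n``; the noise scale is chosen so
    that ``E[cos theta] = exp(-dt / tau)``, giving
    ``C(t) = exp(-t / tau)`` exactly at every frame lag (the
    rotational-diffusion law with diffusivity ``D_r = 1 / (2 tau)``).
    """
    e = rng.normal(size=3)
    e /= np.linalg.norm(e)
    if np.isinf(tau):
        return np.tile(e, (n_frames, 1))
    sigma = _tangent_sigma(np.exp(-dt / tau))
    headings = np.empty((n_frames, 3))
    headings[0] = e
    noise = rng.normal(0.0, sigma, size=(n_frames - 1, 2))
    for i in range(1, n_frames):
        helper = np.zeros(3)
        helper[np.argmin(np.abs(e))] = 1.0
        t1 = np.cross(e, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(e, t1)
        e = e + noise[i - 1, 0] * t1 + noise[i - 1, 1] * t2
        e /= np.linalg.norm(e)
        headings[i] = e
    return headings


def gen_persistent_walk(spec: WalkGenSpec) -> Trajectory:
    """Persistent random walk with target reorientation time tau.

    Heading and per-frame speed are sampled independently; positions are
    integrated with the forward rule ``x_{k+1} = x_k + speed_k * e_k / fps``
    so that downstream forward-difference kinematics recover the heading
    and speed exactly.
    """
    n_frames = int(round(spec.duration * spec.frame_rate)) + 1
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    headings = _diffuse_headings(n_frames - 1, spec.tau, dt, rng)
    speeds = spec.speed_model.sample(n_frames - 1, rng)
    steps = headings * speeds[:, None] * dt
    positions = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Trajectory(
        individual_id="walk",
        frame_rate=spec.frame_rate,
        frames=np.arange(n_frames),
        positions=positions,
    )


def gen_group_trajectories(
    params: vicsek.SimParams,
    length_scale: float = 1.0,
    time_scale: float = 1.0,
) -> list[Trajectory]:
    """Simulator output as per-individual trajectories in physical units.

    Positions are *unwrapped* (cumulative displacement from the first
    sampled frame) so that finite-difference velocities are correct
    across periodic-boundary crossings; multiply by ``length_scale`` (mm
    per box unit) and use ``1 / time_scale`` as the frame rate (seconds
    per simulation step).
    """
    if length_scale <= 0 or time_scale <= 0:
        raise ValueError("length_scale and time_scale must be positive")
    traj = vicsek.run(params)
    if not traj.frames:
        return []
    pos0 = traj.frames[0].positions
    # displacements from the recorded velocities: x(t+1) = wrap(x(t) + v(t+1))
    disp = np.zeros((len(traj.frames), params.n_agents, 3))
    for t in range(1, len(traj.frames)):
        disp[t] = disp[t - 1] + traj.frames[t].velocities
    unwrapped = (pos0[None] + disp) * length_scale
    frames_idx = np.arange(len(traj.frames))
    return [
        Trajectory(
            individual_id=i,
            frame_rate=1.0 / time_scale,
            frames=frames_idx,
            positions=unwrapped[:, i, :],
        )
        for i in range(params.n_agents)
    ]
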
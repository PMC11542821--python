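"""3D inertial Vicsek model in a periodic cubic box.

Self-propelled agents move at constant speed ``v0`` and align with
neighbours within a fixed interaction radius.  Orientational noise is
applied by resampling the alignment direction uniformly on a spherical
cap of solid angle ``4*pi*eta`` centred on it, and an inertial term
``alpha`` mixes the noisy alignment direction with the agent's previous
velocity, slowing reorientation::

    v_i(t+1) = v0 * N[ (1-alpha) * v0 * R_eta[ N(sum_{j in S_i} v_j(t)) ]
                       + alpha * v_i(t) ]

where ``N`` normalises a vector and ``S_i`` is the set of agents within
the interaction radius of agent ``i`` (including ``i`` itself, the
standard Vicsek convention).  ``eta = 1`` resamples on the whole sphere
(completely random), ``eta = 0`` applies no noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "AgentState",
    "SimTrajectory",
    "box_length",
    "sample_cap_direction",
    "neighbor_sum",
    "step",
    "run",
    "iterate_states",
    "noise_sweep",
    "batch_mean_se",
]


def box_length(n_agents: int, density: float) -> float:
    """Edge length L of the cubic box holding ``n_agents`` at number density rho.

    Uses the convention rho = N / L**3, i.e. ``L = (N / rho) ** (1/3)``.
    """
    if n_agents < 1:
        raise ValueError(f"n_agents must be >= 1, got {n_agents}")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    return float((n_agents / density) ** (1.0 / 3.0))


@dataclass(frozen=True)
class SimParams:
    """Configuration of one inertial Vicsek run.

    Parameters
    ----------
    n_agents : int
        Number of agents N.
    density : float
        Number density rho = N / L**3; sets the box length.
    speed : float
        Constant self-propulsion speed v0 (box units per step).
    inertia : float
        Mixing weight alpha in [0, 1]; alpha = 0 is the standard Vicsek
        update, alpha = 1 freezes every agent's velocity.
    noise : float
        Cap-noise amplitude eta in [0, 1]; the noisy direction is uniform
        on a spherical cap of solid angle 4*pi*eta.
    interaction_radius : float
        Alignment neighbourhood radius (box units), default 1.
    burn_in_steps, sample_steps : int
        Steps discarded to reach steady state, then steps recorded.
    seed : int
        Seed of the single RNG driving the run.
    """

    n_agents: int
    density: float
    speed: float
    inertia: float
    noise: float
    interaction_radius: float = 1.0
    burn_in_steps: int = 0
    sample_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0.0 <= self.inertia <= 1.0:
            raise ValueError(f"inertia must lie in [0, 1], got {self.inertia}")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError(f"noise must lie in [0, 1], got {self.noise}")
        if self.interaction_radius <= 0:
            raise ValueError("interaction_radius must be positive")
        if self.burn_in_steps < 0 or self.sample_steps < 0:
            raise ValueError("step counts must be non-negative")

    @property
    def box(self) -> float:
        """Cubic box edge length L = (N / rho)**(1/3)."""
        return box_length(self.n_agents, self.density)


@dataclass(frozen=True)
class AgentState:
    """Positions and velocities of all agents at one time step."""

    time: int
    positions: np.ndarray  # (N, 3), each coordinate in [0, L)
    velocities: np.ndarray  # (N, 3), each row of norm v0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SimTrajectory:
    """A recorded run: parameters plus the sampled states."""

    params: SimParams
    frames: tuple[AgentState, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns step, agent_id, x, y, z, vx, vy, vz."""
        rows = []
        for state in self.frames:
            n = state.n_agents
            rows.append(
                np.column_stack(
                    [
                        np.full(n, state.time),
                        np.arange(n),
                        state.positions,
                        state.velocities,
                    ]
                )
            )
        cols = ["step", "agent_id", "x", "y", "z", "vx", "vy", "vz"]
        if not rows:
            return pd.DataFrame(columns=cols)
        out = pd.DataFrame(np.concatenate(rows), columns=cols)
        out["step"] = out["step"].astype(int)
        out["agent_id"] = out["agent_id"].astype(int)
        return out


def _normalize_rows(vectors: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Normalise rows to unit length; zero rows get a uniformly random direction.

    An exactly cancelling sum is a measure-zero event; it is resolved by a
    random unit vector and logged.
    """
    norms = np.linalg.norm(vectors, axis=1)
    zero = norms == 0.0
    if np.any(zero):
        logger.warning("substituting random direction for %d zero-norm vector(s)", zero.sum())
        sub = rng.normal(size=(int(zero.sum()), 3))
        sub /= np.linalg.norm(sub, axis=1, keepdims=True)
        vectors = vectors.copy()
        vectors[zero] = sub
        norms = norms.copy()
        norms[zero] = 1.0
    return vectors / norms[:, None]


def _cap_directions(centers: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples on the spherical cap of solid angle 4*pi*noise per row.

    cos(theta) is uniform on [1 - 2*noise, 1] and the azimuth about each
    centre is uniform on [0, 2*pi); this gives a uniform density on the cap.
    Consumes ``rng.random((n, 2))`` regardless of centre values.
    """
    n = centers.shape[0]
    u = rng.random((n, 2))
    cos_t = 1.0 - 2.0 * noise * u[:, 0]
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * np.pi * u[:, 1]
    # orthonormal frame around each centre; helper axis = least-aligned axis
    helper = np.zeros_like(centers)
    helper[np.arange(n), np.argmin(np.abs(centers), axis=1)] = 1.0
    e1 = np.cross(centers, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(centers, e1)
    return (
        cos_t[:, None] * centers
        + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


def sample_cap_direction(
    center: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one direction uniformly on the cap of solid angle 4*pi*noise.

    ``noise = 0`` returns ``center`` exactly (zero-amplitude cap, no RNG
    draw); ``noise = 1`` is uniform on the whole sphere.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise ValueError("center must be a 3-vector")
    if not np.isclose(np.linalg.norm(center), 1.0, atol=1e-8):
        raise ValueError("center must be a unit vector")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    if noise == 0.0:
        return center.copy()
    return _cap_directions(center[None, :], noise, rng)[0]


def _min_image_delta(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def neighbor_sum(
    state: AgentState, index: int, radius: float, box: float
) -> np.ndarray:
    """Sum of velocities of agents within ``radius`` of agent ``index``.

    Distances use the minimum-image convention in the periodic cubic box;
    the focal agent is always included (distance zero).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    delta = _min_image_delta(state.positions - state.positions[index], box)
    within = np.einsum("ij,ij->i", delta, delta) <= radius**2
    return state.velocities[within].sum(axis=0)


def _all_neighbor_sums(
    positions: np.ndarray, velocities: np.ndarray, radius: float, box: float
) -> np.ndarray:
    delta = _min_image_delta(positions[:, None, :] - positions[None, :, :], box)
    within = np.einsum("ijk,ijk->ij", delta, delta) <= radius**2
    return within @ velocities


def step(state: AgentState, params: SimParams, rng: np.random.Generator) -> AgentState:
    """Advance all agents by one time step (dt = 1).

    Each agent aligns with the normalised neighbour velocity sum, the
    alignment direction is perturbed on the eta-cap, the result is mixed
    with the previous velocity through the inertia weight alpha, and the
    new velocity is rescaled to speed v0.  Positions stream with the new
    velocity and wrap into [0, L).
    """
    box = params.box
    nsum = _all_neighbor_sums(
        state.positions, state.velocities, params.interaction_radius, box
    )
    align = _normalize_rows(nsum, rng)
    if params.noise > 0.0:
        align = _cap_directions(align, params.noise, rng)
    mix = (1.0 - params.inertia) * params.speed * align + params.inertia * state.velocities
    velocities = params.speed * _normalize_rows(mix, rng)
    positions = np.mod(state.positions + velocities, box)
    return AgentState(state.time + 1, positions, velocities)


def _initial_state(params: SimParams, rng: np.random.Generator) -> AgentState:
    positions = rng.random((params.n_agents, 3)) * params.box
    headings = rng.normal(size=(params.n_agents, 3))
    headings /= np.linalg.norm(headings, axis=1, keepdims=True)
    return AgentState(0, positions, params.speed * headings)


def iterate_states(params: SimParams, rng: np.random.Generator) -> Iterator[AgentState]:
    """Yield the post-burn-in states one by one (``sample_steps`` of them)."""
    state = _initial_state(params, rng)
    for _ in range(params.burn_in_steps):
        state = step(state, params, rng)
    for _ in range(params.sample_steps):
        state = step(state, params, rng)
        yield state


def run(params: SimParams) -> SimTrajectory:
    """Run the model from random initial conditions; reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    frames = tuple(iterate_states(params, rng))
    return SimTrajectory(params=params, frames=frames)


def batch_mean_se(values: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the mean of an autocorrelated series by batch means.

    The series is cut into ``n_blocks`` contiguous blocks; the SE of the
    block means estimates the SE of the overall mean without assuming
    independent samples.
    """
    values = np.asarray(values, dtype=float)
    n_blocks = min(n_blocks, len(values))
    if n_blocks < 2:
        return float("nan")
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def noise_sweep(
    params: SimParams,
    noise_grid: Sequence[float],
    sub_seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean steady-state polarization over a grid of noise values.

    One independent run per eta with a fresh deterministic sub-seed
    (children of a SeedSequence rooted at ``params.seed``; pass
    ``sub_seeds`` to control them explicitly).  Returns a table with
    columns eta, phi_mean, phi_se, n_samples; the SE comes from batch
    means over the (autocorrelated) per-frame polarization series.
    """
    from .collective import polarization

    noise_grid = list(noise_grid)
    for eta in noise_grid:
        if not 0.0 <= eta <= 1.0:
            raise ValueError(f"noise value {eta} outside [0, 1]")
    if sub_seeds is None:
        children = np.random.SeedSequence(params.seed).spawn(len(noise_grid))
    else:
        if len(sub_seeds) != len(noise_grid):
            raise ValueError("sub_seeds must match noise_grid length")
        children = list(sub_seeds)
    rows = []
    for eta, child in zip(noise_grid, children):
        p = replace(params, noise=eta)
        rng = np.random.default_rng(child)
        phis = np.fromiter(
            (polarization(state.velocities) for state in iterate_states(p, rng)),
            dtype=float,
            count=p.sample_steps,
        )
        rows.append(
            {
                "eta": eta,
                "phi_mean": phis.mean() if len(phis) else np.nan,
                "phi_se": batch_mean_se(phis),
                "n_samples": len(phis),
            }
        )
    return pd.DataFrame(rows)
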
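"""Naive per-agent reference implementation of the inertial Vicsek update.

Kept deliberately simple (double loops, scalar math) so it can serve as
an independent oracle for the vectorized simulator.
"""

import numpy as np

from shoalkit.vicsek import AgentState


def naive_neighbor_sum(positions, velocities, index, radius, box):
    total = np.zeros(3)
    for j in range(len(positions)):
        d = positions[j] - positions[index]
        d = d - box * np.round(d / box)
        if float(d @ d) <= radius**2:
            total = total + velocities[j]
    return total


def naive_step(state, params, rng):
    """One update step, agent by agent, consuming rng like the implementation:
    one (N, 2) uniform block for the cap noise when noise > 0."""
    n = state.n_agents
    box = params.box
    units = np.empty((n, 3))
    for i in range(n):
        s = naive_neighbor_sum(
            state.positions, state.velocities, i, params.interaction_radius, box
        )
        units[i] = s / np.sqrt(s[0] * s[0] + s[1] * s[1] + s[2] * s[2])
    if params.noise > 0:
        u = rng.random((n, 2))
        noisy = np.empty((n, 3))
        for i in range(n):
            cos_t = 1.0 - 2.0 * params.noise * u[i, 0]
            sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
            phi = 2.0 * np.pi * u[i, 1]
            helper = np.zeros(3)
            helper[np.argmin(np.abs(units[i]))] = 1.0
            e1 = np.cross(units[i], helper)
            e1 = e1 / np.sqrt(e1[0] * e1[0] + e1[1] * e1[1] + e1[2] * e1[2])
            e2 = np.cross(units[i], e1)
            noisy[i] = cos_t * units[i] + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
    else:
        noisy = units
    velocities = np.empty((n, 3))
    for i in range(n):
        mix = (1.0 - params.inertia) * params.speed * noisy[i] + params.inertia * state.velocities[i]
        norm = np.sqrt(mix[0] * mix[0] + mix[1] * mix[1] + mix[2] * mix[2])
        velocities[i] = params.speed * (mix / norm)
    positions = np.mod(state.positions + velocities, box)
    return AgentState(state.time + 1, positions, velocities)
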
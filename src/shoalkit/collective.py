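"""Group-level order and length-scale statistics.

The polarization order parameter

    Phi = (1/N) | sum_i v_i / |v_i| |

approaches 1 when all individuals move in the same direction and is of
order 1/sqrt(N) for random headings.  The persistence length
``l_p = tau * <speed>`` measures how far an individual travels before
losing directional memory; dividing by the mean nearest-neighbour
distance ``l_nn`` gives the dimensionless reduced persistence length
used to compare experiments with simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectories import (
    ACFResult,
    FlatACFError,
    InsufficientDataError,
    OrientationSeries,
    fit_exponential_acf,
    orientation_acf,
)

__all__ = [
    "GroupFrame",
    "CollectiveSummary",
    "polarization",
    "random_polarization_baseline",
    "nn_distance",
    "persistence_stats",
    "windowed_summary",
]


@dataclass(frozen=True)
class GroupFrame:
    """Positions and velocities of a group at one time point."""

    time: float
    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3); zero rows mark invalid individuals


@dataclass(frozen=True)
class CollectiveSummary:
    """Windowed group statistics: order parameter and length scales."""

    window: tuple[float, float]
    phi_mean: float
    l_nn: float
    tau: float
    l_p: float
    reduced_lp: float
    mean_speed: float
    n_frames: int


def polarization(velocities: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Polarization Phi in [0, 1] of a set of velocity vectors.

    Individuals with zero velocity (or excluded by ``mask``) are dropped
    and N adjusted accordingly.
    """
    v = np.asarray(velocities, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    keep = norms > 0
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not np.any(keep):
        raise ValueError("polarization undefined: no valid nonzero velocities")
    units = v[keep] / norms[keep, None]
    return float(np.linalg.norm(units.mean(axis=0)))


def random_polarization_baseline(
    n: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Empirical Phi distribution for ``draws`` sets of n uniform random unit vectors.

    For large n the mean tends to sqrt(8 / (3 pi n)) (three-dimensional
    random-walk result), e.g. ~0.184 for n = 25.
    """
    if n < 1 or draws < 1:
        raise ValueError("n and draws must be >= 1")
    vecs = rng.normal(size=(draws, n, 3))
    vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
    return np.linalg.norm(vecs.mean(axis=1), axis=1)


def nn_distance(
    positions: np.ndarray, periodic: bool = False, box: float | None = None
) -> float:
    """Mean over individuals of the distance to their nearest neighbour.

    With ``periodic=True`` distances use the minimum-image convention in
    a cubic box of edge ``box``.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError(f"nearest-neighbour distance needs >= 2 individuals, got {n}")
    delta = pos[:, None, :] - pos[None, :, :]
    if periodic:
        if box is None or box <= 0:
            raise ValueError("periodic distances need a positive box length")
        delta -= box * np.round(delta / box)
    d2 = np.einsum("ijk,ijk->ij", delta, delta)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min(axis=1)).mean())


def persistence_stats(
    tau: float, mean_speed: float, l_nn: float
) -> tuple[float, float]:
    """Persistence length l_p = tau * mean_speed and reduced l_p / l_nn."""
    if tau <= 0 or mean_speed <= 0 or l_nn <= 0:
        raise ValueError("tau, mean_speed and l_nn must all be positive")
    l_p = tau * mean_speed
    return l_p, l_p / l_nn


def _window_orientation_series(
    frames: Sequence[GroupFrame], fps: float
) -> list[OrientationSeries]:
    """Per-individual heading series from the velocity rows of group frames."""
    n_agents = frames[0].velocities.shape[0]
    vel = np.stack([f.velocities for f in frames])  # (T, N, 3)
    speeds = np.linalg.norm(vel, axis=2)
    idx = np.arange(len(frames))
    series = []
    for i in range(n_agents):
        valid = speeds[:, i] > 0
        headings = np.zeros((len(frames), 3))
        np.divide(vel[:, i], speeds[:, i, None], out=headings, where=valid[:, None])
        series.append(
            OrientationSeries(
                individual_id=i,
                frame_rate=fps,
                frames=idx,
                headings=headings,
                valid=valid,
            )
        )
    return series


def windowed_summary(
    frames: Sequence[GroupFrame],
    fps: float,
    window: float = 120.0,
    max_lag: float | None = None,
    periodic: bool = False,
    box: float | None = None,
) -> pd.DataFrame:
    """Per-window group statistics over non-overlapping time windows.

    For each window (default 2 minutes): mean polarization, mean nearest-
    neighbour distance, pooled-ACF reorientation time tau, persistence
    length from the within-window mean speed, and the reduced persistence
    length l_p / l_nn.  Windows whose ACF cannot be fitted (no decay or
    too few pairs) report NaN for tau-derived columns.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    if fps <= 0 or window <= 0:
        raise ValueError("fps and window must be positive")
    per_window = int(round(window * fps))
    if per_window < 3:
        raise ValueError(
            f"window of {window} s at {fps} fps is {per_window} frame(s); need >= 3"
        )
    if max_lag is None:
        max_lag = window / 4.0
    rows = []
    for start in range(0, len(frames), per_window):
        chunk = frames[start : start + per_window]
        if len(chunk) < 3:
            continue
        phi = np.mean([polarization(f.velocities) for f in chunk])
        lnn = np.mean(
            [nn_distance(f.positions, periodic=periodic, box=box) for f in chunk]
        )
        speeds = np.concatenate(
            [np.linalg.norm(f.velocities, axis=1) for f in chunk]
        )
        mean_speed = float(speeds[speeds > 0].mean()) if np.any(speeds > 0) else np.nan
        tau = l_p = red = np.nan
        try:
            acf = orientation_acf(
                _window_orientation_series(chunk, fps), max_lag=max_lag
            )
            tau = fit_exponential_acf(acf).tau
            l_p, red = persistence_stats(tau, mean_speed, lnn)
        except (FlatACFError, InsufficientDataError, ValueError) as exc:
            warnings.warn(f"window starting at frame {start}: tau not fitted ({exc})")
        rows.append(
            {
                "window_start": chunk[0].time,
                "window_end": chunk[-1].time,
                "phi_mean": float(phi),
                "l_nn": float(lnn),
                "tau": tau,
                "l_p": l_p,
                "reduced_lp": red,
                "mean_speed": mean_speed,
                "n_frames": len(chunk),
            }
        )
    return pd.DataFrame(rows)
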
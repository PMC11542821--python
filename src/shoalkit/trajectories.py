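"""Kinematics, filtering and orientational autocorrelation of 3D trajectories.

Velocities are forward differences of positions over consecutive frames,
headings are the corresponding unit vectors, and the reorientation time
tau is obtained by fitting ``C(t) = A * exp(-t / tau)`` (A <= 1) to the
orientational autocorrelation function C(t) = <e(s) . e(s + t)>.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class InsufficientDataError(ValueError):
    """Raised when a trajectory or ACF has too few samples for the operation."""


class FlatACFError(RuntimeError):
    """Raised when the ACF does not decay, so no finite tau can be fitted."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 3D positions of one individual at a fixed frame rate.

    Frame indices must be strictly increasing; missing indices are gaps.
    Positions are in mm for experimental data (box units for simulation
    output); the frame rate converts frame lags to seconds.
    """

    individual_id: str | int
    frame_rate: float
    frames: np.ndarray  # (n,) int, strictly increasing
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        positions = np.asarray(self.positions, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if frames.ndim != 1 or positions.shape != (len(frames), 3):
            raise ValueError("frames must be (n,), positions (n, 3)")
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", frames.astype(int))
        object.__setattr__(self, "positions", positions)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class OrientationSeries:
    """Unit heading vectors per frame, with a validity mask.

    A heading is invalid where the displacement was zero, or where the
    next frame is missing (forward differences never bridge gaps).
    """

    individual_id: str | int
    frame_rate: float
    frames: np.ndarray  # (n,) int
    headings: np.ndarray  # (n, 3); rows meaningful only where valid
    valid: np.ndarray  # (n,) bool


@dataclass(frozen=True)
class Kinematics:
    """Forward-difference velocities aligned to the earlier frame of each pair."""

    frames: np.ndarray  # (n-1,) frame index of the earlier sample
    velocities: np.ndarray  # (n-1, 3) in units/s
    speeds: np.ndarray  # (n-1,)
    positions: np.ndarray  # (n-1, 3) position at the earlier frame
    valid: np.ndarray  # (n-1,) bool; False across gaps
    orientations: OrientationSeries


@dataclass(frozen=True)
class ACFResult:
    """Orientational autocorrelation values with per-lag pair counts."""

    lags: np.ndarray  # (k,) seconds, starting at 0
    values: np.ndarray  # (k,) C(t)
    counts: np.ndarray  # (k,) number of heading pairs per lag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "C": self.values, "n_pairs": self.counts}
        )


@dataclass(frozen=True)
class ExpFit:
    """Result of the constrained exponential fit C(t) = A exp(-t/tau)."""

    amplitude: float  # A in (0, 1]
    tau: float  # seconds
    fit_window: tuple[float, float]  # lag range (s) used
    residual: float  # RMS residual over the window


def kinematics(traj: Trajectory) -> Kinematics:
    """Forward-difference velocities, speeds and headings of a trajectory.

    ``v_k = (x_{k+1} - x_k) * frame_rate`` over consecutive frames only;
    pairs spanning a gap are masked.  The velocity and heading are
    assigned to the earlier frame.  Zero displacement masks the heading
    (the speed is still 0 and valid for filtering purposes).
    """
    if len(traj) < 2:
        raise InsufficientDataError(
            f"trajectory {traj.individual_id!r} has {len(traj)} sample(s); need >= 2"
        )
    consecutive = np.diff(traj.frames) == 1
    disp = np.diff(traj.positions, axis=0)
    velocities = disp * traj.frame_rate
    speeds = np.linalg.norm(velocities, axis=1)
    moving = speeds > 0
    headings = np.zeros_like(velocities)
    np.divide(velocities, speeds[:, None], out=headings, where=moving[:, None])
    orient = OrientationSeries(
        individual_id=traj.individual_id,
        frame_rate=traj.frame_rate,
        frames=traj.frames[:-1],
        headings=headings,
        valid=consecutive & moving,
    )
    return Kinematics(
        frames=traj.frames[:-1],
        velocities=velocities,
        speeds=speeds,
        positions=traj.positions[:-1],
        valid=consecutive,
        orientations=orient,
    )


def filter_kinematics(
    speeds: np.ndarray,
    positions: np.ndarray | None = None,
    min_speed: float | None = 50.0,
    z_range: tuple[float, float] | None = (50.0, 150.0),
) -> np.ndarray:
    """Validity mask excluding non-moving samples and samples outside a height band.

    A sample survives iff ``speed >= min_speed`` (the non-moving exclusion
    "speed < min_speed" keeps the boundary value) and its z coordinate is
    *strictly* inside ``z_range``.  Either filter may be disabled with None.
    """
    speeds = np.asarray(speeds, dtype=float)
    mask = np.ones(len(speeds), dtype=bool)
    if min_speed is not None:
        mask &= speeds >= min_speed
    if z_range is not None:
        z_min, z_max = z_range
        if z_min >= z_max:
            raise ValueError(f"invalid z_range {z_range}: lower bound must be below upper")
        if positions is None:
            raise ValueError("positions required when z_range is given")
        z = np.asarray(positions, dtype=float)[:, 2]
        mask &= (z > z_min) & (z < z_max)
    return mask


def _valid_runs(series: OrientationSeries, extra_mask: np.ndarray | None) -> list[np.ndarray]:
    """Split the headings into maximal runs of consecutive valid frames.

    ACF pairs are only formed inside a run, so they never bridge a gap or
    a masked sample.
    """
    valid = series.valid.copy()
    if extra_mask is not None:
        valid &= np.asarray(extra_mask, dtype=bool)
    runs: list[np.ndarray] = []
    start = None
    frames = series.frames
    for i in range(len(frames)):
        ok = valid[i] and (start is None or frames[i] == frames[i - 1] + 1)
        if valid[i] and start is None:
            start = i
        elif start is not None and not ok:
            runs.append(series.headings[start:i])
            start = i if valid[i] else None
    if start is not None:
        runs.append(series.headings[start:])
    return [r for r in runs if len(r) >= 1]


def orientation_acf(
    series: OrientationSeries | Sequence[OrientationSeries],
    max_lag: float,
    mask: np.ndarray | Sequence[np.ndarray] | None = None,
) -> ACFResult:
    """Orientational autocorrelation pooled over start times and individuals.

    ``C(t)`` is the mean of ``e(s) . e(s+t)`` over every valid pair at
    frame lag ``t * frame_rate``, pooled across all supplied series.
    Pairs that would span a missing or masked frame are excluded.
    """
    if isinstance(series, OrientationSeries):
        series = [series]
    if mask is not None and not isinstance(mask, (list, tuple)):
        mask = [mask]
    fps = series[0].frame_rate
    if any(s.frame_rate != fps for s in series):
        raise ValueError("all series must share one frame rate")
    max_lag_frames = int(round(max_lag * fps))
    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1, dtype=int)
    for k, s in enumerate(series):
        m = mask[k] if mask is not None else None
        for h in _valid_runs(s, m):
            n = len(h)
            top = min(max_lag_frames, n - 1)
            for lag in range(top + 1):
                dots = np.einsum("ij,ij->", h[: n - lag], h[lag:])
                sums[lag] += dots
                counts[lag] += n - lag
    if counts[0] == 0:
        raise InsufficientDataError("no valid heading pairs at any lag")
    computed = counts > 0
    lags = np.arange(max_lag_frames + 1)[computed] / fps
    values = sums[computed] / counts[computed]
    return ACFResult(lags=lags, values=values, counts=counts[computed])


def fit_exponential_acf(
    acf: ACFResult,
    fit_window: tuple[float, float] | None = None,
    flat_threshold: float = 0.95,
) -> ExpFit:
    """Constrained least-squares fit of ``A * exp(-t / tau)`` to the ACF.

    Constraints: 0 < A <= 1, tau > 0.  When no window is given, the fit
    runs from lag 0 to the first lag where C drops below ``exp(-2)`` (or
    the last lag, whichever comes first).  An ACF that never drops below
    ``flat_threshold`` over the window carries no decay information and
    raises :class:`FlatACFError` rather than returning an unbounded tau.
    """
    lags, values = acf.lags, acf.values
    if fit_window is None:
        below = np.nonzero(values < np.exp(-2))[0]
        hi = lags[below[0]] if len(below) else lags[-1]
        fit_window = (0.0, float(hi))
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi)
    if sel.sum() < 3:
        raise InsufficientDataError(
            f"fit window {fit_window} contains {int(sel.sum())} lag(s); need >= 3"
        )
    t, c = lags[sel], values[sel]
    if c.min() > flat_threshold:
        raise FlatACFError(
            "ACF does not decay over the fit window "
            f"(min C = {c.min():.4f} > {flat_threshold}); tau is unbounded"
        )
    decayed = np.nonzero(c < np.exp(-1))[0]
    tau0 = float(t[decayed[0]]) if len(decayed) else float(max(t[-1], t[1]))
    a0 = float(np.clip(c[0], 0.5, 1.0))
    popt, _ = curve_fit(
        lambda tt, a, tau: a * np.exp(-tt / tau),
        t,
        c,
        p0=(a0, max(tau0, 1e-6)),
        bounds=([1e-12, 1e-12], [1.0, np.inf]),
        maxfev=10000,
    )
    a_fit, tau_fit = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((c - a_fit * np.exp(-t / tau_fit)) ** 2)))
    return ExpFit(amplitude=a_fit, tau=tau_fit, fit_window=(float(lo), float(hi)), residual=resid)


def _safe_edges(data: np.ndarray, bins) -> np.ndarray:
    """Equal-width bin edges, padded when the data range is degenerate."""
    if not np.isscalar(bins):
        return np.asarray(bins, dtype=float)
    bins = int(bins)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):
        # unit-width padded range, shifted so the datum sits mid-bin
        c = 0.5 * (lo + hi)
        shift = 0.5 / bins if bins % 2 == 0 else 0.0
        return np.linspace(c - 0.5 - shift, c + 0.5 - shift, bins + 1)
    return np.linspace(lo, hi, bins + 1)


def distributions(
    trajs: Sequence[Trajectory],
    speed_bins: int | np.ndarray = 50,
    r_bins: int | np.ndarray = 30,
    z_bins: int | np.ndarray = 30,
    axis_center: tuple[float, float] = (0.0, 0.0),
):
    """Speed histogram and joint latitude-radius/height (R-Z) histogram.

    R = sqrt((x - cx)**2 + (y - cy)**2) about a user-supplied vertical
    tank axis.  Both histograms are normalised to probability (mass sums
    to 1); bin edges are returned alongside.  Speeds come from forward
    differences; the positional histogram uses every sample.
    """
    if not trajs:
        raise ValueError("no trajectories supplied")
    speeds_all, xyz_all = [], []
    for traj in trajs:
        xyz_all.append(traj.positions)
        if len(traj) >= 2:
            kin = kinematics(traj)
            speeds_all.append(kin.speeds[kin.valid])
    speeds = np.concatenate(speeds_all) if speeds_all else np.empty(0)
    xyz = np.concatenate(xyz_all)
    cx, cy = axis_center
    r = np.hypot(xyz[:, 0] - cx, xyz[:, 1] - cy)
    z = xyz[:, 2]
    speed_edges = _safe_edges(speeds if len(speeds) else np.array([0.0]), speed_bins)
    if len(speeds):
        speed_counts, _ = np.histogram(speeds, bins=speed_edges)
        speed_probs = speed_counts / speed_counts.sum()
    else:
        speed_probs = np.zeros(len(speed_edges) - 1)
    r_edges = _safe_edges(r, r_bins)
    z_edges = _safe_edges(z, z_bins)
    rz_counts, _, _ = np.histogram2d(r, z, bins=[r_edges, z_edges])
    rz_probs = rz_counts / rz_counts.sum()
    return {
        "speed_probs": speed_probs,
        "speed_edges": speed_edges,
        "rz_probs": rz_probs,
        "r_edges": r_edges,
        "z_edges": z_edges,
    }


def count_histogram_modes(probs: np.ndarray, min_prominence: float = 0.0) -> int:
    """Number of interior + boundary local maxima of a histogram.

    Used to check uni- vs bimodality of speed distributions; a bin is a
    mode if it exceeds both neighbours (boundary bins compare one-sided).
    """
    p = np.asarray(probs, dtype=float)
    if len(p) < 2:
        return int(len(p) > 0)
    modes = 0
    for i in range(len(p)):
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i < len(p) - 1 else -np.inf
        if p[i] > left + min_prominence and p[i] > right + min_prominence:
            modes += 1
    return modes
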
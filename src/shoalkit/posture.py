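"""Eigenshape analysis of single-fish silhouettes.

A swimming fish imaged from above appears as an elongated blob that
bends intermittently.  Each frame is segmented, translated and rotated
into a canonical w-by-w grid (principal axes along the image axes), and
flattened into a w**2 feature vector.  The eigenvectors of the
*uncentered* second-moment matrix ``C = X^T X`` of the stacked dataset
are the characteristic shape modes: the leading mode captures the mean
elongated body, and typically the mode of the second largest eigenvalue
encodes body bending (the *bending mode* b).  The *bending index* of a
frame is the projection ``x . b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure, transform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedShape",
    "PCABasis",
    "BendingSeries",
    "ShapeModePCA",
    "segment",
    "align_shape",
    "shape_modes",
    "bending_index",
    "bending_speed_profile",
]


class EmptyForegroundError(ValueError):
    """Raised when thresholding leaves no foreground pixels."""


@dataclass(frozen=True)
class AlignedShape:
    """A w-by-w silhouette in the canonical frame (centred, axis-aligned)."""

    pixels: np.ndarray  # (w, w) non-negative intensities

    @property
    def vector(self) -> np.ndarray:
        """Flattened length-w**2 view used for mode projection."""
        return self.pixels.ravel()


@dataclass(frozen=True)
class PCABasis:
    """Shape modes: eigenvalues (descending), orthonormal modes, bending mode id."""

    eigenvalues: np.ndarray  # (k,) non-increasing, >= 0
    modes: np.ndarray  # (k, w**2) orthonormal rows
    bending_mode_index: int

    @property
    def bending_mode(self) -> np.ndarray:
        return self.modes[self.bending_mode_index]


@dataclass(frozen=True)
class BendingSeries:
    """Per-frame bending indices of one individual, paired with speed."""

    individual_id: str | int
    frames: np.ndarray
    bending_index: np.ndarray
    speed: np.ndarray  # mm/s, aligned with frames

    def __post_init__(self) -> None:
        n = len(self.frames)
        if len(self.bending_index) != n or len(self.speed) != n:
            raise ValueError("frames, bending_index and speed must have equal length")


def segment(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: pixels >= threshold, reduced to the largest component.

    Pixels below the threshold are background; small bright speckles are
    removed by keeping only the largest 8-connected foreground component.
    """
    image = np.asarray(image, dtype=float)
    mask = image >= threshold
    if not mask.any():
        raise EmptyForegroundError(
            f"no pixels at or above threshold {threshold} (image max {image.max():.3g})"
        )
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    return labels == counts.argmax()


def _moments(image: np.ndarray):
    """Weighted centroid and central second moments (mu20, mu02, mu11).

    Row index is y, column index is x, matching image conventions.
    """
    total = image.sum()
    ys, xs = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    cy = (ys * image).sum() / total
    cx = (xs * image).sum() / total
    dy, dx = ys - cy, xs - cx
    mu20 = (dx * dx * image).sum() / total
    mu02 = (dy * dy * image).sum() / total
    mu11 = (dx * dy * image).sum() / total
    return (cy, cx), mu20, mu02, mu11


def align_shape(image: np.ndarray, w: int = 50) -> AlignedShape:
    """Translate and rotate a silhouette into the canonical w-by-w frame.

    The foreground centroid moves to the grid centre and the major
    principal axis of the intensity-weighted second-moment tensor is
    rotated onto the horizontal axis (bilinear interpolation).  The
    remaining 180-degree ambiguity is resolved by making the third
    central moment along the major axis non-negative; for isotropic
    shapes the orientation is an arbitrary but deterministic tie, which
    is logged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image or mask")
    if (image > 0).sum() < 2:
        raise ValueError("degenerate foreground: fewer than 2 nonzero pixels")
    (cy, cx), mu20, mu02, mu11 = _moments(image)
    aniso = np.hypot(mu20 - mu02, 2 * mu11)
    if aniso < 1e-9 * (mu20 + mu02):
        logger.info("isotropic shape: principal-axis rotation is an arbitrary tie")
        angle = 0.0
    else:
        # angle of the major axis w.r.t. the x axis
        angle = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    center = (w - 1) / 2.0
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    # output (x', y') -> input: rotate by +angle about the centroid
    mat = np.array(
        [
            [cos_a, -sin_a, cx - center * cos_a + center * sin_a],
            [sin_a, cos_a, cy - center * sin_a - center * cos_a],
            [0, 0, 1],
        ]
    )
    aligned = transform.warp(
        image,
        transform.AffineTransform(matrix=mat),
        output_shape=(w, w),
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    if aligned.sum() > 0:
        (_, acx), *_ = _moments(aligned)
        xs = np.arange(w) - acx
        mu30 = (aligned.sum(axis=0) * xs**3).sum()
        if mu30 < 0:
            aligned = aligned[::-1, ::-1]
    return AlignedShape(pixels=aligned)


def _orient_mode(mode: np.ndarray, w: int) -> np.ndarray:
    """Fix a mode's sign so an upward C-bend projects positively.

    Convention: the total weight of the mode in the upper half of the
    grid (smaller row indices are plotted on top) must be >= that in the
    lower half; if the halves tie, the overall sum must be >= 0.
    """
    grid = mode.reshape(w, w)
    half = w // 2
    diff = grid[:half].sum() - grid[w - half :].sum()
    if diff < 0 or (diff == 0 and mode.sum() < 0):
        return -mode
    return mode


class ShapeModePCA(TransformerMixin, BaseEstimator):
    """Eigenmodes of aligned-silhouette datasets, sklearn transformer style.

    Decomposes the stacked shape matrix ``X`` (m samples by w**2 pixels)
    through the eigenvectors of the uncentered second-moment matrix
    ``C = X^T X`` (default), in which case the first mode captures the
    mean body shape and the second typically the bending.  With
    ``centering=True`` the column means are removed first (ordinary PCA).

    Parameters
    ----------
    centering : bool, default False
        Subtract the column mean before the decomposition.
    bending_mode_index : int, default 1
        Which mode is treated as the bending mode b; override when the
        automatic choice (second largest eigenvalue) does not hold for a
        given dataset.
    n_modes : int or None
        Keep only the leading ``n_modes`` modes; None keeps all.

    Attributes
    ----------
    eigenvalues_ : ndarray of shape (k,)
        Eigenvalues of C, non-increasing and non-negative.
    modes_ : ndarray of shape (k, w**2)
        Orthonormal eigenvectors (rows), sign-fixed so a canonical
        upward C-bend has a positive bending index.
    bending_mode_ : ndarray of shape (w**2,)
        The mode used for bending indices.
    mean_ : ndarray
        Column means removed when ``centering=True`` (zeros otherwise).
    """

    def __init__(
        self,
        centering: bool = False,
        bending_mode_index: int = 1,
        n_modes: int | None = None,
    ) -> None:
        self.centering = centering
        self.bending_mode_index = bending_mode_index
        self.n_modes = n_modes

    def fit(self, X: np.ndarray, y=None) -> "ShapeModePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2D with at least 2 rows")
        w = int(round(np.sqrt(X.shape[1])))
        if w * w != X.shape[1]:
            raise ValueError("feature dimension must be a perfect square (w**2)")
        self.mean_ = X.mean(axis=0) if self.centering else np.zeros(X.shape[1])
        Xc = X - self.mean_
        if not np.any(Xc):
            raise ValueError("rank-0 shape matrix: no variation to decompose")
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        eigenvalues = s**2
        modes = vt
        if self.n_modes is not None:
            eigenvalues = eigenvalues[: self.n_modes]
            modes = modes[: self.n_modes]
        modes = np.array([_orient_mode(m, w) for m in modes])
        if self.bending_mode_index >= len(modes):
            raise ValueError(
                f"bending_mode_index {self.bending_mode_index} out of range "
                f"for {len(modes)} modes"
            )
        self.grid_size_ = w
        self.eigenvalues_ = eigenvalues
        self.modes_ = modes
        self.bending_mode_ = modes[self.bending_mode_index]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project shapes onto the fitted modes (mode coordinates per row)."""
        check_is_fitted(self, "modes_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.modes_.T

    def bending_indices(self, X: np.ndarray) -> np.ndarray:
        """Bending index x . b for each row of X."""
        check_is_fitted(self, "bending_mode_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.bending_mode_

    def to_basis(self) -> PCABasis:
        check_is_fitted(self, "modes_")
        return PCABasis(
            eigenvalues=self.eigenvalues_,
            modes=self.modes_,
            bending_mode_index=self.bending_mode_index,
        )


def shape_modes(
    X: np.ndarray, centering: bool = False, bending_mode_index: int = 1
) -> PCABasis:
    """Eigen-decomposition of the (uncentered) shape matrix; see ShapeModePCA."""
    return (
        ShapeModePCA(centering=centering, bending_mode_index=bending_mode_index)
        .fit(X)
        .to_basis()
    )


def bending_index(shape: AlignedShape | np.ndarray, b: np.ndarray) -> float:
    """Projection x . b of an aligned shape onto the bending mode."""
    x = shape.vector if isinstance(shape, AlignedShape) else np.asarray(shape).ravel()
    b = np.asarray(b).ravel()
    if x.shape != b.shape:
        raise ValueError(f"dimension mismatch: shape {x.shape} vs mode {b.shape}")
    return float(x @ b)


def bending_speed_profile(
    series: Sequence[BendingSeries], speed_bins: np.ndarray
) -> pd.DataFrame:
    """Mean bending index vs speed, averaged across individuals.

    Within each speed bin the per-individual mean bending index is
    computed first; the reported value is the mean of those means and the
    SE is their standard error across individuals (NaN with fewer than 2
    individuals contributing).  Empty bins are reported with NaN mean and
    ``n_individuals = 0``, never as zero.
    """
    if not series:
        raise ValueError("at least one individual required")
    speed_bins = np.asarray(speed_bins, dtype=float)
    rows = []
    for lo, hi in zip(speed_bins[:-1], speed_bins[1:]):
        per_ind = []
        for s in series:
            sel = (s.speed >= lo) & (s.speed < hi)
            if np.any(sel):
                per_ind.append(np.mean(s.bending_index[sel]))
        n = len(per_ind)
        mean = float(np.mean(per_ind)) if n else np.nan
        se = float(np.std(per_ind, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {"speed_lo": lo, "speed_hi": hi, "mean_index": mean, "se": se, "n_individuals": n}
        )
    return pd.DataFrame(rows)
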
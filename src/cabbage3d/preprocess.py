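"""Cleaning and standardization of raw plant clouds.

The pipeline mirrors how reconstructed rosette clouds are prepared for
morphometry: background points are removed by a color gate (foliage occupies a
narrow green hue band, platform and background do not), residual reconstruction
speckle is removed by a k-nearest-neighbor distance criterion, the cloud is
rotated into a canonical PCA frame that keeps the botanical vertical on Z,
scaled to a unit Chebyshev box so size-bearing traits become unit-free, and
optionally downsampled by farthest-point sampling (FPS) to a fixed point count.

All steps preserve the relative order of retained points and never fabricate
points; every function returns new objects and leaves its input untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (
    DegenerateGeometryError,
    MissingAttributeError,
    ValidationError,
)

__all__ = [
    "ColorFilterSpec",
    "AxisFrame",
    "color_filter",
    "statistical_denoise",
    "pca_align",
    "normalize",
    "fps_downsample",
]


@dataclass
class ColorFilterSpec:
    """Inclusive per-channel color gate, in RGB or HSV space.

    In HSV space, hue is in degrees [0, 360) and the hue interval may wrap
    around 0; saturation and value are in [0, 1].  The default keeps foliage
    greens (hue 60–180 deg) with at least a little saturation and brightness,
    rejecting glass-platform greys and dark background.
    """

    space: str = "hsv"
    channel_min: tuple = (60.0, 0.15, 0.10)
    channel_max: tuple = (180.0, 1.0, 1.0)

    def __post_init__(self):
        if self.space not in ("rgb", "hsv"):
            raise ValidationError(f"color space must be rgb or hsv, got {self.space!r}")
        lo = np.asarray(self.channel_min, dtype=float)
        hi = np.asarray(self.channel_max, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValidationError("channel_min/channel_max must have 3 entries")
        if self.space == "hsv":
            if not (0 <= lo[0] < 360 and 0 <= hi[0] < 360):
                raise ValidationError("hue bounds must lie in [0, 360)")
            if np.any(lo[1:] > hi[1:]):
                raise ValidationError("channel min > max")
            if np.any(lo[1:] < 0) or np.any(hi[1:] > 1):
                raise ValidationError("saturation/value bounds must lie in [0, 1]")
        else:
            if np.any(lo > hi):
                raise ValidationError("channel min > max")

    def mask(self, colors: np.ndarray) -> np.ndarray:
        """Boolean keep-mask for an (n, 3) RGB [0,1] array."""
        if self.space == "rgb":
            lo = np.asarray(self.channel_min)
            hi = np.asarray(self.channel_max)
            return np.all((colors >= lo) & (colors <= hi), axis=1)
        hsv = rgb_to_hsv(colors)
        hue = hsv[:, 0] * 360.0
        h_lo, s_lo, v_lo = self.channel_min
        h_hi, s_hi, v_hi = self.channel_max
        if h_lo <= h_hi:
            hue_ok = (hue >= h_lo) & (hue <= h_hi)
        else:  # wrap-around interval, e.g. [300, 60)
            hue_ok = (hue >= h_lo) | (hue <= h_hi)
        return (
            hue_ok
            & (hsv[:, 1] >= s_lo) & (hsv[:, 1] <= s_hi)
            & (hsv[:, 2] >= v_lo) & (hsv[:, 2] <= v_hi)
        )


@dataclass
class AxisFrame:
    """A similarity transform ``canonical = scale * rotation @ (raw - translation)``.

    Records how a cloud was mapped into its canonical frame so the transform
    can be replayed or inverted exactly.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (det +1)")
        if not self.scale > 0:
            raise ValidationError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * (coords - self.translation) @ self.rotation.T

    def compose(self, outer: "AxisFrame") -> "AxisFrame":
        """Frame equivalent to applying ``self`` then ``outer``."""
        R = outer.rotation @ self.rotation
        t = self.translation + (self.rotation.T @ outer.translation) / self.scale
        return AxisFrame(R, t, self.scale * outer.scale)


def color_filter(pc: PointCloud, spec: ColorFilterSpec | None = None) -> PointCloud:
    """Keep the points whose color passes ``spec``; order preserved.

    An empty result is legal (warns rather than raises): a mis-set gate on a
    real scan should be visible, not fatal, so the caller can retune.
    """
    if spec is None:
        spec = ColorFilterSpec()
    if not pc.has_colors:
        raise MissingAttributeError("color_filter requires a cloud with colors")
    keep = spec.mask(pc.colors)
    if not keep.any():
        warnings.warn("color filter removed every point", stacklevel=2)
        return _empty_like(pc)
    return pc.select(np.flatnonzero(keep))


def _empty_like(pc: PointCloud) -> PointCloud:
    # PointCloud requires n >= 1; an emptied cloud is returned as a bare
    # zero-row container bypassing validation, flagged by source suffix.
    out = PointCloud.__new__(PointCloud)
    out.coords = np.empty((0, 3))
    out.colors = np.empty((0, 3)) if pc.has_colors else None
    out.source = pc.source + "|color_filter(empty)"
    return out


def statistical_denoise(pc: PointCloud, k_neighbors: int = 8,
                        std_ratio: float = 2.0) -> PointCloud:
    """Remove statistical outliers by mean k-nearest-neighbor distance.

    A point is dropped when its mean distance to its ``k_neighbors`` nearest
    neighbors exceeds ``mean + std_ratio * std`` of that statistic over the
    cloud.  Order among retained points is preserved.
    """
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be positive")
    if std_ratio <= 0:
        raise ValidationError("std_ratio must be positive")
    if pc.n_points <= k_neighbors:
        raise ValidationError(
            f"need more than k_neighbors={k_neighbors} points, have {pc.n_points}")
    tree = cKDTree(pc.coords)
    dists, _ = tree.query(pc.coords, k=k_neighbors + 1)  # first hit is self
    mean_d = dists[:, 1:].mean(axis=1)
    cut = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= cut
    return pc.select(np.flatnonzero(keep))


def pca_align(pc: PointCloud) -> tuple[PointCloud, AxisFrame]:
    """Rotate the cloud into its principal-axis frame, keeping Z vertical.

    The principal axis most parallel to the input Z (largest ``|dot|`` with
    (0,0,1)) becomes canonical Z, signed so the third moment of z is positive
    (plants are top-heavy relative to their centroid in the canonical pose);
    the remaining two axes become X and Y in decreasing-variance order.  The
    centroid moves to the origin.
    """
    if pc.n_points < 3:
        raise DegenerateGeometryError("pca_align needs at least 3 points")
    centroid = pc.coords.mean(axis=0)
    centered = pc.coords - centroid
    cov = centered.T @ centered / (pc.n_points - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 1e-12 * max(evals[2], 1e-300):
        raise DegenerateGeometryError("points are (near-)collinear; no unique frame")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    z_align = np.abs(evecs[2, :])  # |dot| of each PC with world Z
    zi = int(np.argmax(z_align))
    rest = [i for i in range(3) if i != zi]  # already in decreasing variance order
    axes = np.column_stack([evecs[:, rest[0]], evecs[:, rest[1]], evecs[:, zi]])
    # fix Z sign by third moment of projected z
    z_proj = centered @ axes[:, 2]
    m3 = np.mean(z_proj ** 3)
    if m3 < 0:
        axes[:, 2] = -axes[:, 2]
    # right-handedness, then X sign fixed by third moment for determinism
    if np.linalg.det(axes) < 0:
        axes[:, 1] = -axes[:, 1]
    x_proj = centered @ axes[:, 0]
    if np.mean(x_proj ** 3) < 0:
        axes[:, 0] = -axes[:, 0]
        axes[:, 1] = -axes[:, 1]  # keep det +1
    R = axes.T  # canonical = R @ (raw - centroid)
    frame = AxisFrame(R, centroid, 1.0)
    return pc.with_coords(centered @ axes), frame


def normalize(pc: PointCloud) -> tuple[PointCloud, AxisFrame]:
    """Center at the centroid and scale so max |coordinate| (Chebyshev) is 1."""
    centroid = pc.coords.mean(axis=0)
    centered = pc.coords - centroid
    extent = np.abs(centered).max()
    if extent <= 0:
        raise DegenerateGeometryError("cloud has zero extent; cannot normalize")
    frame = AxisFrame(np.eye(3), centroid, 1.0 / extent)
    return pc.with_coords(centered / extent), frame


def fps_downsample(pc: PointCloud, n_out: int, seed: int = 0,
                   start: str = "random") -> PointCloud:
    """Farthest-point sampling down to ``n_out`` points.

    Starting from a seeded random point (or index 0 with ``start="first"``,
    or the point farthest from the centroid with ``start="farthest"``), the
    point with the greatest distance to the already-selected set is added
    repeatedly.  Distance ties break toward the lowest index.  Returns the
    input unchanged when ``n_out >= n``.
    """
    if n_out < 1:
        raise ValidationError("n_out must be positive")
    n = pc.n_points
    if n_out >= n:
        return pc
    coords = pc.coords
    if start == "first":
        first = 0
    elif start == "farthest":
        d0 = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        first = int(np.argmax(d0))
    elif start == "random":
        first = int(np.random.default_rng(seed).integers(n))
    else:
        raise ValidationError(f"unknown start mode {start!r}")
    selected = fps_indices(coords, n_out, first)
    return pc.select(np.sort(selected), source_suffix=f"|fps({n_out})")


def fps_indices(coords: np.ndarray, n_out: int, first: int) -> np.ndarray:
    """Greedy farthest-point selection order starting from index ``first``."""
    selected = np.empty(n_out, dtype=np.intp)
    selected[0] = first
    # min squared distance from every point to the selected set
    min_d2 = np.sum((coords - coords[first]) ** 2, axis=1)
    for i in range(1, n_out):
        nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected
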
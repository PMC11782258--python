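"""The in-memory point-cloud container used throughout the package.

A :class:`PointCloud` is an n-by-3 array of finite coordinates with optional
per-point RGB colors in [0, 1].  Coordinates are in an arbitrary length unit in
a right-handed frame; after preprocessing the convention is Z up and the cloud
centered/normalized, but the container itself makes no such assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    """A single-plant point cloud.

    Parameters
    ----------
    coords : (n, 3) float array
        Point coordinates; every entry must be finite and n >= 1.
    colors : (n, 3) float array, optional
        Per-point RGB in [0, 1].
    source : str
        Free-text provenance tag (file path, generator spec, ...).
    """

    coords: np.ndarray
    colors: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"coords must be (n, 3), got shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ValidationError("point cloud is empty (n must be >= 1)")
        if not np.isfinite(coords).all():
            bad = int(np.argwhere(~np.isfinite(coords).all(axis=1))[0, 0])
            raise ValidationError(f"non-finite coordinate at point index {bad}")
        self.coords = coords
        if self.colors is not None:
            colors = np.asarray(self.colors, dtype=np.float64)
            if colors.shape != coords.shape:
                raise ValidationError(
                    f"colors must match coords shape {coords.shape}, got {colors.shape}"
                )
            if not np.isfinite(colors).all() or colors.min() < 0 or colors.max() > 1:
                raise ValidationError("color channels must be finite and in [0, 1]")
            self.colors = colors

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, index: np.ndarray, source_suffix: str = "") -> "PointCloud":
        """Return the sub-cloud at ``index`` (order of ``index`` preserved)."""
        colors = self.colors[index] if self.has_colors else None
        return PointCloud(self.coords[index], colors, self.source + source_suffix)

    def with_coords(self, coords: np.ndarray, source_suffix: str = "") -> "PointCloud":
        """Return a copy carrying new coordinates and the same colors."""
        colors = None if self.colors is None else self.colors.copy()
        return PointCloud(coords, colors, self.source + source_suffix)

    def __len__(self) -> int:
        return self.n_points
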
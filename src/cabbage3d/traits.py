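"""The ten architecture traits of a rosette plant cloud.

All extractors assume a canonical cloud: Z vertical (PCA-corrected), centroid
at the origin, and coordinates scaled so the Chebyshev extent is 1.  Under
that convention the size-bearing descriptors (W, V, S, S1–S3, M) become
unit-free, which is what makes them comparable across plants of different
absolute size; the ratios (T, theta_bar, O) are scale-invariant regardless.

Descriptors
-----------
T
    Height-to-spread ratio: max Z extent over max horizontal (XY) diameter.
theta_bar
    Mean leaf inclination in degrees: the mean angular deviation of
    leaf-surface normals from vertical, estimated on the middle vertical
    third of the plant (the slab least contaminated by the stem base and the
    crown tip).
W
    Radial dimension difference: max minus min pairwise distance between the
    XY convex-hull vertices — a uniformity measure of the horizontal outline.
V, S
    Convex-hull volume and surface area.
S1, S2, S3
    Convex-hull areas of the XZ, YZ and XY projections.
O
    Head roundness: XY hull area over the area of the minimum enclosing
    circle; 1 for a circular outline.
M
    Symmetry: mean over axial slabs of the variance of point-to-main-axis
    distances; 0 for a perfect surface of revolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import DegenerateGeometryError, InsufficientPointsError, ValidationError
from .geometry import (
    calipers_diameter_width,
    convex_contour_2d,
    convex_hull_3d,
    hull_volume_surface,
    min_enclosing_circle,
    pairwise_extremes,
    polygon_area,
)
from .preprocess import statistical_denoise

__all__ = [
    "TraitVector",
    "TraitConfig",
    "TRAIT_NAMES",
    "height_spread_ratio",
    "mean_leaf_inclination",
    "radial_dimension_difference",
    "hull_volume_area",
    "projection_areas",
    "head_roundness",
    "symmetry",
    "compute_traits",
]

TRAIT_NAMES = ("T", "theta_bar", "W", "V", "S", "S1", "S2", "S3", "O", "M")


@dataclass
class TraitVector:
    """The ten scalar descriptors, in the fixed order of :data:`TRAIT_NAMES`."""

    T: float
    theta_bar: float
    W: float
    V: float
    S: float
    S1: float
    S2: float
    S3: float
    O: float
    M: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TRAIT_NAMES])

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_array(cls, values) -> "TraitVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(TRAIT_NAMES),):
            raise ValidationError(f"trait vector must have {len(TRAIT_NAMES)} entries")
        return cls(*values)


@dataclass
class TraitConfig:
    """Tunable settings of the trait extractors."""

    k_normals: int = 12       # neighbors for leaf-normal plane fits
    n_groups: int = 10        # axial slabs for the symmetry variance
    w_mode: str = "literal"   # "literal" (max-min pairwise) or "width" (calipers)
    denoise_slab: bool = True  # statistically denoise the inclination slab first


def height_spread_ratio(pc: PointCloud) -> float:
    """T = (max z - min z) / (max pairwise XY distance)."""
    coords = pc.coords
    if coords.shape[0] < 2:
        raise InsufficientPointsError("need at least 2 points")
    height = coords[:, 2].max() - coords[:, 2].min()
    spread = _max_xy_spread(coords)
    if spread <= 0:
        raise DegenerateGeometryError("zero horizontal spread (vertical line cloud)")
    return float(height / spread)


def _max_xy_spread(coords: np.ndarray) -> float:
    """Max pairwise distance in the XY projection, via hull vertices."""
    xy = coords[:, :2]
    uniq = np.unique(xy, axis=0)
    if uniq.shape[0] < 2:
        return 0.0
    if uniq.shape[0] == 2:
        return float(np.linalg.norm(uniq[0] - uniq[1]))
    try:
        contour = convex_contour_2d(uniq, "xy")
        pts = contour.points
    except DegenerateGeometryError:
        pts = uniq  # collinear projection: brute force over the points
    dmax, _ = pairwise_extremes(pts)
    return dmax


def mean_leaf_inclination(pc: PointCloud, k_normals: int = 12,
                          denoise_slab: bool = True) -> float:
    """Mean angle (degrees) between leaf-surface normals and vertical.

    The plant is divided into three equal vertical parts and the middle slab
    is analyzed: per point a unit normal is estimated by a total-least-squares
    plane fit over its ``k_normals`` nearest neighbors, the inclination is
    ``arccos(|n . z|)``, and the slab mean is returned.
    """
    coords = pc.coords
    z = coords[:, 2]
    h = z.max() - z.min()
    lo, hi = z.min() + h / 3.0, z.min() + 2.0 * h / 3.0
    mask = (z >= lo) & (z <= hi)
    if mask.sum() < k_normals + 2:
        raise InsufficientPointsError(
            f"middle slab has {int(mask.sum())} points; need > k_normals={k_normals}")
    slab = pc.select(np.flatnonzero(mask))
    if denoise_slab and slab.n_points > 8:
        slab = statistical_denoise(slab)
        if slab.n_points < k_normals + 2:
            raise InsufficientPointsError("middle slab too sparse after denoising")
    normals = _estimate_normals(slab.coords, k_normals)
    cosang = np.clip(np.abs(normals[:, 2]), 0.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    return float(theta.mean())


def _estimate_normals(coords: np.ndarray, k: int) -> np.ndarray:
    """Unit surface normals by local PCA plane fits over k nearest neighbors."""
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    nbrs = coords[idx]                       # (n, k+1, 3), includes self
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)            # ascending; normal = smallest eigval
    return vecs[:, :, 0]


def radial_dimension_difference(pc: PointCloud, mode: str = "literal") -> float:
    """W: spread of the XY hull's extents.

    ``literal`` mode is max minus min pairwise distance over hull vertices;
    ``width`` mode is rotating-calipers diameter minus width, which is robust
    to hull-vertex density (adjacent vertices dominate the literal minimum).
    """
    contour = convex_contour_2d(pc.coords[:, :2], "xy")
    if mode == "literal":
        dmax, dmin = pairwise_extremes(contour.points)
        return float(dmax - dmin)
    if mode == "width":
        dmax, wmin = calipers_diameter_width(contour)
        return float(dmax - wmin)
    raise ValidationError(f"unknown W mode {mode!r}")


def hull_volume_area(pc: PointCloud) -> tuple[float, float]:
    """(V, S): volume and surface area of the 3D convex hull."""
    hull = convex_hull_3d(pc.coords)
    return hull_volume_surface(hull)


def projection_areas(pc: PointCloud) -> tuple[float, float, float]:
    """(S1, S2, S3): convex-hull areas of the XZ, YZ and XY projections.

    A degenerate projection (edge-on view) yields area 0 with a warning
    rather than an error.
    """
    coords = pc.coords
    planes = {"xz": coords[:, [0, 2]], "yz": coords[:, [1, 2]], "xy": coords[:, [0, 1]]}
    areas = []
    for name, pts in planes.items():
        try:
            areas.append(polygon_area(convex_contour_2d(pts, name)))
        except DegenerateGeometryError:
            warnings.warn(f"{name} projection is degenerate; area set to 0",
                          stacklevel=2)
            areas.append(0.0)
    return tuple(areas)  # type: ignore[return-value]


def head_roundness(pc: PointCloud) -> float:
    """O = (XY hull area) / (minimum enclosing circle area), in (0, 1]."""
    xy = pc.coords[:, :2]
    contour = convex_contour_2d(xy, "xy")
    area = polygon_area(contour)
    if area <= 0:
        raise DegenerateGeometryError("degenerate XY outline")
    _, radius = min_enclosing_circle(contour.points)
    return float(area / (math.pi * radius ** 2))


def symmetry(pc: PointCloud, n_groups: int = 10) -> float:
    """M: mean over axial slabs of the variance of point-to-axis distances.

    The main axis L is the first principal axis through the centroid.  Points
    are split into ``n_groups`` equal-thickness slabs along L; per slab the
    population variance (1/S_k) of the distances d(p, L) is computed, and M
    is the mean over slabs holding at least 2 points (sparser slabs are
    skipped with a warning).
    """
    if n_groups < 1:
        raise ValidationError("n_groups must be positive")
    coords = pc.coords
    if coords.shape[0] < 2:
        raise InsufficientPointsError("need at least 2 points")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]  # first principal axis
    t = centered @ axis
    radial = np.linalg.norm(centered - np.outer(t, axis), axis=1)
    edges = np.linspace(t.min(), t.max(), n_groups + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the top point
    which = np.digitize(t, edges) - 1
    variances = []
    skipped = 0
    for k in range(n_groups):
        d = radial[which == k]
        if d.size < 2:
            skipped += 1
            continue
        variances.append(float(np.mean((d - d.mean()) ** 2)))
    if not variances:
        raise InsufficientPointsError("no axial slab holds at least 2 points")
    if skipped:
        warnings.warn(f"{skipped} of {n_groups} axial slabs too sparse; skipped",
                      stacklevel=2)
    return float(np.mean(variances))


def compute_traits(pc: PointCloud, cfg: TraitConfig | None = None) -> TraitVector:
    """Run all ten extractors on a canonical (aligned + normalized) cloud.

    Extractor errors propagate annotated with the trait name.
    """
    cfg = cfg or TraitConfig()
    values = {}
    extractors = {
        "T": lambda: height_spread_ratio(pc),
        "theta_bar": lambda: mean_leaf_inclination(pc, cfg.k_normals, cfg.denoise_slab),
        "W": lambda: radial_dimension_difference(pc, cfg.w_mode),
        "V_S": lambda: hull_volume_area(pc),
        "S123": lambda: projection_areas(pc),
        "O": lambda: head_roundness(pc),
        "M": lambda: symmetry(pc, cfg.n_groups),
    }
    for key, fn in extractors.items():
        try:
            values[key] = fn()
        except Exception as exc:
            raise type(exc)(f"trait {key}: {exc}") from exc
    V, S = values["V_S"]
    S1, S2, S3 = values["S123"]
    return TraitVector(T=values["T"], theta_bar=values["theta_bar"], W=values["W"],
                       V=V, S=S, S1=S1, S2=S2, S3=S3, O=values["O"], M=values["M"])
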
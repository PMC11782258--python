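"""Synthetic labeled rosette clouds for the four plant architectures.

No public single-plant scan collection exists for heading Chinese cabbage, so
every downstream stage (trait extraction, type discovery, classification) is
exercised on generated clouds.  A plant is modeled as ``n_leaves`` arc-bent
leaf patches arranged around a vertical axis: each leaf's midrib is a circular
arc that starts vertical at the base and bends outward by a total angle set by
the leaf inclination, the blade extends azimuthally with a mid-leaf maximum
width and curls at the edges, and the whole plant is squeezed anisotropically
in Y, rescaled in Z to hit a target height-to-spread ratio, jittered with
Gaussian sensor-like noise and colored in a green hue band.

The four presets are engineered for *trait-ordinal* fidelity, not
photorealism: on canonical (aligned + normalized) clouds the highly-lean type
has the largest height-to-spread ratio T, the tight type the smallest hull
volume/surface and projection areas, the round-spread type the largest XY
footprint and roundness, and the full type the smallest T.  Two structural
devices make the tight type's margins robust: its head is thin relative to
the spread set by three short basal "wrapper" leaves (so the XY hull is a
small triangle rather than a filled disc), and its mass sits low (so the
Chebyshev normalization, which is centroid-referenced, shrinks it further).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .cloud import PointCloud
from .errors import ValidationError
from .plant_typing import TypeLabel

__all__ = [
    "ArchetypeSpec",
    "AugmentSpec",
    "ARCHETYPES",
    "generate_cabbage",
    "augment",
    "make_dataset",
    "Dataset",
]


@dataclass
class ArchetypeSpec:
    """Generator parameters for one plant architecture.

    ``height_spread_target`` is the height-to-spread ratio the cloud is
    rescaled to; ``leaf_inclination_deg`` is the intended mean leaf-surface
    inclination from vertical (the midrib arc bends by ``2*(90 - incl)``
    degrees in total); ``spread_anisotropy`` >= 1 squeezes Y relative to X;
    ``heading_tightness`` in [0, 1] is the fraction of leaves wrapped short
    and upright around the axis; ``n_spreaders`` adds short basal wrapper
    leaves that set the horizontal spread without filling the footprint;
    ``mass_bias`` > 1 concentrates points toward the plant base.
    """

    type_label: TypeLabel
    n_leaves: int = 12
    height_spread_target: float = 1.0
    leaf_inclination_deg: float = 60.0
    spread_anisotropy: float = 1.15
    heading_tightness: float = 0.5
    jitter_sd: float = 0.007
    color_hue_range: tuple = (90.0, 140.0)
    n_spreaders: int = 0
    spreader_reach: float = 1.0   # spreader tip radius relative to body reach
    mass_bias: float = 1.0
    leaf_width: float = 0.45      # max blade half-width relative to leaf length
    length_jitter: float = 0.12   # per-leaf relative length variation
    asymmetry: float = 0.0        # azimuthal length gradient (drives M)
    cup: float = 0.25             # edge curl relative to blade width

    def __post_init__(self):
        if self.n_leaves < 1 or self.height_spread_target <= 0:
            raise ValidationError("n_leaves and height_spread_target must be positive")
        if not 0 <= self.heading_tightness <= 1:
            raise ValidationError("heading_tightness must be in [0, 1]")
        if self.spread_anisotropy < 1:
            raise ValidationError("spread_anisotropy must be >= 1")
        if not 0 < self.leaf_inclination_deg < 90:
            raise ValidationError("leaf_inclination_deg must be in (0, 90)")
        if self.jitter_sd < 0 or self.mass_bias <= 0:
            raise ValidationError("jitter_sd must be >= 0 and mass_bias > 0")


@dataclass
class AugmentSpec:
    """Test-set style augmentation: Z-rotation, uniform scale, additive noise."""

    rotation_deg: tuple = (0.0, 360.0)
    scale_range: tuple = (0.9, 1.1)
    noise_sd: float = 0.005   # relative to the cloud's Z extent

    def __post_init__(self):
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValidationError("scale_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


ARCHETYPES: dict[TypeLabel, ArchetypeSpec] = {
    TypeLabel.FULL: ArchetypeSpec(
        TypeLabel.FULL, n_leaves=14, height_spread_target=0.48,
        leaf_inclination_deg=52.0, spread_anisotropy=1.5,
        heading_tightness=0.5, mass_bias=1.0, length_jitter=0.16),
    TypeLabel.HIGHLY_LEAN: ArchetypeSpec(
        TypeLabel.HIGHLY_LEAN, n_leaves=12, height_spread_target=1.6,
        leaf_inclination_deg=52.0, spread_anisotropy=1.35,
        heading_tightness=0.3, leaf_width=1.0, mass_bias=0.9,
        length_jitter=0.16, asymmetry=0.25),
    TypeLabel.TIGHT: ArchetypeSpec(
        TypeLabel.TIGHT, n_leaves=10, height_spread_target=1.30,
        leaf_inclination_deg=87.0, spread_anisotropy=1.45,
        heading_tightness=0.95, n_spreaders=3, spreader_reach=4.0,
        mass_bias=3.2, leaf_width=0.5),
    TypeLabel.ROUND_SPREAD: ArchetypeSpec(
        TypeLabel.ROUND_SPREAD, n_leaves=26, height_spread_target=0.75,
        leaf_inclination_deg=37.0, spread_anisotropy=1.0,
        heading_tightness=0.3, mass_bias=1.1, length_jitter=0.02),
}


def generate_cabbage(spec: ArchetypeSpec, n_points: int = 2000,
                     seed: int = 0) -> PointCloud:
    """Sample a single-plant rosette cloud; deterministic per (spec, n_points, seed)."""
    if n_points < 1000:
        raise ValidationError("n_points must be >= 1000")
    rng = np.random.default_rng(seed)
    n_body = spec.n_leaves
    n_spread = spec.n_spreaders
    n_total_leaves = n_body + n_spread

    # per-leaf geometry ------------------------------------------------------
    azim = 2 * math.pi * np.arange(n_total_leaves) / max(n_body, 1)
    azim = azim + rng.normal(0, 0.35 / n_total_leaves, n_total_leaves)
    if n_spread:
        azim[n_body:] = (2 * math.pi * np.arange(n_spread) / n_spread
                         + rng.uniform(0, 2 * math.pi / n_spread))
    inner = rng.random(n_total_leaves) < spec.heading_tightness
    inner[n_body:] = False
    bend_full = math.radians(2.0 * (90.0 - spec.leaf_inclination_deg))
    length = rng.uniform(1 - spec.length_jitter, 1 + spec.length_jitter,
                         n_total_leaves)
    if spec.asymmetry:
        azim0 = rng.uniform(0, 2 * math.pi)
        length = length * (1.0 + spec.asymmetry * np.cos(azim - azim0))
    bend = np.full(n_total_leaves, bend_full)
    # inner (heading) leaves: shorter and more upright
    length[inner] *= 0.65
    bend[inner] *= 0.55
    if n_spread:
        # basal wrapper leaves: strongly bent, short, so the tips set the
        # spread while adding little bulk
        body_reach = (1.0 / max(bend_full, 0.35)) * (1 - math.cos(max(bend_full, 0.35)))
        bend[n_body:] = math.radians(95.0)
        reach_target = spec.spreader_reach * max(body_reach, 0.12)
        arc = (1 - math.cos(math.radians(95.0))) / math.radians(95.0)
        length[n_body:] = reach_target / arc

    # per-point sampling -----------------------------------------------------
    leaf = rng.integers(0, n_total_leaves, n_points)
    if n_spread:
        # spreaders are sparse: reassign most of their points to body leaves
        sp_mask = leaf >= n_body
        keep = rng.random(n_points) < 0.06
        leaf[sp_mask & ~keep] = rng.integers(0, n_body, int((sp_mask & ~keep).sum()))
    u = rng.random(n_points) ** spec.mass_bias
    v = rng.uniform(-1.0, 1.0, n_points)

    L = length[leaf]
    c = np.maximum(bend[leaf], 1e-3)
    rho = (L / c) * (1.0 - np.cos(c * u))
    zet = (L / c) * np.sin(c * u)
    width = spec.leaf_width * L * np.sin(math.pi * np.clip(u, 0.0, 1.0))
    phi = azim[leaf] + v * width / np.maximum(rho, 0.18 * L)
    # edge curl: lift the blade edges along the local surface normal
    beta = c * u
    lift = spec.cup * width * v ** 2
    r_out = rho + lift * np.cos(beta) * np.sign(np.cos(beta))
    z_out = zet + lift * np.sin(beta)
    x = r_out * np.cos(phi)
    y = r_out * np.sin(phi) / spec.spread_anisotropy
    coords = np.column_stack([x, y, z_out])

    # canonicalize into the PCA frame first: a rosette's covariance is never
    # perfectly axis-aligned (uneven leaf placement tilts the principal
    # frame), and rescaling Z before diagonalizing would let the downstream
    # PCA correction re-tilt the plant and drift T off target
    from .preprocess import pca_align
    aligned, _ = pca_align(PointCloud(coords))
    coords = aligned.coords

    # rescale Z to meet the height-to-spread target --------------------------
    spread = _xy_diameter(coords)
    height = coords[:, 2].max() - coords[:, 2].min()
    if spread > 0 and height > 0:
        coords[:, 2] *= spec.height_spread_target * spread / height
    # sensor-like jitter
    if spec.jitter_sd > 0:
        coords += rng.normal(0.0, spec.jitter_sd * spread, coords.shape)

    hue = rng.uniform(*spec.color_hue_range, n_points) / 360.0
    sat = rng.uniform(0.35, 0.85, n_points)
    val = rng.uniform(0.25, 0.85, n_points)
    colors = hsv_to_rgb(np.column_stack([hue, sat, val]))
    return PointCloud(coords, colors,
                      source=f"synthetic:{spec.type_label.value}:seed={seed}")


def _xy_diameter(coords: np.ndarray) -> float:
    from .geometry import convex_contour_2d, pairwise_extremes
    from .errors import DegenerateGeometryError
    try:
        contour = convex_contour_2d(coords[:, :2])
        dmax, _ = pairwise_extremes(contour.points)
    except DegenerateGeometryError:
        dmax, _ = 0.0, 0.0
    return dmax


def augment(pc: PointCloud, spec: AugmentSpec | None = None,
            seed: int = 0) -> PointCloud:
    """Seeded random Z-rotation, uniform scale and Gaussian coordinate noise."""
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    angle = math.radians(rng.uniform(*spec.rotation_deg))
    scale = rng.uniform(*spec.scale_range)
    ca, sa = math.cos(angle), math.sin(angle)
    R = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    coords = scale * pc.coords @ R.T
    if spec.noise_sd > 0:
        z_extent = coords[:, 2].max() - coords[:, 2].min()
        coords = coords + rng.normal(0.0, spec.noise_sd * max(z_extent, 1e-12),
                                     coords.shape)
    return pc.with_coords(coords, source_suffix=f"|augment(seed={seed})")


@dataclass
class Dataset:
    """A labeled collection of generated clouds with its manifest."""

    clouds: list
    labels: list            # TypeLabel per cloud
    seeds: list = field(default_factory=list)
    augmented: list = field(default_factory=list)  # bool per cloud

    def __len__(self) -> int:
        return len(self.clouds)

    def manifest(self):
        import pandas as pd
        return pd.DataFrame({
            "index": range(len(self.clouds)),
            "type_label": [lab.value for lab in self.labels],
            "seed": self.seeds,
            "augmented": self.augmented,
            "n_points": [pc.n_points for pc in self.clouds],
        })

    def stratified_split(self, test_fraction: float = 0.2, seed: int = 0):
        """Index split preserving class ratios exactly when divisible."""
        rng = np.random.default_rng(seed)
        labels = np.array([lab.value for lab in self.labels])
        train_idx, test_idx = [], []
        for lab in sorted(set(labels)):
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            n_test = int(round(test_fraction * idx.size))
            test_idx.extend(idx[:n_test])
            train_idx.extend(idx[n_test:])
        return np.sort(train_idx), np.sort(test_idx)


def perturb_spec(spec: ArchetypeSpec, rng: np.random.Generator,
                 rel: float = 0.10) -> ArchetypeSpec:
    """Draw a within-class variant of ``spec`` (+-``rel`` uniform per field)."""
    def j(x, lo=None, hi=None):
        y = x * rng.uniform(1 - rel, 1 + rel)
        if lo is not None:
            y = max(lo, y)
        if hi is not None:
            y = min(hi, y)
        return y

    return replace(
        spec,
        height_spread_target=j(spec.height_spread_target),
        leaf_inclination_deg=j(spec.leaf_inclination_deg, 5.0, 89.0),
        spread_anisotropy=j(spec.spread_anisotropy, 1.0),
        heading_tightness=j(spec.heading_tightness, 0.0, 1.0),
        leaf_width=j(spec.leaf_width, 0.1),
        mass_bias=j(spec.mass_bias, 0.2),
    )


def make_dataset(n_per_class: int, n_points: int = 2000, seed: int = 0,
                 balance_to: int | None = None,
                 archetypes: dict[TypeLabel, ArchetypeSpec] | None = None,
                 augment_spec: AugmentSpec | None = None) -> Dataset:
    """Generate ``n_per_class`` clouds per archetype, optionally balanced up.

    Each sample uses a perturbed copy of its archetype spec so classes carry
    within-class variance.  When ``balance_to`` exceeds ``n_per_class``, each
    class is topped up with augmented copies of its own members, mirroring
    test-set balancing by rotation/scaling/noise.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if balance_to is not None and balance_to < n_per_class:
        raise ValidationError("balance_to must be >= n_per_class")
    archetypes = archetypes or ARCHETYPES
    master = np.random.default_rng(seed)
    ds = Dataset([], [], [], [])
    for lab in (TypeLabel.FULL, TypeLabel.HIGHLY_LEAN,
                TypeLabel.TIGHT, TypeLabel.ROUND_SPREAD):
        if lab not in archetypes:
            continue
        base = archetypes[lab]
        per_class_rng = np.random.default_rng(master.integers(2 ** 31))
        members = []
        for i in range(n_per_class):
            sub_seed = int(per_class_rng.integers(2 ** 31))
            spec_i = perturb_spec(base, per_class_rng)
            pc = generate_cabbage(spec_i, n_points, sub_seed)
            members.append(len(ds.clouds))
            ds.clouds.append(pc)
            ds.labels.append(lab)
            ds.seeds.append(sub_seed)
            ds.augmented.append(False)
        if balance_to is not None:
            for i in range(balance_to - n_per_class):
                src = members[i % len(members)]
                sub_seed = int(per_class_rng.integers(2 ** 31))
                ds.clouds.append(augment(ds.clouds[src], augment_spec, sub_seed))
                ds.labels.append(lab)
                ds.seeds.append(sub_seed)
                ds.augmented.append(True)
    return ds
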
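"""Stimulus manipulations and training-time augmentation.

Three perturbation families probe what a recognizer relies on:

* **density / inversion** — random subsets of the points (20%…100%) and a
  180° rotation about the horizontal axis (upside-down presentation);
* **voxel "Lego" deformation** — the cloud is replaced by points sampled on
  the exposed surface of its occupied-voxel grid, destroying local
  curvature while preserving the global shape envelope;
* **part scrambling** — labeled parts are re-positioned (anchor at the
  origin, others offset uniformly from a cube of half-side r), destroying
  the global configuration while preserving each part's local geometry.

All transforms are deterministic given their seed, and everything operates
in the unit-sphere frame (centroid at the origin, farthest point at norm 1).
The vertical axis is y throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PointCloud, StimulusRecord

__all__ = [
    "normalize_unit_sphere", "downsample_density", "invert",
    "VoxelGrid", "voxelize_lego",
    "ScrambleConfig", "subdivide_large_parts", "scramble_parts",
    "AugmentConfig", "augment_train", "augment_batch",
    "EXP1_DENSITIES", "EXP2_VOXEL_SIZES",
]

#: the printed density proportions of the first experiment
EXP1_DENSITIES = (0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0)
#: the voxel-size grid of the second experiment, including the undeformed case
EXP2_VOXEL_SIZES = (0.0, 0.01, 0.05, 0.1, 0.2)


def normalize_unit_sphere(pc: PointCloud) -> PointCloud:
    """Center at the centroid and scale so the farthest point has norm 1.

    Degenerate clouds (a single point, or all points coincident) are
    centered but left unscaled.
    """
    if len(pc) == 0:
        raise ValueError("cannot normalize an empty cloud")
    coords = pc.coords - pc.coords.mean(axis=0)
    radius = np.linalg.norm(coords, axis=1).max()
    if radius > 0.0:
        coords = coords / radius
    return PointCloud(coords, pc.part_labels, pc.category, pc.instance_id)


def downsample_density(pc: PointCloud, proportion: float, seed: int) -> PointCloud:
    """Keep a uniformly random subset of floor(proportion·N) points (min 1).

    ``proportion=1`` returns an identical copy. Part labels follow their
    points. The subset is drawn without replacement.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    if proportion == 1.0:
        return pc.copy()
    n = len(pc)
    size = max(1, int(np.floor(proportion * n)))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=size, replace=False))
    labels = None if pc.part_labels is None else pc.part_labels[keep]
    return PointCloud(pc.coords[keep], labels, pc.category, pc.instance_id)


def invert(pc: PointCloud) -> PointCloud:
    """Upside-down presentation: a proper 180° rotation about the x axis,
    (x, y, z) → (x, −y, −z). An involution and an isometry; chirality is
    preserved (this is a rotation, not a reflection)."""
    if len(pc) == 0:
        raise ValueError("cannot invert an empty cloud")
    coords = pc.coords * np.array([1.0, -1.0, -1.0])
    return PointCloud(coords, pc.part_labels, pc.category, pc.instance_id)


# -- Lego voxelization --------------------------------------------------------


@dataclass
class VoxelGrid:
    """Occupancy grid over a cloud: cubic cells of side ``voxel_size``,
    anchored at the cloud's bounding-box minimum corner."""

    voxel_size: float
    origin: np.ndarray
    occupied: set

    @classmethod
    def from_cloud(cls, pc: PointCloud, voxel_size: float) -> "VoxelGrid":
        if voxel_size <= 0.0:
            raise ValueError(f"voxel_size must be positive, got {voxel_size}")
        if len(pc) == 0:
            raise ValueError("cannot voxelize an empty cloud")
        origin = pc.coords.min(axis=0)
        idx = np.floor((pc.coords - origin) / voxel_size).astype(np.int64)
        cells = set(map(tuple, idx))
        return cls(voxel_size, origin, cells)

    def exposed_faces(self) -> list:
        """Faces of occupied cells not shared with another occupied cell.

        Each face is (cell, axis, direction) with direction ∈ {−1, +1}.
        Interior faces are invisible in a rendered stimulus, so only these
        exposed faces carry sample points.
        """
        faces = []
        for cell in sorted(self.occupied):
            for axis in range(3):
                for direction in (-1, 1):
                    nbr = list(cell)
                    nbr[axis] += direction
                    if tuple(nbr) not in self.occupied:
                        faces.append((cell, axis, direction))
        return faces


def voxelize_lego(pc: PointCloud, voxel_size: float, n_out: int | None = None,
                  seed: int = 0) -> PointCloud:
    """Replace a cloud by points sampled uniformly on the exposed surface of
    its occupied-voxel grid, then renormalize to the unit sphere.

    All faces have equal area (v²), so uniform sampling picks a face
    uniformly and a position uniformly within the square; each sampled point
    lies exactly on its face plane. ``n_out`` defaults to the input size.
    """
    grid = VoxelGrid.from_cloud(pc, voxel_size)
    faces = grid.exposed_faces()
    n_out = len(pc) if n_out is None else n_out
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    rng = np.random.default_rng(seed)
    which = rng.integers(0, len(faces), size=n_out)
    v = grid.voxel_size
    pts = np.empty((n_out, 3), dtype=np.float64)
    u = rng.random((n_out, 2))
    for row, fi in enumerate(which):
        cell, axis, direction = faces[fi]
        lo = grid.origin + np.asarray(cell, dtype=np.float64) * v
        p = np.empty(3)
        p[axis] = lo[axis] + (v if direction > 0 else 0.0)
        other = [a for a in range(3) if a != axis]
        p[other[0]] = lo[other[0]] + u[row, 0] * v
        p[other[1]] = lo[other[1]] + u[row, 1] * v
        pts[row] = p
    out = PointCloud(pts, None, pc.category, pc.instance_id)
    return normalize_unit_sphere(out)


# -- part scrambling ----------------------------------------------------------


@dataclass
class ScrambleConfig:
    """Parameters of the part-scrambling family: offsets drawn from the cube
    [−r, r]³, parts larger than ``subdivide_threshold`` of the cloud split
    into ``n_subclusters`` by spectral clustering on a k-nearest-neighbor
    affinity graph."""

    r: float = 0.6
    subdivide_threshold: float = 0.30
    n_subclusters: int = 3
    knn_affinity: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.r <= 0.0:
            raise ValueError("offset half-range r must be positive")
        if not 0.0 < self.subdivide_threshold < 1.0:
            raise ValueError("subdivide_threshold must be in (0, 1)")


def subdivide_large_parts(pc: PointCloud, config: ScrambleConfig) -> PointCloud:
    """Split every part occupying more than the threshold share of the cloud
    into ``n_subclusters`` spatially coherent pieces.

    Clustering is spectral, on a symmetrized k-nearest-neighbor
    connectivity graph of the part's points. Labels are re-indexed to be
    contiguous from 0 afterwards.
    """
    if pc.part_labels is None:
        raise ValueError("subdivision requires part labels")
    from sklearn.cluster import SpectralClustering

    n = len(pc)
    new_labels = np.empty(n, dtype=np.int64)
    next_id = 0
    for part in np.unique(pc.part_labels):
        mask = pc.part_labels == part
        share = mask.sum() / n
        if share <= config.subdivide_threshold:
            new_labels[mask] = next_id
            next_id += 1
            continue
        if mask.sum() < config.n_subclusters:
            raise ValueError(
                f"part {part} exceeds the {config.subdivide_threshold:.0%} threshold "
                f"but has only {mask.sum()} points (< {config.n_subclusters})")
        pts = pc.coords[mask]
        if len(pts) == config.n_subclusters:   # trivial partition
            new_labels[mask] = next_id + np.arange(len(pts))
            next_id += config.n_subclusters
            continue
        sc = SpectralClustering(
            n_clusters=config.n_subclusters,
            affinity="nearest_neighbors",
            n_neighbors=min(config.knn_affinity, len(pts) - 1),
            assign_labels="kmeans",
            random_state=config.seed)
        sub = sc.fit_predict(pts)
        new_labels[mask] = next_id + sub
        next_id += config.n_subclusters
    return PointCloud(pc.coords.copy(), new_labels, pc.category, pc.instance_id)


def scramble_parts(pc: PointCloud, config: ScrambleConfig,
                   _forced_offsets: np.ndarray | None = None) -> StimulusRecord:
    """Disrupt global configuration while preserving part geometry.

    One part (chosen uniformly) becomes the anchor: centered at the origin
    and left fixed. Every other part is centered on its own centroid and
    then offset by a vector with components ~ Uniform(−r, r). The result is
    renormalized to the unit sphere, so each part's internal distances are
    preserved up to the single global scale.
    """
    if pc.part_labels is None:
        raise ValueError("scrambling requires part labels")
    parts = np.unique(pc.part_labels)
    if len(parts) < 2:
        raise ValueError("scrambling needs at least two parts")
    rng = np.random.default_rng(config.seed)
    anchor = parts[rng.integers(0, len(parts))]
    coords = pc.coords.copy()
    offsets = {}
    for i, part in enumerate(parts):
        mask = pc.part_labels == part
        centroid = coords[mask].mean(axis=0)
        if part == anchor:
            offset = np.zeros(3)
        elif _forced_offsets is not None:
            offset = np.asarray(_forced_offsets[i], dtype=np.float64)
        else:
            offset = rng.uniform(-config.r, config.r, size=3)
        coords[mask] = coords[mask] - centroid + offset
        offsets[int(part)] = offset.tolist()
    out = normalize_unit_sphere(
        PointCloud(coords, pc.part_labels.copy(), pc.category, pc.instance_id))
    return StimulusRecord(
        cloud=out, base_instance=pc.instance_id, family="scramble",
        params={"r": config.r, "anchor_part": int(anchor), "offsets": offsets},
        seed=config.seed)


# -- training augmentation ----------------------------------------------------


@dataclass
class AugmentConfig:
    """Training augmentation: random point dropout (replaced by the first
    point's coordinates, ratio ~ U[0, 0.875]), then a global scale from
    [0.8, 1.25], then a per-axis shift from [−0.1, 0.1]."""

    dropout_range: tuple = (0.0, 0.875)
    scale_range: tuple = (0.8, 1.25)
    shift_range: tuple = (-0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_range[0] <= self.dropout_range[1] < 1.0:
            raise ValueError("dropout range must sit inside [0, 1)")


def augment_train(pc: PointCloud, config: AugmentConfig,
                  rng: np.random.Generator | None = None) -> PointCloud:
    """Apply dropout → scale → shift. The point count never changes:
    dropped points take the first point's coordinates (and are then scaled
    and shifted with everything else). Deterministic given the generator."""
    if len(pc) == 0:
        raise ValueError("cannot augment an empty cloud")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coords = pc.coords.copy()
    n = len(coords)
    ratio = rng.uniform(*config.dropout_range)
    n_drop = int(np.floor(ratio * n))
    if n_drop > 0:
        drop = rng.choice(n, size=n_drop, replace=False)
        coords[drop] = coords[0]
    scale = rng.uniform(*config.scale_range)
    shift = rng.uniform(config.shift_range[0], config.shift_range[1], size=3)
    coords = coords * scale + shift
    labels = None if pc.part_labels is None else pc.part_labels.copy()
    return PointCloud(coords, labels, pc.category, pc.instance_id)


def augment_batch(batch: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorized ``augment_train`` over a (B, N, 3) array (training loop)."""
    batch = np.array(batch, dtype=np.float64)
    b, n, _ = batch.shape
    for i in range(b):
        ratio = rng.uniform(*config.dropout_range)
        n_drop = int(np.floor(ratio * n))
        if n_drop > 0:
            drop = rng.choice(n, size=n_drop, replace=False)
            batch[i, drop] = batch[i, 0]
    scales = rng.uniform(*config.scale_range, size=(b, 1, 1))
    shifts = rng.uniform(config.shift_range[0], config.shift_range[1], size=(b, 1, 3))
    return batch * scales + shifts
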
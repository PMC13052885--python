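"""Procedural generation of labeled, part-annotated 3D point-cloud objects.

Each category is a parametric template assembled from five surface
primitives (box, cylinder, cone, sphere cap, torus segment), every primitive
assigned to a named part. Objects are sampled area-uniformly over the union
of primitive surfaces — the per-primitive point counts follow exact surface
areas — so the clouds have the statistics the experiments assume: 1,024
unit-sphere-normalized surface samples with per-point part labels, 3–12
parts per category, and within-category instance variation from a ±20%
jitter of every size parameter.

The roster covers the ten experiment categories (airplane, bottle, bowl,
chair, cup, lamp, person, piano, stool, table) plus a car template for the
part-scrambling pool (airplane, car, chair, lamp, table). The vertical axis
is y, so upside-down presentation is a rotation taking y → −y.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import io as pc_io
from .core import PointCloud
from .transforms import normalize_unit_sphere

__all__ = [
    "Primitive", "ShapeTemplate",
    "EXPERIMENT_CATEGORIES", "SCRAMBLE_CATEGORIES",
    "get_template", "all_templates", "templates_for",
    "generate_object", "generate_clouds", "generate_dataset",
    "SIZE_JITTER",
]

#: relative half-width of the uniform size jitter applied per instance
SIZE_JITTER = 0.2

EXPERIMENT_CATEGORIES = ("airplane", "bottle", "bowl", "chair", "cup",
                         "lamp", "person", "piano", "stool", "table")
SCRAMBLE_CATEGORIES = ("airplane", "car", "chair", "lamp", "table")

_KINDS = ("box", "cylinder", "cone", "sphere_cap", "torus_segment")


@dataclass(frozen=True)
class Primitive:
    """One surface primitive in a template's local frame.

    ``size`` is kind-specific; ``rotation`` is extrinsic xyz Euler angles in
    radians applied before ``position``. ``part`` names the part the
    primitive belongs to.
    """

    kind: str
    size: tuple                      # kind-specific positional size params
    position: tuple = (0.0, 0.0, 0.0)
    rotation: tuple = (0.0, 0.0, 0.0)
    part: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class ShapeTemplate:
    category_name: str
    primitives: tuple

    def __post_init__(self):
        parts = sorted({p.part for p in self.primitives})
        if parts != list(range(len(parts))):
            raise ValueError(f"{self.category_name}: part ids must be contiguous from 0")
        # experimental stimuli carry 3-12 parts (asserted for the shipped
        # roster in tests); ad-hoc templates may be simpler
        if not 1 <= len(parts) <= 12:
            raise ValueError(
                f"{self.category_name}: part count {len(parts)} outside [1, 12]")

    @property
    def part_count(self) -> int:
        return len({p.part for p in self.primitives})


# -- primitive surface areas and samplers -------------------------------------
# every sampler is exactly area-uniform on its surface


def _area(kind: str, s: tuple) -> float:
    if kind == "box":
        sx, sy, sz = s
        return 2.0 * (sx * sy + sx * sz + sy * sz)
    if kind == "cylinder":                    # radius, height (capped)
        r, h = s
        return 2.0 * np.pi * r * h + 2.0 * np.pi * r * r
    if kind == "cone":                        # base radius, height (with base)
        r, h = s
        return np.pi * r * np.hypot(r, h) + np.pi * r * r
    if kind == "sphere_cap":                  # radius, polar opening angle
        radius, angle = s
        return 2.0 * np.pi * radius * radius * (1.0 - np.cos(angle))
    if kind == "torus_segment":               # ring radius, tube radius, arc angle
        ring, tube, arc = s
        return arc * 2.0 * np.pi * ring * tube
    raise ValueError(kind)


def _sample(kind: str, s: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "box":
        sx, sy, sz = s
        half = np.array([sx, sy, sz]) / 2.0
        areas = np.array([sy * sz, sy * sz, sx * sz, sx * sz, sx * sy, sx * sy])
        face = rng.choice(6, size=n, p=areas / areas.sum())
        pts = rng.uniform(-1.0, 1.0, size=(n, 3)) * half
        axis = face // 2
        sign = np.where(face % 2 == 0, 1.0, -1.0)
        pts[np.arange(n), axis] = sign * half[axis]
        return pts
    if kind == "cylinder":
        r, h = s
        lateral = 2.0 * np.pi * r * h
        caps = 2.0 * np.pi * r * r
        on_side = rng.random(n) < lateral / (lateral + caps)
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        pts = np.empty((n, 3))
        y = rng.uniform(-h / 2.0, h / 2.0, n)
        rad = np.sqrt(rng.random(n)) * r
        top = rng.random(n) < 0.5
        pts[:, 0] = np.where(on_side, r, rad) * np.cos(theta)
        pts[:, 2] = np.where(on_side, r, rad) * np.sin(theta)
        pts[:, 1] = np.where(on_side, y, np.where(top, h / 2.0, -h / 2.0))
        return pts
    if kind == "cone":                        # base at −h/2, apex at +h/2
        r, h = s
        lateral = np.pi * r * np.hypot(r, h)
        base = np.pi * r * r
        on_side = rng.random(n) < lateral / (lateral + base)
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        frac = np.sqrt(rng.random(n))          # distance fraction from apex
        rad = np.where(on_side, frac * r, np.sqrt(rng.random(n)) * r)
        pts = np.empty((n, 3))
        pts[:, 0] = rad * np.cos(theta)
        pts[:, 2] = rad * np.sin(theta)
        pts[:, 1] = np.where(on_side, h / 2.0 - frac * h, -h / 2.0)
        return pts
    if kind == "sphere_cap":                  # cap around the +y pole
        radius, angle = s
        cos_t = rng.uniform(np.cos(angle), 1.0, n)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        return np.stack([radius * sin_t * np.cos(phi),
                         radius * cos_t,
                         radius * sin_t * np.sin(phi)], axis=1)
    if kind == "torus_segment":               # ring in the x–z plane
        ring, tube, arc = s
        phi = rng.uniform(0.0, arc, n)
        theta = np.empty(n)
        got = 0
        while got < n:                        # rejection-sample the tube angle
            cand = rng.uniform(0.0, 2.0 * np.pi, 2 * (n - got))
            accept = rng.random(len(cand)) < (ring + tube * np.cos(cand)) / (ring + tube)
            take = cand[accept][: n - got]
            theta[got:got + len(take)] = take
            got += len(take)
        rad = ring + tube * np.cos(theta)
        return np.stack([rad * np.cos(phi),
                         tube * np.sin(theta),
                         rad * np.sin(phi)], axis=1)
    raise ValueError(kind)


# -- the category roster ------------------------------------------------------


def _airplane() -> tuple:
    return (
        Primitive("cylinder", (0.25, 3.0), rotation=(np.pi / 2, 0, 0), part=0),
        Primitive("cone", (0.25, 0.6), position=(0, 0, 1.8),
                  rotation=(-np.pi / 2, 0, 0), part=0),
        Primitive("box", (3.6, 0.08, 0.8), position=(0, 0, 0.3), part=1),
        Primitive("box", (1.3, 0.06, 0.45), position=(0, 0.05, -1.35), part=2),
        Primitive("box", (0.08, 0.7, 0.45), position=(0, 0.35, -1.35), part=2),
        Primitive("cylinder", (0.12, 0.7), position=(0.9, -0.22, 0.4),
                  rotation=(np.pi / 2, 0, 0), part=3),
        Primitive("cylinder", (0.12, 0.7), position=(-0.9, -0.22, 0.4),
                  rotation=(np.pi / 2, 0, 0), part=3),
    )


def _bottle() -> tuple:
    return (
        Primitive("cylinder", (0.5, 1.6), position=(0, 0.8, 0), part=0),
        Primitive("cylinder", (0.16, 0.5), position=(0, 1.85, 0), part=1),
        Primitive("cylinder", (0.2, 0.18), position=(0, 2.19, 0), part=2),
    )


def _bowl() -> tuple:
    return (
        Primitive("sphere_cap", (0.9, 1.9), position=(0, 0.75, 0),
                  rotation=(np.pi, 0, 0), part=0),
        Primitive("torus_segment", (0.85, 0.06, 2 * np.pi),
                  position=(0, 0.78, 0), part=1),
        Primitive("cylinder", (0.3, 0.12), position=(0, 0.06, 0), part=2),
    )


def _chair() -> tuple:
    legs = [Primitive("cylinder", (0.05, 1.0), position=(sx * 0.42, 0.5, sz * 0.42),
                      part=2 + i)
            for i, (sx, sz) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)])]
    return (
        Primitive("box", (1.0, 0.1, 1.0), position=(0, 1.05, 0), part=0),
        Primitive("box", (1.0, 1.1, 0.08), position=(0, 1.65, -0.46), part=1),
        *legs,
    )


def _cup() -> tuple:
    return (
        Primitive("cylinder", (0.4, 0.9), position=(0, 0.45, 0), part=0),
        Primitive("torus_segment", (0.28, 0.06, np.pi),
                  position=(0.42, 0.45, 0), rotation=(np.pi / 2, 0, np.pi / 2), part=1),
        Primitive("cylinder", (0.42, 0.08), position=(0, 0.04, 0), part=2),
    )


def _lamp() -> tuple:
    return (
        Primitive("cylinder", (0.5, 0.1), position=(0, 0.05, 0), part=0),
        Primitive("cylinder", (0.05, 1.6), position=(0, 0.9, 0), part=1),
        Primitive("cone", (0.55, 0.55), position=(0, 1.95, 0), part=2),
        Primitive("sphere_cap", (0.16, np.pi), position=(0, 1.62, 0), part=3),
    )


def _person() -> tuple:
    return (
        Primitive("sphere_cap", (0.25, np.pi), position=(0, 1.78, 0), part=0),
        Primitive("box", (0.6, 0.8, 0.3), position=(0, 1.15, 0), part=1),
        Primitive("cylinder", (0.07, 0.68), position=(0.4, 1.1, 0),
                  rotation=(0, 0, 0.25), part=2),
        Primitive("cylinder", (0.07, 0.68), position=(-0.4, 1.1, 0),
                  rotation=(0, 0, -0.25), part=3),
        Primitive("cylinder", (0.09, 0.85), position=(0.16, 0.43, 0), part=4),
        Primitive("cylinder", (0.09, 0.85), position=(-0.16, 0.43, 0), part=5),
    )


def _piano() -> tuple:
    legs = [Primitive("cylinder", (0.06, 0.62), position=(sx * 0.8, 0.31, sz * 0.4),
                      part=2)
            for sx, sz in [(1, 1), (1, -1), (-1, 1), (-1, -1)]]
    return (
        Primitive("box", (1.8, 0.9, 1.0), position=(0, 1.07, 0), part=0),
        Primitive("box", (1.5, 0.08, 0.4), position=(0, 0.66, 0.65), part=1),
        *legs,
        Primitive("box", (0.5, 0.06, 0.18), position=(0, 0.12, 0.62), part=3),
    )


def _stool() -> tuple:
    legs = []
    for i in range(3):
        ang = 2 * np.pi * i / 3
        legs.append(Primitive("cylinder", (0.05, 0.92),
                              position=(0.32 * np.cos(ang), 0.46, 0.32 * np.sin(ang)),
                              rotation=(0.18 * np.sin(ang), 0, -0.18 * np.cos(ang)),
                              part=1 + i))
    return (Primitive("cylinder", (0.45, 0.1), position=(0, 0.95, 0), part=0), *legs)


def _table() -> tuple:
    legs = [Primitive("cylinder", (0.06, 0.92), position=(sx * 0.8, 0.46, sz * 0.46),
                      part=1 + i)
            for i, (sx, sz) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)])]
    return (Primitive("box", (1.9, 0.1, 1.1), position=(0, 0.97, 0), part=0), *legs)


def _car() -> tuple:
    wheels = [Primitive("torus_segment", (0.16, 0.08, 2 * np.pi),
                        position=(sx * 0.75, 0.22, sz * 0.55),
                        rotation=(np.pi / 2, 0, 0), part=2 + i)
              for i, (sx, sz) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)])]
    return (
        Primitive("box", (2.3, 0.5, 1.0), position=(0, 0.6, 0), part=0),
        Primitive("box", (1.2, 0.45, 0.92), position=(-0.1, 1.05, 0), part=1),
        *wheels,
    )


_BUILDERS = {
    "airplane": _airplane, "bottle": _bottle, "bowl": _bowl, "chair": _chair,
    "cup": _cup, "lamp": _lamp, "person": _person, "piano": _piano,
    "stool": _stool, "table": _table, "car": _car,
}


def get_template(category: str) -> ShapeTemplate:
    if category not in _BUILDERS:
        raise KeyError(f"no template for category {category!r}; "
                       f"available: {sorted(_BUILDERS)}")
    return ShapeTemplate(category, _BUILDERS[category]())


def all_templates() -> list:
    return [get_template(c) for c in sorted(_BUILDERS)]


def templates_for(categories) -> list:
    return [get_template(c) for c in categories]


# -- object and dataset generation --------------------------------------------


def _instance_rng(template: ShapeTemplate, instance_seed: int) -> np.random.Generator:
    tag = zlib.crc32(template.category_name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(instance_seed), tag])


def generate_object(template: ShapeTemplate, instance_seed: int,
                    n_points: int = 1024) -> PointCloud:
    """Sample one object instance: jitter each size parameter by ±20%,
    allocate points to primitives by exact surface area (largest-remainder
    rounding), sample each surface uniformly, label points by part, and
    normalize to the unit sphere. Deterministic given
    (template, instance_seed, n_points)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = _instance_rng(template, instance_seed)
    lo, hi = 1.0 - SIZE_JITTER, 1.0 + SIZE_JITTER
    layout_scale = rng.uniform(lo, hi)
    jittered = []
    for prim in template.primitives:
        size = tuple(float(s) * rng.uniform(lo, hi) for s in prim.size)
        # arc/opening angles are shape, not size: keep them un-jittered
        if prim.kind == "sphere_cap":
            size = (size[0], prim.size[1])
        elif prim.kind == "torus_segment":
            size = (size[0], size[1], prim.size[2])
        jittered.append((prim, size))
    areas = np.array([_area(p.kind, s) for p, s in jittered])
    total = areas.sum()
    if total <= 0.0:
        raise ValueError(f"template {template.category_name!r} has zero surface area")
    # largest-remainder allocation: exact n_points, proportions exact to ±1
    quota = areas / total * n_points
    counts = np.floor(quota).astype(np.int64)
    short = n_points - counts.sum()
    if short > 0:
        counts[np.argsort(-(quota - counts), kind="stable")[:short]] += 1
    pieces, labels = [], []
    for (prim, size), c in zip(jittered, counts):
        if c == 0:
            continue
        pts = _sample(prim.kind, size, int(c), rng)
        rot = Rotation.from_euler("xyz", prim.rotation)
        pts = pts @ rot.as_matrix().T + np.asarray(prim.position) * layout_scale
        pieces.append(pts)
        labels.append(np.full(int(c), prim.part, dtype=np.int64))
    coords = np.concatenate(pieces, axis=0)
    parts = np.concatenate(labels)
    order = rng.permutation(n_points)
    cloud = PointCloud(coords[order], parts[order], template.category_name,
                       f"{template.category_name}_{instance_seed}")
    return normalize_unit_sphere(cloud)


def generate_clouds(categories, n_per_cat: int, seed: int,
                    n_points: int = 1024, offset: int = 0) -> list:
    """In-memory convenience: ``n_per_cat`` instances of each category.

    ``offset`` shifts the instance-seed block, so disjoint splits are
    obtained by disjoint offsets.
    """
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    clouds = []
    for cat in categories:
        template = get_template(cat)
        for i in range(n_per_cat):
            clouds.append(generate_object(template, base + offset + i, n_points))
    return clouds


def generate_dataset(templates, n_train_per_cat: int, n_test_per_cat: int,
                     seed: int, n_points: int = 1024,
                     out_dir=None) -> pc_io.DatasetManifest:
    """Generate a labeled train/test dataset and its manifest.

    Train and test instances use disjoint instance-seed blocks. When
    ``out_dir`` is given, clouds are written as ASCII PLY (with the part
    property) plus ``.seg`` label files, and the manifest as JSON; the
    manifest (and all files) are byte-identical across runs with the same
    seed. The in-memory clouds are attached as ``manifest.clouds``.
    """
    if n_train_per_cat < 1 or n_test_per_cat < 1:
        raise ValueError("per-category counts must be >= 1")
    names = [t.category_name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate category names: {sorted(names)}")
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    records, clouds = [], []
    per_cat = n_train_per_cat + n_test_per_cat
    for template in templates:
        for i in range(per_cat):
            split = "train" if i < n_train_per_cat else "test"
            inst_seed = base + i
            cloud = generate_object(template, inst_seed, n_points)
            iid = f"{template.category_name}_{split}_{i:03d}"
            cloud.instance_id = iid
            rec = pc_io.ManifestRecord(
                instance_id=iid, category=template.category_name, split=split,
                cloud_path=f"{iid}.ply", label_path=f"{iid}.seg", seed=inst_seed)
            records.append(rec)
            clouds.append(cloud)
    manifest = pc_io.DatasetManifest(records, metadata={
        "seed": seed, "n_points": n_points, "size_jitter": SIZE_JITTER,
        "n_train_per_cat": n_train_per_cat, "n_test_per_cat": n_test_per_cat,
        "categories": sorted(names)})
    manifest.clouds = clouds
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, cloud in zip(records, clouds):
            pc_io.write_ply(cloud, out / rec.cloud_path)
            pc_io.write_seg_labels(cloud.part_labels, out / rec.label_path)
        pc_io.write_manifest(manifest, out / "manifest.json")
    return manifest
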
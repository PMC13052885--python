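"""Training loop and the three experiment runners.

Training follows the published recipe: Adam at 1e-3 with a step schedule
(×0.3 every 50 epochs), and per-epoch augmentation (random point dropout up
to 87.5% with first-point replacement, random scale in [0.8, 1.25], random
per-axis shift in [−0.1, 0.1]).

Experiment runners turn a trained classifier plus a stimulus design into a
flat predictions table; every row carries the provenance (condition
parameters and seed) needed to regenerate its stimulus exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .core import PointCloud, StimulusRecord
from .models import build_model, ModelSpec
from .transforms import (
    EXP1_DENSITIES,
    EXP2_VOXEL_SIZES,
    AugmentConfig,
    ScrambleConfig,
    augment_batch,
    downsample_density,
    invert,
    scramble_parts,
    subdivide_large_parts,
    voxelize_lego,
)

__all__ = [
    "TrainConfig", "desk_train_config", "learning_rate_at", "train",
    "predict_logits", "restrict_predict", "evaluate_accuracy",
    "ExperimentDesign", "exp1_design", "exp2_design",
    "exp2_participant_design", "generate_experiment_stimuli",
    "run_experiment", "filter_scrambles", "exp3_stimulus_set",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 200
    decay_factor: float = 0.3
    decay_every: int = 50
    batch_size: int = 16
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must be in (0, 1)")


def desk_train_config(**overrides) -> TrainConfig:
    """CPU-scale profile: same optimizer and augmentation, compressed
    schedule (25 epochs, decay every 10)."""
    cfg = TrainConfig(epochs=25, decay_every=10, batch_size=8)
    return replace(cfg, **overrides)


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr(e) = lr0 · factor^floor(e / interval)."""
    return config.learning_rate * config.decay_factor ** (epoch // config.decay_every)


def _as_arrays(clouds, categories):
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    coords = np.stack([pc.coords for pc in clouds]).astype(np.float32)
    labels = np.array([index[pc.category] for pc in clouds], dtype=np.int64)
    return coords, labels


def train(spec_or_model, clouds, config: TrainConfig, categories=None):
    """Train a classifier on labeled point clouds.

    ``categories`` (default: sorted unique categories of the clouds) fixes
    the class order; it is attached to the returned model as
    ``model.categories``. Returns (model, log) where the log has one entry
    per epoch with the learning rate, mean loss and training accuracy.
    """
    if not clouds:
        raise ValueError("empty training set")
    if categories is None:
        categories = sorted({pc.category for pc in clouds})
    model = (build_model(spec_or_model, seed=config.seed)
             if isinstance(spec_or_model, ModelSpec) else spec_or_model)
    coords, labels = _as_arrays(clouds, categories)
    n = len(coords)
    rng = np.random.default_rng(config.seed)
    model.rng_holder["rng"] = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    log = []
    model.train()
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(config, epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = augment_batch(coords[idx], config.augment, rng).astype(np.float32)
            logits = model(batch)
            loss = nn.cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        log.append({"epoch": epoch, "lr": opt.lr,
                    "loss": float(np.mean(losses)), "train_acc": correct / n})
    model.eval()
    model.categories = list(categories)
    return model, log


def predict_logits(model, pc) -> np.ndarray:
    """Class logits for a single cloud (eval mode)."""
    coords = pc.coords if isinstance(pc, PointCloud) else np.asarray(pc)
    model.eval()
    return model(coords.astype(np.float32)).data[0]


def restrict_predict(model, pc, category_subset) -> str:
    """Argmax over only the subset's logits (ties → lowest class index).

    Mirrors restricting a 40-way classifier to the ten categories shown to
    participants.
    """
    if not category_subset:
        raise ValueError("category subset must be non-empty")
    cats = getattr(model, "categories", None)
    if cats is None:
        raise ValueError("model has no category list; train() attaches one")
    try:
        sub_idx = sorted(cats.index(c) for c in category_subset)
    except ValueError as err:
        raise ValueError(f"unknown category in subset: {err}") from None
    logits = predict_logits(model, pc)
    return cats[sub_idx[int(np.argmax(logits[sub_idx]))]]


def evaluate_accuracy(model, clouds, category_subset) -> float:
    hits = sum(restrict_predict(model, pc, category_subset) == pc.category
               for pc in clouds)
    return hits / len(clouds)


# -- experiment designs -------------------------------------------------------


@dataclass
class ExperimentDesign:
    """A condition grid plus the category subset used for report-out."""

    experiment: str                  # "exp1" | "exp2" | "exp3"
    conditions: list                 # list of dicts of condition parameters
    categories: tuple
    seed: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("condition grid must be non-empty")


def exp1_design(categories, seed: int = 0,
                densities=EXP1_DENSITIES,
                orientations=("upright", "inverted")) -> ExperimentDesign:
    conditions = [{"density": d, "orientation": o}
                  for o in orientations for d in densities]
    return ExperimentDesign("exp1", conditions, tuple(categories), seed)


def exp2_design(categories, seed: int = 0,
                voxel_sizes=EXP2_VOXEL_SIZES) -> ExperimentDesign:
    conditions = [{"voxel_size": v} for v in voxel_sizes]
    return ExperimentDesign("exp2", conditions, tuple(categories), seed)


def exp2_participant_design(instances_by_category: dict, seed: int = 0,
                            n_per_category: int = 4,
                            voxel_sizes=(0.01, 0.05, 0.1, 0.2)) -> pd.DataFrame:
    """One participant's trial list for the Lego experiment: from each
    category, ``n_per_category`` instances drawn at random, each randomly
    assigned one voxel size — 40 trials for 10 categories."""
    rng = np.random.default_rng(seed)
    rows = []
    for cat in sorted(instances_by_category):
        pool = list(instances_by_category[cat])
        picks = rng.choice(len(pool), size=n_per_category, replace=False)
        sizes = rng.choice(voxel_sizes, size=n_per_category, replace=True)
        for i, v in zip(picks, sizes):
            rows.append({"category": cat, "instance": pool[i], "voxel_size": float(v)})
    return pd.DataFrame(rows)


def _stimulus_seed(design_seed: int, cond_i: int, cloud_i: int) -> int:
    return int((design_seed * 1_000_003 + cond_i * 1_009 + cloud_i) % (2 ** 31))


def generate_experiment_stimuli(design: ExperimentDesign, clouds) -> list:
    """Materialize every (condition × base cloud) stimulus with provenance."""
    records = []
    for ci, cond in enumerate(design.conditions):
        for pi, pc in enumerate(clouds):
            seed = _stimulus_seed(design.seed, ci, pi)
            if design.experiment == "exp1":
                stim = downsample_density(pc, cond["density"], seed)
                if cond["orientation"] == "inverted":
                    stim = invert(stim)
            elif design.experiment == "exp2":
                if cond["voxel_size"] == 0.0:
                    stim = pc.copy()
                else:
                    stim = voxelize_lego(pc, cond["voxel_size"], seed=seed)
            else:
                raise ValueError(f"no direct grid for experiment {design.experiment!r}")
            records.append(StimulusRecord(stim, pc.instance_id,
                                          design.experiment, dict(cond), seed))
    return records


def run_experiment(classifiers: dict, design: ExperimentDesign, clouds) -> pd.DataFrame:
    """Predictions table over the full stimulus grid.

    One row per (model, condition, stimulus) with the true and predicted
    category and full provenance.
    """
    stimuli = generate_experiment_stimuli(design, clouds)
    truth = {pc.instance_id: pc.category for pc in clouds}
    rows = []
    for name, model in classifiers.items():
        for rec in stimuli:
            pred = restrict_predict(model, rec.cloud, design.categories)
            row = {"model": name, "instance": rec.base_instance,
                   "true": truth[rec.base_instance], "predicted": pred,
                   "seed": rec.seed}
            row.update(rec.params)
            rows.append(row)
    return pd.DataFrame(rows)


# -- part-scrambling with the model-agreement filter --------------------------


def filter_scrambles(model, originals, category_subset, quota: int = 10,
                     retry_cap: int = 200,
                     config: ScrambleConfig | None = None) -> list:
    """Scrambled stimuli the model classifies like their originals.

    For each category, originals are scrambled (after threshold-triggered
    part subdivision) with fresh seeds until ``quota`` scrambles are
    accepted — a scramble is accepted iff the model's restricted prediction
    matches its prediction for the intact cloud. Raises if any category
    cannot fill its quota within ``retry_cap`` attempts per original.
    """
    config = config or ScrambleConfig()
    by_cat: dict[str, list] = {}
    for pc in originals:
        by_cat.setdefault(pc.category, []).append(pc)
    accepted = []
    failing = []
    for cat in sorted(by_cat):
        got = 0
        pool = by_cat[cat]
        for oi, pc in enumerate(pool):
            if got >= quota:
                break
            base_pred = restrict_predict(model, pc, category_subset)
            refined = subdivide_large_parts(pc, config)
            for attempt in range(retry_cap):
                tag = zlib.crc32(f"{cat}:{oi}:{attempt}".encode())
                seed = int((config.seed * 7_919 + tag) % (2 ** 31))
                rec = scramble_parts(refined, replace(config, seed=seed))
                if restrict_predict(model, rec.cloud, category_subset) == base_pred:
                    accepted.append(rec)
                    got += 1
                    break
        if got < quota:
            failing.append(f"{cat} ({got}/{quota})")
    if failing:
        raise RuntimeError("scramble quota unreachable for: " + ", ".join(failing))
    return accepted


def exp3_stimulus_set(models: dict, originals, category_subset,
                      quota: int = 10, retry_cap: int = 200,
                      config: ScrambleConfig | None = None) -> list:
    """The full part-scrambling stimulus set.

    For each source model: ``quota`` accepted scrambles per category plus
    their intact originals. With two models, five categories and quota 10
    this is 2 × 5 × 10 × 2 = 200 stimuli.
    """
    stimuli = []
    lookup = {pc.instance_id: pc for pc in originals}
    for name, model in models.items():
        scrambles = filter_scrambles(model, originals, category_subset,
                                     quota=quota, retry_cap=retry_cap, config=config)
        for rec in scrambles:
            base = lookup[rec.base_instance]
            stimuli.append(StimulusRecord(base.copy(), base.instance_id,
                                          "intact", {"source_model": name}, None))
            rec.params["source_model"] = name
            stimuli.append(rec)
    return stimuli
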
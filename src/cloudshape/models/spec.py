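"""Declarative model specifications, ablations, and the downsampling
intervention.

A :class:`ModelSpec` fully describes either classifier family; ``build_model``
turns it into a network. The default specs pin the hyperparameters of the
reference public implementations so that the trainable-parameter totals land
on the published figures (1.81M for DGCNN, 9.58M for the Point Transformer).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace

__all__ = [
    "ModelSpec", "dgcnn_spec", "point_transformer_spec",
    "desk_dgcnn_spec", "desk_point_transformer_spec",
    "ablate", "add_downsampling_to_dgcnn", "build_model",
    "count_parameters", "stage_point_counts",
    "spec_to_json", "spec_from_json",
]

DGCNN = "dgcnn"
POINT_TRANSFORMER = "point_transformer"

#: mechanisms that can be ablated (all owned by the Point Transformer family)
ABLATABLE = ("attention", "position_encoding", "downsampling")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    n_classes: int = 40
    n_points: int = 1024
    k: int = 20
    stage_widths: tuple = (64, 64, 128, 256)
    # DGCNN-only fields
    emb_dims: int = 1024
    head_widths: tuple = (512, 256)
    dropout: float = 0.5
    dgcnn_downsampling: bool = False   # the intervention: TD after each EdgeConv
    td_ratio: int = 4
    td_k: int = 16
    # Point-Transformer-only fields
    transformer_dim: int = 512
    downsample_ratios: tuple = (1, 4, 16, 64, 256)
    use_attention: bool = True
    use_position_encoding: bool = True
    use_downsampling: bool = True

    def validate(self) -> None:
        if self.family not in (DGCNN, POINT_TRANSFORMER):
            raise ValueError(f"unknown family {self.family!r}")
        if self.k < 1:
            raise ValueError("neighborhood size k must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.family == POINT_TRANSFORMER:
            if len(self.downsample_ratios) != len(self.stage_widths):
                raise ValueError("one downsample ratio per stage is required")
            if self.use_downsampling and any(
                    a >= b for a, b in zip(self.downsample_ratios,
                                           self.downsample_ratios[1:])):
                raise ValueError("downsample ratios must be strictly increasing")


def dgcnn_spec(**overrides) -> ModelSpec:
    """Default DGCNN classifier: 4 EdgeConv stages (64/64/128/256), k=20,
    1024-d global embedding, 512/256 head, 40 classes."""
    spec = ModelSpec(family=DGCNN, k=20, stage_widths=(64, 64, 128, 256),
                     emb_dims=1024, head_widths=(512, 256))
    spec = replace(spec, **overrides)
    spec.validate()
    return spec


def point_transformer_spec(**overrides) -> ModelSpec:
    """Default Point Transformer classifier: 32→512 stage widths doubling
    across four Transition Down stages at the fixed point-count ratio
    [N, N/4, N/16, N/64, N/256], vector self-attention with k=16."""
    spec = ModelSpec(family=POINT_TRANSFORMER, k=16,
                     stage_widths=(32, 64, 128, 256, 512),
                     transformer_dim=512,
                     downsample_ratios=(1, 4, 16, 64, 256),
                     head_widths=(256, 64))
    spec = replace(spec, **overrides)
    spec.validate()
    return spec


def desk_dgcnn_spec(**overrides) -> ModelSpec:
    """Width-reduced DGCNN profile for CPU-scale experiments on the
    synthetic category set."""
    defaults = dict(n_classes=5, n_points=128, k=10,
                    stage_widths=(16, 16, 32, 32), emb_dims=64,
                    head_widths=(64, 32))
    defaults.update(overrides)
    return dgcnn_spec(**defaults)


def desk_point_transformer_spec(**overrides) -> ModelSpec:
    """Width-reduced Point Transformer profile (two Transition Down stages)
    for CPU-scale experiments on the synthetic category set."""
    defaults = dict(n_classes=5, n_points=128, k=8,
                    stage_widths=(16, 32, 64), transformer_dim=32,
                    downsample_ratios=(1, 4, 16), head_widths=(64, 32))
    defaults.update(overrides)
    return point_transformer_spec(**defaults)


def ablate(spec: ModelSpec, component: str) -> ModelSpec:
    """Remove one mechanism from a Point Transformer spec.

    * ``attention``: attention weights fixed to uniform 1/k (mean over the
      neighbors' value terms).
    * ``position_encoding``: the positional term is zero everywhere.
    * ``downsampling``: every Transition Down keeps all points (local
      re-embedding without reduction), so parameter counts are unchanged.
    """
    if component not in ABLATABLE:
        raise ValueError(f"unknown component {component!r}; expected one of {ABLATABLE}")
    if spec.family != POINT_TRANSFORMER:
        raise ValueError(f"family {spec.family!r} has no {component} mechanism to ablate")
    field = {"attention": "use_attention",
             "position_encoding": "use_position_encoding",
             "downsampling": "use_downsampling"}[component]
    return replace(spec, **{field: False})


def add_downsampling_to_dgcnn(spec: ModelSpec) -> ModelSpec:
    """The intervention: insert a Transition Down stage (ratio 4, k=16 by
    default) after every EdgeConv layer of a DGCNN, matching the structural
    depth of the Point Transformer."""
    if spec.family != DGCNN:
        raise ValueError("the downsampling intervention applies to DGCNN specs")
    return replace(spec, dgcnn_downsampling=True)


def stage_point_counts(spec: ModelSpec, n_points: int | None = None) -> list[int]:
    """Point counts entering each stage under the spec's reduction schedule.

    Counts for N not divisible by the ratio use floor with a minimum of 1.
    """
    n = n_points if n_points is not None else spec.n_points
    if spec.family == POINT_TRANSFORMER:
        if not spec.use_downsampling:
            return [n] * len(spec.stage_widths)
        return [max(1, n // r) for r in spec.downsample_ratios]
    counts, m = [], n
    for _ in spec.stage_widths:
        counts.append(m)
        if spec.dgcnn_downsampling:
            m = max(1, m // spec.td_ratio)
    return counts


def build_model(spec: ModelSpec, seed: int = 0):
    """Construct a classifier from a spec (weights initialized from ``seed``)."""
    spec.validate()
    from .dgcnn import DGCNNClassifier
    from .point_transformer import PointTransformerClassifier
    if spec.family == DGCNN:
        return DGCNNClassifier(spec, seed=seed)
    return PointTransformerClassifier(spec, seed=seed)


def count_parameters(model) -> int:
    """Exact number of trainable scalars in a built model."""
    return int(sum(p.data.size for p in model.parameters()))


def spec_to_json(spec: ModelSpec) -> str:
    return json.dumps(dataclasses.asdict(spec), indent=2, sort_keys=True)


def spec_from_json(text: str) -> ModelSpec:
    d = json.loads(text)
    for key in ("stage_widths", "head_widths", "downsample_ratios"):
        d[key] = tuple(d[key])
    spec = ModelSpec(**d)
    spec.validate()
    return spec
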
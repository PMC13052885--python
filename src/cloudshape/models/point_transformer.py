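"""Point Transformer classifier.

An MLP embedding is followed by alternating vector self-attention blocks and
Transition Down stages; point counts shrink along the configured ratio
schedule (the default [N, N/4, N/16, N/64, N/256]) while feature widths
double. Global mean pooling feeds a small MLP head. Neighborhoods are always
defined in 3D space (k=16 by default).

The three ablation flags on the spec remove, respectively, the attention
weighting (replaced by a uniform mean), the positional term, and the point
reduction (Transition Down keeps all points).
"""

from __future__ import annotations

import numpy as np

from .. import nn
from .._tensor import Tensor
from .layers import TransformerBlock, TransitionDown
from .spec import ModelSpec, stage_point_counts


class PointTransformerClassifier(nn.Module):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng_holder = {"rng": np.random.default_rng(seed + 1)}
        widths = spec.stage_widths
        dm = spec.transformer_dim
        self.fc1 = nn.Sequential(
            nn.Linear(3, widths[0], rng=rng), nn.ReLU(),
            nn.Linear(widths[0], widths[0], rng=rng))
        self.blocks = [TransformerBlock(
            widths[0], dm, spec.k, rng,
            use_attention=spec.use_attention,
            use_position_encoding=spec.use_position_encoding)]
        self.transition_downs = []
        for w_in, w_out in zip(widths[:-1], widths[1:]):
            self.transition_downs.append(
                TransitionDown(w_in, w_out, spec.k, rng))
            self.blocks.append(TransformerBlock(
                w_out, dm, spec.k, rng,
                use_attention=spec.use_attention,
                use_position_encoding=spec.use_position_encoding))
        h1, h2 = spec.head_widths
        self.head = nn.Sequential(
            nn.Linear(widths[-1], h1, rng=rng), nn.ReLU(),
            nn.Linear(h1, h2, rng=rng), nn.ReLU(),
            nn.Linear(h2, spec.n_classes, rng=rng))
        self.last_stage_counts: list[int] | None = None

    def forward(self, coords: np.ndarray) -> Tensor:
        coords = np.asarray(coords, dtype=np.float32)
        if coords.ndim == 2:
            coords = coords[None]
        n = coords.shape[1]
        targets = stage_point_counts(self.spec, n)
        xyz = coords
        feats = self.blocks[0](xyz, self.fc1(Tensor(coords)))
        counts = [feats.shape[1]]
        for td, block, target in zip(self.transition_downs,
                                     self.blocks[1:], targets[1:]):
            xyz, feats, _ = td(xyz, feats, min(target, feats.shape[1]))
            feats = block(xyz, feats)
            counts.append(feats.shape[1])
        self.last_stage_counts = counts
        return self.head(feats.mean(axis=1))
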
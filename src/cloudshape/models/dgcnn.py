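"""DGCNN classifier, with the optional Transition Down intervention.

The plain network stacks four EdgeConv stages whose neighbor graphs are
recomputed in feature space at every layer, concatenates the multi-scale
stage outputs, embeds them (1024-d by default), and pools globally by max
and mean before a three-layer head.

With ``spec.dgcnn_downsampling`` set (see ``add_downsampling_to_dgcnn``), a
Transition Down stage follows every EdgeConv, reducing the point set by the
configured ratio; earlier stage outputs are gathered down to the surviving
points so the multi-scale concatenation remains well defined.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from .._tensor import Tensor, concat, index_points
from .layers import EdgeConv, TransitionDown
from .spec import ModelSpec


class DGCNNClassifier(nn.Module):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng_holder = {"rng": np.random.default_rng(seed + 1)}
        widths = spec.stage_widths
        in_dims = (3,) + tuple(widths[:-1])
        self.edge_convs = [EdgeConv(d_in, d_out, spec.k, rng)
                           for d_in, d_out in zip(in_dims, widths)]
        if spec.dgcnn_downsampling:
            self.transition_downs = [TransitionDown(w, w, spec.td_k, rng)
                                     for w in widths]
        else:
            self.transition_downs = []
        self.embed = nn.Linear(sum(widths), spec.emb_dims, bias=False, rng=rng)
        self.embed_bn = nn.BatchNorm(spec.emb_dims)
        h1, h2 = spec.head_widths
        self.head = nn.Sequential(
            nn.Linear(2 * spec.emb_dims, h1, bias=False, rng=rng),
            nn.BatchNorm(h1), nn.LeakyReLU(0.2),
            nn.Dropout(spec.dropout, self.rng_holder),
            nn.Linear(h1, h2, rng=rng),
            nn.BatchNorm(h2), nn.LeakyReLU(0.2),
            nn.Dropout(spec.dropout, self.rng_holder),
            nn.Linear(h2, spec.n_classes, rng=rng),
        )
        self.last_stage_counts: list[int] | None = None

    def forward(self, coords: np.ndarray) -> Tensor:
        coords = np.asarray(coords, dtype=np.float32)
        if coords.ndim == 2:
            coords = coords[None]
        b, n, _ = coords.shape
        xyz = coords
        feats = Tensor(coords)
        stage_outs: list[Tensor] = []
        counts: list[int] = []
        for i, conv in enumerate(self.edge_convs):
            counts.append(feats.shape[1])
            h = conv(feats)
            stage_outs.append(h)
            if self.transition_downs:
                m = h.shape[1]
                target = max(1, m // self.spec.td_ratio)
                xyz, h, fps_idx = self.transition_downs[i](xyz, h, target)
                stage_outs = [index_points(s, fps_idx) for s in stage_outs]
            feats = h
        self.last_stage_counts = counts
        x = concat(stage_outs, axis=-1)
        e = self.embed_bn(self.embed(x)).leaky_relu(0.2)
        pooled = concat([e.max(axis=1), e.mean(axis=1)], axis=-1)
        return self.head(pooled)
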
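"""The three mechanism-bearing layers: EdgeConv, vector self-attention,
and Transition Down (farthest-point-sampling pooling)."""

from __future__ import annotations

import numpy as np

from .. import nn
from .._tensor import Tensor, concat, index_points, softmax
from ._ops import farthest_point_sampling_batch, knn_cross, knn_indices

__all__ = ["EdgeConv", "TransitionDown", "TransformerBlock", "position_encoding"]


class EdgeConv(nn.Module):
    """Dynamic-graph edge convolution.

    Each point is compared with its k nearest neighbors *in feature space*;
    the per-edge input is the concatenation (center, neighbor − center),
    mapped through a shared affine + batch norm + leaky ReLU, then
    max-aggregated over the k edges. Because the graph is rebuilt from the
    current features at every layer, the neighborhood structure changes as
    the representation deepens.
    """

    def __init__(self, in_dim: int, out_dim: int, k: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.lin = nn.Linear(2 * in_dim, out_dim, bias=False, rng=rng)
        self.bn = nn.BatchNorm(out_dim)
        self.act = nn.LeakyReLU(0.2)

    def forward(self, feats: Tensor) -> Tensor:
        b, n, d = feats.shape
        idx = knn_indices(feats.data, self.k, include_self=False)
        nbr = index_points(feats, idx)                       # (B, N, k, D)
        ctr = feats.reshape(b, n, 1, d)
        edge = concat([ctr.broadcast_to(nbr.shape), nbr - ctr], axis=-1)
        h = self.act(self.bn(self.lin(edge)))
        return h.max(axis=2)


def position_encoding(fc_delta: nn.Module, coords_i: np.ndarray,
                      coords_j: np.ndarray) -> Tensor:
    """Learned encoding of the relative displacement ``coords_i − coords_j``.

    Only the difference enters the map, so the encoding is invariant to a
    common translation of both points.
    """
    rel = np.asarray(coords_i, dtype=np.float32) - np.asarray(coords_j, dtype=np.float32)
    return fc_delta(Tensor(rel))


class TransformerBlock(nn.Module):
    """Vector self-attention over k-nearest neighbors in 3D space.

    Produces, for each neighbor, a full attention *vector* (one weight per
    channel) from a learned map of (query − key + positional term), softmax-
    normalized over the neighbor axis, and aggregates attention ⊙ (value +
    positional term). A residual connection wraps the block.

    Ablations: ``use_attention=False`` replaces the attention weights with a
    fixed uniform 1/k (mean over neighbors of the value term); the query/key
    and weight-generating maps are then not instantiated.
    ``use_position_encoding=False`` drops the positional term (and its map)
    entirely.
    """

    def __init__(self, d_points: int, d_model: int, k: int,
                 rng: np.random.Generator, use_attention: bool = True,
                 use_position_encoding: bool = True):
        super().__init__()
        self.k = k
        self.d_model = d_model
        self.use_attention = use_attention
        self.use_position_encoding = use_position_encoding
        self.fc1 = nn.Linear(d_points, d_model, rng=rng)
        self.fc2 = nn.Linear(d_model, d_points, rng=rng)
        if use_position_encoding:
            self.fc_delta = nn.Sequential(
                nn.Linear(3, d_model, rng=rng), nn.ReLU(),
                nn.Linear(d_model, d_model, rng=rng))
        self.w_vs = nn.Linear(d_model, d_model, bias=False, rng=rng)
        if use_attention:
            self.w_qs = nn.Linear(d_model, d_model, bias=False, rng=rng)
            self.w_ks = nn.Linear(d_model, d_model, bias=False, rng=rng)
            self.fc_gamma = nn.Sequential(
                nn.Linear(d_model, d_model, rng=rng), nn.ReLU(),
                nn.Linear(d_model, d_model, rng=rng))

    def forward(self, xyz: np.ndarray, feats: Tensor,
                return_attention: bool = False):
        if self.use_position_encoding and xyz is None:
            raise ValueError("position encoding requires point coordinates")
        b, n, _ = feats.shape
        idx = knn_cross(xyz, xyz, self.k)                    # (B, N, k), self included
        knn_xyz = xyz[np.arange(b)[:, None, None], idx]
        pre = feats
        x = self.fc1(feats)
        value = index_points(self.w_vs(x), idx)              # (B, N, k, dm)
        if self.use_position_encoding:
            pos = position_encoding(self.fc_delta, xyz[:, :, None], knn_xyz)
            value = value + pos
        if self.use_attention:
            q = self.w_qs(x).reshape(b, n, 1, self.d_model)
            key = index_points(self.w_ks(x), idx)
            a_in = q - key
            if self.use_position_encoding:
                a_in = a_in + pos
            attn = softmax(self.fc_gamma(a_in) * (1.0 / np.sqrt(self.d_model)),
                           axis=-2)
            res = (attn * value).sum(axis=-2)
        else:
            attn = None  # fixed uniform weights, nothing learned
            res = value.mean(axis=-2)
        out = self.fc2(res) + pre
        if return_attention:
            weights = attn.data if attn is not None else np.full(
                (b, n, self.k, self.d_model), 1.0 / self.k, dtype=np.float32)
            return out, weights
        return out


class TransitionDown(nn.Module):
    """Reduce the point set and locally re-embed features.

    Representatives are chosen by farthest point sampling; each keeps the
    max over a learned two-layer map of its k nearest source points'
    (relative position, feature) pairs. With ``target_count == M`` no
    reduction happens and the layer is a pure local re-embedding, which is
    exactly the NoDS ablation.
    """

    def __init__(self, in_dim: int, out_dim: int, k: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.lin1 = nn.Linear(in_dim + 3, out_dim, rng=rng)
        self.bn1 = nn.BatchNorm(out_dim)
        self.lin2 = nn.Linear(out_dim, out_dim, rng=rng)
        self.bn2 = nn.BatchNorm(out_dim)

    def forward(self, xyz: np.ndarray, feats: Tensor, target_count: int):
        b, m, _ = xyz.shape
        if target_count < 1:
            raise ValueError("target_count must be >= 1")
        if target_count > m:
            raise ValueError(f"target_count {target_count} exceeds point count {m}")
        if target_count == m:
            fps_idx = np.broadcast_to(np.arange(m, dtype=np.int64), (b, m))
            new_xyz = xyz
        else:
            fps_idx = farthest_point_sampling_batch(xyz, target_count)
            new_xyz = xyz[np.arange(b)[:, None], fps_idx]
        nidx = knn_cross(new_xyz, xyz, self.k)               # (B, m', k)
        grouped_xyz = (xyz[np.arange(b)[:, None, None], nidx]
                       - new_xyz[:, :, None]).astype(np.float32)
        grouped = concat([Tensor(grouped_xyz), index_points(feats, nidx)], axis=-1)
        h = self.bn1(self.lin1(grouped)).relu()
        h = self.bn2(self.lin2(h)).relu()
        return new_xyz, h.max(axis=2), fps_idx
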
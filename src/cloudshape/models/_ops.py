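"""Index-space operations shared by both architectures.

These run on plain ndarrays (neighbor selection is not differentiated
through); features gathered with the resulting indices do carry gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["knn_indices", "knn_cross", "farthest_point_sampling"]


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # (..., M, D) x (..., N, D) -> (..., M, N); clipped so exact ties stay ties
    d = (np.sum(a * a, axis=-1)[..., :, None]
         + np.sum(b * b, axis=-1)[..., None, :]
         - 2.0 * (a @ np.swapaxes(b, -1, -2)))
    return np.maximum(d, 0.0)


def _take_k(order: np.ndarray, k: int) -> np.ndarray:
    """First k columns of a sorted index array, cycling when too few exist.

    When a stage has fewer candidates than k, the nearest available points
    are repeated so downstream aggregation stays total.
    """
    avail = order.shape[-1]
    if avail >= k:
        return order[..., :k]
    reps = np.concatenate([order] * (k // avail + 1), axis=-1)
    return reps[..., :k]


def knn_indices(points: np.ndarray, k: int, include_self: bool = True) -> np.ndarray:
    """k nearest neighbors of every row among all rows, by squared distance.

    ``points`` is (M, D) or (B, M, D); the result is (M, k) or (B, M, k).
    Ties are broken toward the lowest index (stable sort). DGCNN uses this
    on per-layer feature embeddings with ``include_self=False``; the Point
    Transformer uses it on 3D coordinates with ``include_self=True``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    pts = np.asarray(points)
    squeeze = pts.ndim == 2
    if squeeze:
        pts = pts[None]
    d = _pairwise_sq_dists(pts, pts)
    if not include_self:
        m = pts.shape[1]
        d[:, np.arange(m), np.arange(m)] = np.inf
    order = np.argsort(d, axis=-1, kind="stable")
    if not include_self:
        order = order[..., :-1]  # drop the masked self column
        if order.shape[-1] == 0:  # single-point cloud: fall back to self
            order = np.zeros(order.shape[:-1] + (1,), dtype=np.int64)
    out = _take_k(order, k)
    return out[0] if squeeze else out


def knn_cross(query: np.ndarray, ref: np.ndarray, k: int) -> np.ndarray:
    """k nearest rows of ``ref`` for each row of ``query`` (batched)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    q, r = np.asarray(query), np.asarray(ref)
    squeeze = q.ndim == 2
    if squeeze:
        q, r = q[None], r[None]
    order = np.argsort(_pairwise_sq_dists(q, r), axis=-1, kind="stable")
    out = _take_k(order, k)
    return out[0] if squeeze else out


def canonical_start_index(coords: np.ndarray) -> np.ndarray:
    """Index of the point farthest from the centroid (first one on ties).

    Used as the default FPS seed point: it depends only on the point *set*,
    so downstream results are invariant to the storage order of the cloud.
    """
    coords = np.asarray(coords, dtype=np.float64)
    d = np.sum((coords - coords.mean(axis=-2, keepdims=True)) ** 2, axis=-1)
    return np.argmax(d, axis=-1)


def farthest_point_sampling(coords: np.ndarray, m: int,
                            start_index: int | None = None) -> np.ndarray:
    """Greedy max–min subset selection.

    Starting from ``start_index`` (default: the canonical point farthest
    from the centroid), repeatedly add the point whose distance to the
    already-selected set is largest; ties resolve to the lowest index.
    Returns the m chosen indices in selection order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if start_index is None:
        start_index = int(canonical_start_index(coords))
    if not 0 <= start_index < n:
        raise ValueError(f"start_index out of range: {start_index}")
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = start_index
    min_d = np.sum((coords - coords[start_index]) ** 2, axis=-1)
    for i in range(1, m):
        nxt = int(np.argmax(min_d))  # argmax returns the first (lowest) maximizer
        chosen[i] = nxt
        np.minimum(min_d, np.sum((coords - coords[nxt]) ** 2, axis=-1), out=min_d)
    return chosen


def farthest_point_sampling_batch(coords: np.ndarray, m: int,
                                  start_index: np.ndarray | None = None) -> np.ndarray:
    """Vectorized greedy max–min over a batch: (B, N, 3) -> (B, m)."""
    coords = np.asarray(coords, dtype=np.float64)
    b, n = coords.shape[:2]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if start_index is None:
        start_index = canonical_start_index(coords)
    start = np.broadcast_to(np.asarray(start_index, dtype=np.int64), (b,))
    chosen = np.empty((b, m), dtype=np.int64)
    chosen[:, 0] = start
    rows = np.arange(b)
    min_d = np.sum((coords - coords[rows, start][:, None]) ** 2, axis=-1)
    for i in range(1, m):
        nxt = np.argmax(min_d, axis=-1)
        chosen[:, i] = nxt
        np.minimum(min_d, np.sum((coords - coords[rows, nxt][:, None]) ** 2, axis=-1),
                   out=min_d)
    return chosen
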
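"""Architecture components against brute-force oracles, plus the spec-level
contracts: parameter counts, permutation invariance, ablation isolation and
the downsampling schedules."""

import numpy as np
import pytest

from cloudshape._tensor import Tensor
from cloudshape.models import (
    EdgeConv,
    TransformerBlock,
    TransitionDown,
    ablate,
    add_downsampling_to_dgcnn,
    build_model,
    count_parameters,
    desk_dgcnn_spec,
    desk_point_transformer_spec,
    dgcnn_spec,
    farthest_point_sampling,
    knn_indices,
    point_transformer_spec,
    position_encoding,
    spec_from_json,
    spec_to_json,
    stage_point_counts,
)


# -- neighbor search ----------------------------------------------------------


def brute_knn(points, k, include_self):
    out = []
    for i, p in enumerate(points):
        d = [(float(np.sum((p - q) ** 2)), j) for j, q in enumerate(points)
             if include_self or j != i]
        d.sort()                      # ties resolve to the lower index
        idx = [j for _, j in d]
        while len(idx) < k:
            idx = idx + idx
        out.append(idx[:k])
    return np.array(out)


def test_knn_collinear_example():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [3, 0, 0]])
    np.testing.assert_array_equal(
        knn_indices(pts, 1, include_self=False).ravel(), [1, 0, 1])


def test_knn_k_equals_m_with_self_covers_everything(rng):
    pts = rng.standard_normal((7, 3))
    idx = knn_indices(pts, 7, include_self=True)
    for row in idx:
        assert set(row) == set(range(7))


def test_knn_matches_bruteforce_oracle(rng):
    for _ in range(30):
        m = int(rng.integers(3, 40))
        d = int(rng.integers(2, 6))
        k = int(rng.integers(1, m + 2))
        pts = rng.standard_normal((m, d))
        for include_self in (True, False):
            np.testing.assert_array_equal(
                knn_indices(pts, k, include_self=include_self),
                brute_knn(pts, k, include_self))


def test_feature_space_graph_differs_from_spatial_graph(rng):
    coords = rng.standard_normal((20, 3))
    feats = rng.standard_normal((20, 8))   # unrelated embedding reorders ranks
    assert not np.array_equal(knn_indices(coords, 3, include_self=False),
                              knn_indices(feats, 3, include_self=False))


def test_knn_rejects_nonpositive_k(rng):
    with pytest.raises(ValueError):
        knn_indices(rng.standard_normal((5, 3)), 0)


# -- farthest point sampling --------------------------------------------------


def brute_fps(coords, m, start):
    chosen = [start]
    for _ in range(m - 1):
        best, best_d = None, -1.0
        for i in range(len(coords)):
            d = min(float(np.sum((coords[i] - coords[j]) ** 2)) for j in chosen)
            if d > best_d:            # strict: ties keep the lowest index
                best, best_d = i, d
        chosen.append(best)
    return np.array(chosen)


def test_fps_line_example():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]])
    np.testing.assert_array_equal(farthest_point_sampling(pts, 2, start_index=0),
                                  [0, 3])


def test_fps_degenerate_sizes(rng):
    pts = rng.standard_normal((6, 3))
    assert farthest_point_sampling(pts, 1, start_index=2).tolist() == [2]
    assert set(farthest_point_sampling(pts, 6, start_index=0)) == set(range(6))


def test_fps_matches_bruteforce_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(4, 50))
        m = int(rng.integers(1, n + 1))
        start = int(rng.integers(0, n))
        pts = rng.standard_normal((n, 3))
        np.testing.assert_array_equal(
            farthest_point_sampling(pts, m, start_index=start),
            brute_fps(pts, m, start))


# -- EdgeConv -----------------------------------------------------------------


def test_edge_conv_identical_points_give_identical_rows(rng):
    layer = EdgeConv(3, 8, k=4, rng=rng).eval()
    feats = Tensor(np.tile(np.float32([1, 2, 3]), (1, 6, 1)))
    out = layer(feats).data[0]
    np.testing.assert_allclose(out, np.tile(out[0], (6, 1)), atol=1e-6)


def test_edge_conv_permutation_equivariance(rng):
    layer = EdgeConv(3, 8, k=3, rng=rng).eval()
    pts = rng.standard_normal((1, 10, 3)).astype(np.float32)
    perm = rng.permutation(10)
    out = layer(Tensor(pts)).data[0]
    out_p = layer(Tensor(pts[:, perm])).data[0]
    np.testing.assert_allclose(out_p, out[perm], atol=1e-5)


def test_edge_conv_single_point_matches_hand_rolled(rng):
    layer = EdgeConv(3, 4, k=2, rng=rng).eval()
    x = np.float32([[0.3, -0.2, 0.5]])
    out = layer(Tensor(x[None])).data[0, 0]
    # one point: neighbor falls back to self, edge feature is (x, 0)
    edge = np.concatenate([x[0], np.zeros(3, np.float32)])
    w = layer.lin.weight.data
    h = edge @ w.T
    rm, rv = layer.bn.running_mean, layer.bn.running_var
    h = (h - rm) / np.sqrt(rv + layer.bn.eps) * layer.bn.weight.data + layer.bn.bias.data
    h = np.where(h > 0, h, 0.2 * h)
    np.testing.assert_allclose(out, h, atol=1e-6)


# -- vector self-attention ----------------------------------------------------


def test_attention_weights_normalize_over_neighbors(rng):
    block = TransformerBlock(6, 8, k=3, rng=rng).eval()
    xyz = rng.standard_normal((2, 9, 3)).astype(np.float32)
    feats = Tensor(rng.standard_normal((2, 9, 6)).astype(np.float32))
    _, attn = block(xyz, feats, return_attention=True)
    np.testing.assert_allclose(attn.sum(axis=2), 1.0, atol=1e-6)


def test_attention_matches_direct_summation_oracle(rng):
    m, d_p, dm, k = 4, 2, 5, 2
    block = TransformerBlock(d_p, dm, k=k, rng=rng).eval()
    xyz = rng.standard_normal((1, m, 3)).astype(np.float32)
    feats = rng.standard_normal((1, m, d_p)).astype(np.float32)
    out = block(xyz, Tensor(feats)).data[0]

    def lin(layer, v):
        y = v @ layer.weight.data.T
        return y + layer.bias.data if layer.bias is not None else y

    def mlp(seq, v):
        h = lin(seq.layers[0], v)
        h = np.maximum(h, 0)
        return lin(seq.layers[2], h)

    expected = np.empty((m, d_p))
    x = lin(block.fc1, feats[0])
    for i in range(m):
        dists = np.sum((xyz[0] - xyz[0, i]) ** 2, axis=1)
        nbrs = np.argsort(dists, kind="stable")[:k]
        scores, values = [], []
        for j in nbrs:
            pos = mlp(block.fc_delta, xyz[0, i] - xyz[0, j])
            q = lin(block.w_qs, x[i])
            key = lin(block.w_ks, x[j])
            scores.append(mlp(block.fc_gamma, q - key + pos) / np.sqrt(dm))
            values.append(lin(block.w_vs, x[j]) + pos)
        scores = np.stack(scores)
        attn = np.exp(scores - scores.max(axis=0))
        attn /= attn.sum(axis=0)
        agg = (attn * np.stack(values)).sum(axis=0)
        expected[i] = lin(block.fc2, agg) + feats[0, i]
    np.testing.assert_allclose(out, expected, atol=1e-5)


def test_position_encoding_translation_invariance(rng):
    block = TransformerBlock(4, 8, k=2, rng=rng).eval()
    a = rng.standard_normal(3).astype(np.float32)
    b = rng.standard_normal(3).astype(np.float32)
    shift = np.float32([10.0, -4.0, 2.0])
    enc = position_encoding(block.fc_delta, a, b).data
    enc_shifted = position_encoding(block.fc_delta, a + shift, b + shift).data
    np.testing.assert_allclose(enc, enc_shifted, atol=1e-5)
    same = position_encoding(block.fc_delta, a, a).data
    np.testing.assert_allclose(same, position_encoding(block.fc_delta, b, b).data)


# -- transition down ----------------------------------------------------------


def test_transition_down_counts_and_identity_mode(rng):
    td = TransitionDown(4, 8, k=3, rng=rng).eval()
    xyz = rng.standard_normal((1, 12, 3)).astype(np.float32)
    feats = Tensor(rng.standard_normal((1, 12, 4)).astype(np.float32))
    new_xyz, out, idx = td(xyz, feats, 5)
    assert new_xyz.shape == (1, 5, 3) and out.shape[1] == 5
    # target == M: pure re-embedding, original order kept
    new_xyz, out, idx = td(xyz, feats, 12)
    np.testing.assert_array_equal(idx[0], np.arange(12))
    np.testing.assert_allclose(new_xyz, xyz)
    with pytest.raises(ValueError):
        td(xyz, feats, 0)
    with pytest.raises(ValueError):
        td(xyz, feats, 13)


@pytest.mark.parametrize("n,expected", [
    (1024, [1024, 256, 64, 16, 4]),
    (205, [205, 51, 12, 3, 1]),
])
def test_point_transformer_downsampling_schedule(n, expected):
    assert stage_point_counts(point_transformer_spec(), n) == expected


def test_nods_schedule_holds_all_counts():
    spec = ablate(point_transformer_spec(), "downsampling")
    assert stage_point_counts(spec, 1024) == [1024] * 5


def test_dgcnn_intervention_schedule():
    spec = add_downsampling_to_dgcnn(dgcnn_spec())
    assert stage_point_counts(spec, 1024) == [1024, 256, 64, 16]
    assert stage_point_counts(dgcnn_spec(), 1024) == [1024] * 4


# -- built models -------------------------------------------------------------


def test_parameter_counts_match_published_architecture_sizes():
    assert count_parameters(build_model(dgcnn_spec())) == 1_809_576
    assert count_parameters(build_model(point_transformer_spec())) == 9_584_040


def test_single_affine_parameter_count(rng):
    from cloudshape import nn
    assert sum(p.data.size for p in nn.Linear(3, 8, rng=rng).parameters()) == 32


@pytest.mark.parametrize("spec_fn", [desk_dgcnn_spec, desk_point_transformer_spec],
                         ids=["dgcnn", "point_transformer"])
def test_forward_permutation_invariance(spec_fn, rng):
    model = build_model(spec_fn(), seed=3).eval()
    pts = rng.standard_normal((1, 48, 3)).astype(np.float32)
    out = model(pts).data
    out_p = model(pts[:, rng.permutation(48)]).data
    np.testing.assert_allclose(out, out_p, atol=1e-5)


def test_forward_instrumented_stage_counts(rng):
    pts = rng.standard_normal((1, 64, 3)).astype(np.float32)
    pt = build_model(desk_point_transformer_spec(), seed=0).eval()
    pt(pts)
    assert pt.last_stage_counts == [64, 16, 4]
    nods = build_model(ablate(desk_point_transformer_spec(), "downsampling")).eval()
    nods(pts)
    assert nods.last_stage_counts == [64, 64, 64]
    ds = build_model(add_downsampling_to_dgcnn(desk_dgcnn_spec())).eval()
    ds(pts)
    assert ds.last_stage_counts == [64, 16, 4, 1]


def test_ablation_isolation():
    base = point_transformer_spec()
    # NoDS: reduction is index selection, parameter count unchanged exactly
    assert (count_parameters(build_model(ablate(base, "downsampling")))
            == count_parameters(build_model(base)))
    # NoPE: identical layout except the positional maps
    names = {n for n, _ in build_model(base).named_parameters()}
    names_nope = {n for n, _ in build_model(ablate(base, "position_encoding")).named_parameters()}
    assert names_nope < names
    assert all("fc_delta" in n for n in names - names_nope)


def test_noattn_uses_uniform_neighbor_weights(rng):
    spec = ablate(desk_point_transformer_spec(), "attention")
    model = build_model(spec, seed=0).eval()
    block = model.blocks[0]
    xyz = rng.standard_normal((1, 10, 3)).astype(np.float32)
    feats = Tensor(rng.standard_normal((1, 10, spec.stage_widths[0])).astype(np.float32))
    _, weights = block(xyz, feats, return_attention=True)
    np.testing.assert_allclose(weights, 1.0 / spec.k)


def test_nope_block_invariant_to_rigid_translation(rng):
    # with the positional term removed, coordinates enter an attention block
    # only through neighbor selection, which is translation invariant
    block = TransformerBlock(4, 8, k=3, rng=rng,
                             use_position_encoding=False).eval()
    xyz = rng.standard_normal((1, 20, 3)).astype(np.float32)
    feats = Tensor(rng.standard_normal((1, 20, 4)).astype(np.float32))
    out = block(xyz, feats).data
    out_shift = block(xyz + np.float32([5.0, -2.0, 1.0]), feats).data
    np.testing.assert_allclose(out, out_shift, atol=1e-5)


def test_intervention_adds_parameters():
    assert (count_parameters(build_model(add_downsampling_to_dgcnn(dgcnn_spec())))
            > count_parameters(build_model(dgcnn_spec())))


def test_spec_validation_and_serialization():
    with pytest.raises(ValueError):
        dgcnn_spec(k=0)
    with pytest.raises(ValueError):
        point_transformer_spec(downsample_ratios=(1, 4))
    with pytest.raises(ValueError):
        point_transformer_spec(downsample_ratios=(1, 4, 4, 64, 256))
    with pytest.raises(ValueError):
        ablate(dgcnn_spec(), "attention")
    with pytest.raises(ValueError):
        ablate(point_transformer_spec(), "edges")
    with pytest.raises(ValueError):
        add_downsampling_to_dgcnn(point_transformer_spec())
    spec = point_transformer_spec()
    assert spec_from_json(spec_to_json(spec)) == spec
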
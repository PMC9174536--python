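"""Architecture tests: blocks, attention modules, assembly, parameter counts."""

import numpy as np
import pytest

from angioseg._autograd import Tensor
from angioseg.model import (
    BlockSpec,
    BottleneckBlock,
    BottleneckResidualUNet,
    NetConfig,
    PamConfig,
    PatchAttention,
    SeConfig,
    SqueezeExcite,
    attention_map,
    backbone_config,
    block_param_count,
    build_network,
    count_parameters,
    patch_split,
    relu6,
)


# ---------------------------------------------------------------------------
# ReLU6 and patch splitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (7.0, 6.0), (3.5, 3.5),
                                        (0.0, 0.0), (6.0, 6.0)])
def test_relu6_clamps_both_sides(x, expected):
    assert relu6(x) == expected


def test_relu6_elementwise_on_arrays():
    x = np.array([-1.0, 2.0, 8.0])
    assert np.array_equal(relu6(x), [0.0, 2.0, 6.0])


def test_patch_split_cases():
    assert np.array_equal(patch_split(np.arange(8.0).reshape(2, 2, 2), 1),
                          np.arange(8.0).reshape(2, 2, 2))
    ones = np.ones((4, 4, 1))
    assert np.array_equal(patch_split(ones, 2), np.ones((2, 2, 1)))
    m = np.array([[0.0, 2.0], [4.0, 6.0]])[:, :, None]
    assert patch_split(m, 2).item() == 3.0


def test_patch_split_rejects_nondivisible():
    with pytest.raises(ValueError):
        patch_split(np.zeros((6, 6, 1)), 4)


# ---------------------------------------------------------------------------
# attention map
# ---------------------------------------------------------------------------

def test_attention_map_uniform_for_zero_inputs():
    s = attention_map(np.zeros((4, 3)), np.zeros((4, 3)))
    assert np.allclose(s, 0.25)


def test_attention_map_rows_sum_to_one(rng):
    s = attention_map(rng.normal(size=(6, 5)), rng.normal(size=(6, 5)))
    assert np.allclose(s.sum(axis=1), 1.0, atol=1e-6)


def test_attention_map_two_patch_hand_case():
    s = attention_map(np.array([[1.0], [0.0]]), np.array([[1.0], [0.0]]))
    e = np.e
    assert np.allclose(s[0], [e / (e + 1), 1 / (e + 1)])
    assert np.allclose(s[1], [0.5, 0.5])


# ---------------------------------------------------------------------------
# bottleneck block
# ---------------------------------------------------------------------------

def test_bottleneck_preserves_shape_when_stride_one(rng):
    blk = BottleneckBlock(BlockSpec(8, 8, 1, 2), rng=rng)
    x = rng.normal(size=(2, 8, 16, 16)).astype(np.float32)
    assert blk(Tensor(x)).shape == x.shape


def test_bottleneck_downsamples_and_projects(rng):
    blk = BottleneckBlock(BlockSpec(8, 16, 2, 2), rng=rng)
    x = rng.normal(size=(1, 8, 32, 32)).astype(np.float32)
    assert blk(Tensor(x)).shape == (1, 16, 16, 16)


def test_bottleneck_residual_passthrough_with_zero_projection(rng):
    blk = BottleneckBlock(BlockSpec(8, 8, 1, 2), rng=rng)
    blk.project.weight.data[...] = 0.0
    blk.eval()
    x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    assert np.allclose(blk(Tensor(x)).data, x)


def test_bottleneck_rejects_channel_mismatch(rng):
    blk = BottleneckBlock(BlockSpec(8, 8, 1, 2), rng=rng)
    with pytest.raises(ValueError):
        blk(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))


@pytest.mark.parametrize("spec,expected", [
    (BlockSpec(16, 16, 1, 2), 1472),
    (BlockSpec(1, 8, 1, 1), 38),
])
def test_block_param_count_hand_enumerations(spec, expected):
    assert block_param_count(spec) == expected


@pytest.mark.parametrize("spec", [
    BlockSpec(16, 16, 1, 2),
    BlockSpec(8, 24, 2, 3),
    BlockSpec(40, 64, 2, 2, use_se=True),
    BlockSpec(1, 32, 1, 4, use_se=True),
])
def test_block_param_count_matches_built_block(spec):
    blk = BottleneckBlock(spec, SeConfig())
    assert blk.num_parameters() == block_param_count(spec, SeConfig())


def test_block_param_count_affine_in_expansion():
    counts = [block_param_count(BlockSpec(16, 24, 1, t)) for t in (2, 4, 6, 8)]
    diffs = np.diff(counts)
    assert len(set(diffs.tolist())) == 1


# ---------------------------------------------------------------------------
# squeeze and excitation
# ---------------------------------------------------------------------------

def test_se_zero_weights_halve_the_input(rng):
    se = SqueezeExcite(6, SeConfig(), rng=rng)
    for p in se.parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
    assert np.allclose(se(Tensor(x)).data, 0.5 * x, atol=1e-6)


def test_se_output_is_per_channel_scaling_in_unit_interval(rng):
    se = SqueezeExcite(6, SeConfig(), rng=rng)
    x = rng.uniform(0.5, 1.5, size=(1, 6, 5, 5)).astype(np.float32)
    y = se(Tensor(x)).data
    factors = y / x
    # one factor per channel, strictly inside (0, 1)
    per_channel = factors.reshape(6, -1)
    assert np.allclose(per_channel, per_channel[:, :1], atol=1e-5)
    assert (per_channel > 0.0).all() and (per_channel < 1.0).all()


def test_se_squeeze_is_channel_mean(rng):
    x = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)[None, None]
    z = Tensor(x).mean(axis=(2, 3))
    assert z.data[0, 0] == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# patch attention module
# ---------------------------------------------------------------------------

def pam_loop_oracle(F, wq, wk, wv, alpha, n):
    """Literal per-patch-pair implementation of patch attention.

    F is (H, W, C); wq/wk/wv are (C, C) 1x1 convolution matrices applied to
    the pooled map; returns the (H, W, C) module output.
    """
    H, W, C = F.shape
    h, w = H // n, W // n
    pooled = np.zeros((h, w, C))
    for i in range(h):
        for j in range(w):
            pooled[i, j] = F[i * n:(i + 1) * n, j * n:(j + 1) * n].mean(axis=(0, 1))
    flat = pooled.reshape(h * w, C)
    q, k, v = flat @ wq.T, flat @ wk.T, flat @ wv.T
    N = h * w
    s = np.zeros((N, N))
    for m in range(N):
        logits = np.array([q[m] @ k[nn] for nn in range(N)])
        logits -= logits.max()
        e = np.exp(logits)
        s[m] = e / e.sum()
    attended = np.zeros_like(flat)
    for m in range(N):
        for nn in range(N):
            attended[m] += s[m, nn] * v[nn]
    combined = (alpha * attended + flat).reshape(h, w, C)
    up = np.repeat(np.repeat(combined, n, axis=0), n, axis=1)
    return F + up


@pytest.mark.parametrize("shape,n", [((4, 4, 2), 2), ((8, 8, 4), 2),
                                     ((8, 8, 4), 4)])
def test_pam_matches_loop_oracle(shape, n, rng):
    H, W, C = shape
    pam = PatchAttention(C, PamConfig(patch_size=n), rng=rng)
    pam.alpha.data[...] = 0.7
    F = rng.normal(size=shape).astype(np.float32)
    wq = pam.q.weight.data.reshape(C, C)
    wk = pam.k.weight.data.reshape(C, C)
    wv = pam.v.weight.data.reshape(C, C)
    ref = pam_loop_oracle(F.astype(np.float64), wq, wk, wv, 0.7, n)
    out = pam(Tensor(F.transpose(2, 0, 1)[None]))
    got = out.data[0].transpose(1, 2, 0)
    assert np.allclose(got, ref, atol=1e-5)


def test_pam_with_unit_patches_equals_position_attention(rng):
    """n=1 reduces patch attention to DANet-style pixel position attention."""
    C, H = 3, 8
    pam = PatchAttention(C, PamConfig(patch_size=1), rng=rng)
    pam.alpha.data[...] = 1.3
    F = rng.normal(size=(H, H, C)).astype(np.float32)
    wq = pam.q.weight.data.reshape(C, C)
    wk = pam.k.weight.data.reshape(C, C)
    wv = pam.v.weight.data.reshape(C, C)
    # position attention over pixels, written directly
    flat = F.reshape(H * H, C).astype(np.float64)
    q, k, v = flat @ wq.T, flat @ wk.T, flat @ wv.T
    s = attention_map(q, k)
    ref = F + (1.3 * (s @ v) + flat).reshape(H, H, C)
    out = pam(Tensor(F.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
    assert np.allclose(out, ref, atol=1e-5)


def test_pam_identity_maps_double_the_input(rng):
    C = 4
    pam = PatchAttention(C, PamConfig(patch_size=1), rng=rng)
    eye = np.eye(C, dtype=np.float32).reshape(C, C, 1, 1)
    for conv in (pam.q, pam.k, pam.v):
        conv.weight.data[...] = eye
    pam.alpha.data[...] = 0.0
    x = rng.normal(size=(1, C, 4, 4)).astype(np.float32)
    assert np.allclose(pam(Tensor(x)).data, 2.0 * x, atol=1e-6)


def test_pam_preserves_shape_and_shrinks_attention_by_n4(rng):
    for n in (1, 2, 4):
        pam = PatchAttention(2, PamConfig(patch_size=n), rng=rng)
        x = rng.normal(size=(1, 2, 16, 16)).astype(np.float32)
        y = pam(Tensor(x))
        assert y.shape == x.shape
        _, N, N2 = pam.last_attention_shape
        assert N == N2
        full_entries = (16 * 16) ** 2
        assert N * N * n ** 4 == full_entries


def test_pam_rejects_nondivisible_patch(rng):
    pam = PatchAttention(2, PamConfig(patch_size=3), rng=rng)
    with pytest.raises(ValueError):
        pam(Tensor(np.zeros((1, 2, 16, 16), dtype=np.float32)))


# ---------------------------------------------------------------------------
# network assembly and parameter counting
# ---------------------------------------------------------------------------

def test_network_output_contract(rng):
    net = build_network(NetConfig(), seed=0).eval()
    x = rng.random((1, 1, 96, 96), dtype=np.float32)
    y = net(Tensor(x))
    assert y.shape == (1, 1, 96, 96)
    assert (y.data > 0.0).all() and (y.data < 1.0).all()


def test_network_accepts_any_multiple_of_downsample_factor(rng):
    net = build_network(NetConfig(), seed=0).eval()
    x = rng.random((1, 1, 64, 96), dtype=np.float32)
    assert net(Tensor(x)).shape == (1, 1, 64, 96)


def test_network_rejects_bad_input_shape():
    net = build_network(NetConfig(), seed=0)
    with pytest.raises(ValueError):
        net(Tensor(np.zeros((1, 1, 50, 50), dtype=np.float32)))
    with pytest.raises(ValueError):
        net(Tensor(np.zeros((1, 3, 96, 96), dtype=np.float32)))


def test_conv_bn_param_count_enumeration():
    from angioseg._autograd import BatchNorm2d, Conv2d
    conv = Conv2d(4, 8, 1)
    bn = BatchNorm2d(8)
    assert conv.num_parameters() + bn.num_parameters() == 48


def test_pam_toggle_changes_count_by_qkv_plus_alpha():
    with_pam = count_parameters(build_network(backbone_config(2, use_pam=True)))
    without = count_parameters(build_network(backbone_config(2)))
    c = NetConfig().stage_widths[-1]
    assert with_pam - without == 3 * c * c + 1


def test_backbone_count_is_affine_in_expansion():
    counts = [count_parameters(build_network(backbone_config(t)))
              for t in (2, 4, 6, 8)]
    diffs = np.diff(counts)
    assert len(set(diffs.tolist())) == 1


def test_seeded_build_is_reproducible(rng):
    a = build_network(NetConfig(), seed=11).eval()
    b = build_network(NetConfig(), seed=11).eval()
    x = rng.random((1, 1, 64, 64), dtype=np.float32)
    assert np.array_equal(a(Tensor(x)).data, b(Tensor(x)).data)
    sa, sb = a.state_dict(), b.state_dict()
    assert all(np.array_equal(sa[k], sb[k]) for k in sa)


def test_forward_is_deterministic_given_weights(rng):
    net = build_network(NetConfig(), seed=5).eval()
    x = rng.random((2, 1, 64, 64), dtype=np.float32)
    assert np.array_equal(net(Tensor(x)).data, net(Tensor(x)).data)
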
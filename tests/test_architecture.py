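"""Block semantics, shape propagation and exact parameter accounting."""
import numpy as np
import pytest

from octstitch import nn
from octstitch.architecture import (ECB, ESA, LFFN, LTB, MHCA, build_medvit,
                                    count_parameters, parameters_millions)
from octstitch.nn import Tensor
from octstitch.specs import (BlockConventions, ConfigurationError,
                             micro_spec, reduced_spec, tiny_spec)


def _identity_bn(bn):
    """Make a BatchNorm an exact identity in eval mode."""
    bn.weight.data[...] = 1.0
    bn.bias.data[...] = 0.0
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps


# ---------------------------------------------------------------------------
# MHCA
# ---------------------------------------------------------------------------

def test_mhca_preserves_stage1_shape():
    nn.manual_seed(0)
    m = MHCA(96, head_dim=32).eval()
    x = np.random.default_rng(0).random((2, 96, 56, 56)).astype(np.float32)
    with nn.no_grad():
        out = m(Tensor(x))
    assert out.shape == (2, 96, 56, 56)


def test_mhca_identity_projection_returns_aggregated_input():
    # h = 1; aggregation kernel = centre tap; projection = identity.
    nn.manual_seed(0)
    m = MHCA(2, head_dim=2).eval()
    m.aggregate.weight.data[...] = 0.0
    for c in range(2):
        m.aggregate.weight.data[c, c, 1, 1] = 1.0   # centre of 3x3
    _identity_bn(m.norm)
    m.project.weight.data[...] = 0.0
    for c in range(2):
        m.project.weight.data[c, c, 0, 0] = 1.0
    m.project.bias.data[...] = 0.0
    x = np.random.default_rng(1).random((1, 2, 4, 4)).astype(np.float32)
    with nn.no_grad():
        out = m(Tensor(x)).data
    np.testing.assert_allclose(out, x, atol=1e-5)


def test_mhca_small_input_matches_hand_evaluation():
    """(1, 4, 2, 2), 2 heads: per-head 3x3 aggregation then 1x1 projection,
    cross-checked against direct arithmetic over all 4 tokens."""
    nn.manual_seed(0)
    m = MHCA(4, head_dim=2).eval()
    rng = np.random.default_rng(2)
    wagg = rng.normal(size=(4, 2, 3, 3)).astype(np.float32)
    wproj = rng.normal(size=(4, 4, 1, 1)).astype(np.float32)
    bproj = rng.normal(size=4).astype(np.float32)
    m.aggregate.weight.data = wagg
    _identity_bn(m.norm)
    m.project.weight.data = wproj
    m.project.bias.data = bproj
    x = rng.random((1, 4, 2, 2)).astype(np.float32)
    with nn.no_grad():
        out = m(Tensor(x)).data

    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    agg = np.zeros((1, 4, 2, 2), dtype=np.float64)
    for co in range(4):
        head = co // 2                         # group of 2 channels
        for y in range(2):
            for xx in range(2):
                window = xp[0, 2 * head:2 * head + 2, y:y + 3, xx:xx + 3]
                agg[0, co, y, xx] = (window * wagg[co]).sum()
    agg = np.maximum(agg, 0.0)                 # ReLU after identity norm
    expected = np.einsum("oc,bcyx->boyx", wproj[:, :, 0, 0], agg) \
        + bproj[None, :, None, None]
    np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-4)


def test_mhca_rejects_head_channel_mismatch():
    with pytest.raises(ConfigurationError, match="divisible"):
        MHCA(7, head_dim=2, block_name="stage1.ECB7")


# ---------------------------------------------------------------------------
# LFFN
# ---------------------------------------------------------------------------

def test_lffn_preserves_stage2_shape():
    nn.manual_seed(0)
    m = LFFN(192, expansion=3.0).eval()
    x = np.random.default_rng(0).random((2, 192, 28, 28)).astype(np.float32)
    with nn.no_grad():
        out = m(Tensor(x))
    assert out.shape == (2, 192, 28, 28)


def test_block_with_zero_branches_is_residual_identity():
    # all branch weights zero -> ECB output equals its input exactly
    nn.manual_seed(0)
    block = ECB(8, 8, path_dropout=0.0, head_dim=4, expansion=2.0).eval()
    for mod in (block.mhca, block.lffn):
        mod.project.weight.data[...] = 0.0
        mod.project.bias.data[...] = 0.0
    x = np.random.default_rng(0).random((2, 8, 4, 4)).astype(np.float32)
    with nn.no_grad():
        out = block(Tensor(x)).data
    np.testing.assert_array_equal(out, x)


def test_lffn_small_input_matches_hand_convolution_chain():
    nn.manual_seed(0)
    m = LFFN(2, expansion=2.0).eval()
    rng = np.random.default_rng(3)
    w1 = rng.normal(size=(4, 2, 1, 1)).astype(np.float32)
    b1 = rng.normal(size=4).astype(np.float32)
    wd = rng.normal(size=(4, 1, 3, 3)).astype(np.float32)
    bd = rng.normal(size=4).astype(np.float32)
    w2 = rng.normal(size=(2, 4, 1, 1)).astype(np.float32)
    b2 = rng.normal(size=2).astype(np.float32)
    m.expand.weight.data, m.expand.bias.data = w1, b1
    m.dwc.weight.data, m.dwc.bias.data = wd, bd
    m.project.weight.data, m.project.bias.data = w2, b2
    x = rng.random((1, 2, 2, 2)).astype(np.float32)
    with nn.no_grad():
        out = m(Tensor(x)).data

    h = np.einsum("oc,bcyx->boyx", w1[:, :, 0, 0], x) + b1[None, :, None, None]
    hp = np.pad(h, ((0, 0), (0, 0), (1, 1), (1, 1)))
    d = np.zeros_like(h)
    for c in range(4):
        for y in range(2):
            for xx in range(2):
                d[0, c, y, xx] = (hp[0, c, y:y + 3, xx:xx + 3]
                                  * wd[c, 0]).sum()
    d = np.maximum(d + bd[None, :, None, None], 0.0)
    expected = np.einsum("oc,bcyx->boyx", w2[:, :, 0, 0], d) \
        + b2[None, :, None, None]
    np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-4)


# ---------------------------------------------------------------------------
# ESA
# ---------------------------------------------------------------------------

def brute_force_mhsa(x, q_w, q_b, k_w, k_b, v_w, v_b, o_w, o_b, heads):
    """Reference multi-head self-attention over flattened tokens."""
    b, c, hh, ww = x.shape
    t = x.reshape(b, c, hh * ww).transpose(0, 2, 1).astype(np.float64)
    d = c // heads
    out = np.zeros_like(t)
    q = t @ q_w + q_b
    k = t @ k_w + k_b
    v = t @ v_w + v_b
    for h in range(heads):
        sl = slice(h * d, (h + 1) * d)
        scores = q[:, :, sl] @ k[:, :, sl].transpose(0, 2, 1) / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = e / e.sum(axis=-1, keepdims=True)
        out[:, :, sl] = attn @ v[:, :, sl]
    out = out @ o_w + o_b
    return out.transpose(0, 2, 1).reshape(b, c, hh, ww)


@pytest.mark.parametrize("heads,side", [(1, 2), (2, 4), (4, 2)])
def test_esa_with_unit_pool_equals_brute_force_mhsa(heads, side):
    dim = 8
    nn.manual_seed(0)
    esa = ESA(dim, head_dim=dim // heads, pool_stride=1).eval()
    rng = np.random.default_rng(4)
    for lin in (esa.q, esa.k, esa.v, esa.project):
        lin.weight.data = rng.normal(size=(dim, dim)).astype(np.float32) * 0.5
        lin.bias.data = rng.normal(size=dim).astype(np.float32) * 0.1
    x = rng.random((2, dim, side, side)).astype(np.float32)
    with nn.no_grad():
        out = esa(Tensor(x)).data
    ref = brute_force_mhsa(x, esa.q.weight.data, esa.q.bias.data,
                           esa.k.weight.data, esa.k.bias.data,
                           esa.v.weight.data, esa.v.bias.data,
                           esa.project.weight.data, esa.project.bias.data,
                           heads)
    np.testing.assert_allclose(out, ref, atol=1e-5)


def test_esa_pooled_keys_reduce_token_count_and_keep_shape():
    nn.manual_seed(0)
    esa = ESA(384, head_dim=32, pool_stride=2).eval()
    x = np.random.default_rng(5).random((2, 384, 14, 14)).astype(np.float32)
    pooled = nn.avg_pool2d(Tensor(x), 2)
    assert pooled.shape[2] * pooled.shape[3] == 49   # key/value tokens
    with nn.no_grad():
        out = esa(Tensor(x))
    assert out.shape == (2, 384, 14, 14)


# ---------------------------------------------------------------------------
# Blocks and builder
# ---------------------------------------------------------------------------

def test_stage2_ltb_adapts_channels():
    nn.manual_seed(0)
    block = LTB(192, 256, path_dropout=0.0, head_dim=32, expansion=0.3,
                pool_stride=4, qkv_bias=True).eval()
    x = np.random.default_rng(0).random((2, 192, 28, 28)).astype(np.float32)
    with nn.no_grad():
        out = block(Tensor(x))
    assert out.shape == (2, 256, 28, 28)


def test_eval_mode_forward_is_deterministic():
    model = build_medvit("reduced-micro", seed=0).eval()
    x = np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32)
    with nn.no_grad():
        a = model(x).data
        b = model(x).data
    np.testing.assert_array_equal(a, b)


def test_stage3_group_shape_propagation():
    # ECB384 x4 then LTB512 on a (1, 384, 14, 14) input -> (1, 512, 14, 14)
    nn.manual_seed(0)
    blocks = [ECB(384, 384, 0.0, 32, 3.0) for _ in range(4)]
    blocks.append(LTB(384, 512, 0.0, 32, 0.284375, pool_stride=2,
                      qkv_bias=True))
    seq = nn.Sequential(*blocks).eval()
    x = np.random.default_rng(0).random((1, 384, 14, 14)).astype(np.float32)
    with nn.no_grad():
        out = seq(Tensor(x))
    assert out.shape == (1, 512, 14, 14)


def test_micro_backbone_stage_geometry_and_logits():
    model = build_medvit("micro", seed=0).eval()
    x = np.random.default_rng(0).random((2, 3, 224, 224)).astype(np.float32)
    stage_last = {}
    for info in model.block_infos:
        stage_last[info.stage] = info.index
    with nn.no_grad():
        expected_side = {1: 56, 2: 28, 3: 14, 4: 7}
        for stage, last in stage_last.items():
            feats = model.run_prefix(Tensor(x), last)
            assert feats.shape[2] == feats.shape[3] == expected_side[stage]
        logits = model(x)
    assert logits.shape == (2, 3)


def test_reduced_spec_builds_and_runs_on_32px():
    model = build_medvit("reduced-tiny", seed=0).eval()
    x = np.random.default_rng(0).random((4, 3, 32, 32)).astype(np.float32)
    with nn.no_grad():
        out = model(x)
    assert out.shape == (4, 3)


def test_tiny_differs_from_micro_only_in_stage3_repeat_and_dropout():
    m, t = micro_spec(), tiny_spec()
    assert m.path_dropout == 0.05 and t.path_dropout == 0.1
    assert t.stages[2].group_repeat == 2 and m.stages[2].group_repeat == 1
    for i in (0, 1, 3):
        assert m.stages[i] == t.stages[i]
    assert m.stem == t.stem


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def analytic_block_count(kind, dim, in_ch, conventions: BlockConventions):
    """Layer-wise closed-form parameter count, independent of the builder."""
    hd = conventions.head_dim
    adapt = in_ch * dim + 2 * dim if in_ch != dim else 0
    mhca = 9 * hd * dim + 2 * dim + dim * dim + dim
    if kind == "ECB":
        hidden = int(round(dim * conventions.ecb_expansion))
        lffn = 2 * dim * hidden + 11 * hidden + dim
        return adapt + 2 * dim + mhca + 2 * dim + lffn
    esa = 4 * (dim * dim + dim)
    hidden = int(round(dim * conventions.ltb_expansion))
    lffn = 2 * dim * hidden + 11 * hidden + dim
    return adapt + 6 * dim + esa + mhca + lffn


def test_extra_stage3_group_explains_tiny_minus_micro():
    micro = build_medvit("micro", seed=0)
    tiny = build_medvit("tiny", seed=0)
    conv = micro_spec().conventions
    expected = (analytic_block_count("ECB", 384, 512, conv)
                + 3 * analytic_block_count("ECB", 384, 384, conv)
                + analytic_block_count("LTB", 512, 384, conv))
    assert count_parameters(tiny) - count_parameters(micro) == expected


def test_parameter_monotonicity_and_reporting():
    micro = build_medvit("micro", seed=0)
    tiny = build_medvit("tiny", seed=0)
    assert count_parameters(tiny) > count_parameters(micro)
    assert parameters_millions(micro) == pytest.approx(24.50)
    assert parameters_millions(tiny) == pytest.approx(31.14)


def test_malformed_spec_raises_descriptive_error():
    spec = micro_spec()
    spec.stages = spec.stages[:3]
    with pytest.raises(ConfigurationError, match="4 stages"):
        build_medvit(spec)
    spec2 = reduced_spec()
    spec2.conventions.head_dim = 5
    with pytest.raises(ConfigurationError, match="divisible"):
        build_medvit(spec2)
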
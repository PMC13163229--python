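"""Channel-spatial attention block: examples, oracles and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsanet.attention import (
    ChannelSpatialAttention,
    CsaParams,
    apply_csa,
    channel_attention,
    csa_parameter_count,
    spatial_attention,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _oracle_channel_attention(f, w1, b1, w2, b2):
    """Independent reference: explicit pooling + dense arithmetic."""
    c = f.shape[2]
    gap = np.array([f[:, :, k].mean() for k in range(c)])
    gmp = np.array([f[:, :, k].max() for k in range(c)])

    def mlp(v):
        hidden = np.maximum(v @ w1 + b1, 0.0)
        return hidden @ w2 + b2

    return _sigmoid(mlp(gap) + mlp(gmp))


def _oracle_spatial_attention(f, kernel, bias):
    """Independent reference: explicit same-padded convolution loop."""
    h, w = f.shape[:2]
    pooled = np.stack([f.mean(axis=2), f.max(axis=2)], axis=2)
    k = kernel.shape[0]
    pad = (k - 1) // 2
    padded = np.pad(pooled, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            patch = padded[i : i + k, j : j + k, :]
            out[i, j] = (patch * kernel[:, :, :, 0]).sum() + bias
    return _sigmoid(out)[:, :, None]


# -- parameter accounting --------------------------------------------------


@pytest.mark.parametrize("c,r,k,expected", [(256, 8, 7, 16_771), (2, 2, 3, 26)])
def test_parameter_count_formula(c, r, k, expected):
    assert csa_parameter_count(c, r, k) == expected


@given(
    c_over_r=st.integers(1, 8),
    r=st.integers(1, 8),
    k=st.sampled_from([1, 3, 5, 7]),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_instantiated_block_matches_formula(c_over_r, r, k):
    c = c_over_r * r
    block = ChannelSpatialAttention("csa", c, r, k, rng=np.random.default_rng(0))
    assert block.param_count() == csa_parameter_count(c, r, k)


def test_indivisible_reduction_rejected():
    with pytest.raises(ValueError, match="divisible"):
        csa_parameter_count(10, 4, 3)


# -- channel attention -----------------------------------------------------


def test_zero_weights_give_half_everywhere():
    params = CsaParams.zeros(8, reduction_ratio=4, spatial_kernel=3)
    f = np.zeros((7, 7, 8))
    assert np.allclose(channel_attention(f, params), 0.5)
    assert np.allclose(spatial_attention(f, params), 0.5)


def test_constant_channels_double_mlp_response():
    # constant per-channel maps: GAP == GMP, so the output is sigmoid(2*MLP(s))
    rng = np.random.default_rng(1)
    c, r = 6, 2
    consts = rng.normal(size=c)
    f = np.broadcast_to(consts, (4, 5, c)).copy()
    params = CsaParams(c, r, 3, seed=3)
    layer = params._layer

    def mlp(v):
        hidden = np.maximum(v @ layer.w1.data + layer.b1.data, 0.0)
        return hidden @ layer.w2.data + layer.b2.data

    assert np.allclose(channel_attention(f, params), _sigmoid(2.0 * mlp(consts)))


def test_channel_attention_matches_hand_oracle():
    c, r = 4, 2
    w1 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0], [-1.0, 1.0]])
    b1 = np.array([0.5, -0.5])
    w2 = np.array([[1.0, -1.0, 0.5, 0.0], [0.0, 1.0, -0.5, 1.0]])
    b2 = np.array([0.1, 0.2, -0.1, 0.0])
    f = np.arange(16, dtype=float).reshape(2, 2, 4)
    params = CsaParams(c, r, 3, mlp_weights=(w1, b1, w2, b2))
    assert np.allclose(channel_attention(f, params), _oracle_channel_attention(f, w1, b1, w2, b2))


def test_channel_attention_spatial_permutation_invariant():
    rng = np.random.default_rng(2)
    f = rng.normal(size=(5, 4, 8))
    params = CsaParams(8, 4, 3, seed=0)
    flat = f.reshape(-1, 8)[rng.permutation(20)]
    assert np.allclose(channel_attention(f, params), channel_attention(flat.reshape(5, 4, 8), params))


def test_channel_mismatch_and_nonfinite_rejected():
    params = CsaParams(8, 4, 3)
    with pytest.raises(ValueError, match="channel mismatch"):
        channel_attention(np.zeros((3, 3, 4)), params)
    bad = np.zeros((3, 3, 8))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        apply_csa(bad, params)


# -- spatial attention -----------------------------------------------------


def test_spatial_attention_matches_hand_oracle():
    kernel = np.array(
        [
            [[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5]],
            [[0.5, -0.5], [2.0, 1.0], [0.0, 0.0]],
            [[-1.0, 1.0], [0.0, -1.0], [1.0, 1.0]],
        ]
    )[:, :, :, None]
    bias = 0.25
    f = np.arange(18, dtype=float).reshape(3, 3, 2)
    params = CsaParams(2, 2, 3, spatial_conv_weights=(kernel, np.array([bias])))
    got = spatial_attention(f, params)
    assert got.shape == (3, 3, 1)
    assert np.allclose(got, _oracle_spatial_attention(f, kernel, bias))


def test_hot_pixel_peak_colocated_with_1x1_kernel():
    f = np.zeros((6, 6, 2))
    f[2, 4, :] = 10.0
    params = CsaParams(2, 2, 1, spatial_conv_weights=(np.ones((1, 1, 2, 1)), np.zeros(1)))
    sa = spatial_attention(f, params)[:, :, 0]
    assert np.unravel_index(sa.argmax(), sa.shape) == (2, 4)


def test_oversized_kernel_warns_but_computes():
    params = CsaParams(2, 2, 7)
    with pytest.warns(UserWarning, match="same padding"):
        out = spatial_attention(np.zeros((2, 2, 2)), params)
    assert out.shape == (2, 2, 1)


# -- joint application -----------------------------------------------------


def test_apply_csa_zero_input_stays_zero():
    params = CsaParams(8, 4, 3, seed=5)
    assert np.allclose(apply_csa(np.zeros((4, 4, 8)), params), 0.0)


def test_apply_csa_identity_limit():
    # pre-sigmoid -> +inf makes both attentions -> 1, so Fout -> Fin
    c = 4
    big = 1e4
    params = CsaParams(
        c,
        2,
        1,
        mlp_weights=(np.zeros((c, 2)), np.zeros(2), np.zeros((2, c)), np.full(c, big)),
        spatial_conv_weights=(np.zeros((1, 1, 2, 1)), np.array([big])),
    )
    f = np.linspace(-2, 2, 3 * 3 * c).reshape(3, 3, c)
    assert np.allclose(apply_csa(f, params), f, atol=1e-10)


def test_apply_csa_half_half_quarter():
    params = CsaParams.zeros(8, 4, 3)
    f = np.ones((5, 5, 8))
    assert np.allclose(apply_csa(f, params), 0.25)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_attention_ranges_and_damping(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(scale=3.0, size=(4, 6, 8))
    params = CsaParams(8, 4, 3, seed=seed % 1000)
    ca = channel_attention(f, params)
    sa = spatial_attention(f, params)
    out = apply_csa(f, params)
    assert np.all((ca > 0) & (ca < 1))
    assert np.all((sa > 0) & (sa < 1))
    assert out.shape == f.shape
    assert np.all(np.abs(out) <= np.abs(f) + 1e-12)
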
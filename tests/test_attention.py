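"""Attention mechanisms: normalisation, shape contracts, parameter budget,
hand-checked scaled-dot attention, and the channel-gate baselines."""

import numpy as np
import pytest

from crtnn.attention import (
    CSAM,
    ECANet,
    MHSA,
    SENet,
    eca_kernel_size,
    make_channel_attention,
    scaled_dot_attention,
)
from crtnn.autodiff import Tensor


RNG = np.random.default_rng(3)


class TestScaledDotAttention:
    def test_identical_keys_average_the_values(self):
        q = RNG.normal(size=(3, 4))
        k = np.tile(RNG.normal(size=(1, 4)), (5, 1))
        v = RNG.normal(size=(5, 4))
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data, np.tile(v.mean(0), (3, 1)), atol=1e-6)

    def test_sequence_length_one_returns_values(self):
        q = RNG.normal(size=(2, 1, 4))
        v = RNG.normal(size=(2, 1, 4))
        out = scaled_dot_attention(q, q, v)
        np.testing.assert_allclose(out.data, v, atol=1e-7)

    def test_two_by_two_integer_case_matches_hand_computation(self):
        """Direct evaluation of softmax(q k^T / sqrt(d_k)) v on integers."""
        q = np.array([[1.0], [2.0]])
        k = np.array([[1.0], [3.0]])
        v = np.array([[10.0], [20.0]])
        scores = q @ k.T / 1.0  # d_k = 1
        weights = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        expected = weights @ v
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data, expected, rtol=1e-7)

    def test_attention_rows_sum_to_one_via_constant_values(self):
        q, k = RNG.normal(size=(6, 8)), RNG.normal(size=(5, 8))
        out = scaled_dot_attention(q, k, np.ones((5, 1)))
        np.testing.assert_allclose(out.data, 1.0, atol=1e-6)

    def test_masked_positions_are_ignored(self):
        q = RNG.normal(size=(2, 4))
        k = RNG.normal(size=(3, 4))
        v = RNG.normal(size=(3, 4))
        mask = np.array([[True, True, False]] * 2)
        out = scaled_dot_attention(q, k, v, mask)
        ref = scaled_dot_attention(q, k[:2], v[:2])
        np.testing.assert_allclose(out.data, ref.data, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))


class TestMHSA:
    def test_head_dim_and_shape_preservation(self):
        mhsa = MHSA(64, 8, np.random.default_rng(0))
        assert mhsa.d_k == 8
        mhsa.eval()
        x = Tensor(RNG.normal(size=(128, 3, 64)).astype(np.float32))
        assert mhsa(x).shape == (128, 3, 64)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MHSA(62, 8, np.random.default_rng(0))

    def test_eval_mode_is_dropout_free(self):
        mhsa = MHSA(16, 4, np.random.default_rng(0), dropout=0.5)
        mhsa.eval()
        x = Tensor(RNG.normal(size=(2, 5, 16)))
        np.testing.assert_array_equal(mhsa(x).data, mhsa(x).data)

    def test_single_head_identity_projections_reduce_to_scaled_dot(self):
        mhsa = MHSA(6, 1, np.random.default_rng(0), dropout=0.0)
        eye = np.eye(6, dtype=np.float32)
        for lin in (mhsa.w_q, mhsa.w_k, mhsa.w_v, mhsa.w_o):
            lin.weight.data = eye.copy()
            lin.bias.data = np.zeros(6, dtype=np.float32)
        mhsa.eval()
        x = RNG.normal(size=(2, 4, 6)).astype(np.float32)
        ref = scaled_dot_attention(x, x, x)
        np.testing.assert_allclose(mhsa(Tensor(x)).data, ref.data, atol=1e-5)


class TestCSAM:
    def test_weights_sum_to_one_over_channels(self):
        csam = CSAM(32, np.random.default_rng(1))
        x = Tensor(RNG.normal(size=(4, 3, 32, 128)).astype(np.float32))
        _, w = csam(x)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_output_shape_matches_input_at_batch_128(self):
        csam = CSAM(32, np.random.default_rng(1))
        x = Tensor(RNG.normal(size=(128, 3, 32, 128)).astype(np.float32))
        out, w = csam(x)
        assert out.shape == (128, 3, 32, 128)
        assert w.shape == (128, 3, 32)

    def test_zero_weight_zeroes_the_channel(self):
        """Multiplicative gating: a zeroed weight silences its channel."""
        x = Tensor(RNG.normal(size=(2, 3, 4, 8)))
        w = np.full((2, 3, 4), 0.25)
        w[:, :, 1] = 0.0
        out = x * Tensor(w).reshape(2, 3, 4, 1)
        assert not out.data[:, :, 1, :].any()
        assert out.data[:, :, 0, :].any()

    def test_parameter_budget_is_16544(self):
        assert CSAM(32, np.random.default_rng(0)).n_params() == 16544

    def test_bias_free_linear_up_drops_64_parameters(self):
        csam = CSAM(32, np.random.default_rng(0))
        csam.linear_up.bias = None
        assert csam.n_params() == 16544 - 64

    def test_seed_layout_generalisation(self):
        csam = CSAM(62, np.random.default_rng(0))
        x = Tensor(RNG.normal(size=(2, 3, 62, 128)).astype(np.float32))
        out, w = csam(x)
        assert out.shape == (2, 3, 62, 128)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_channel_mismatch_rejected(self):
        csam = CSAM(32, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            csam(Tensor(np.zeros((1, 3, 16, 128))))

    def test_softmax_only_gate_differs_from_default(self):
        x = Tensor(RNG.normal(size=(2, 3, 32, 128)).astype(np.float32))
        rng_state = np.random.default_rng(2)
        a = CSAM(32, np.random.default_rng(2), gate="sigmoid_softmax")
        b = CSAM(32, np.random.default_rng(2), gate="softmax_only")
        assert not np.allclose(a.channel_weights(x).data, b.channel_weights(x).data)

    def test_permutation_tied_weights_are_equivariant(self):
        """With permutation-symmetric linear maps and an identity-kernel
        convolution, permuting input channels permutes the weights."""
        csam = CSAM(4, np.random.default_rng(0))
        C, H = 4, 8
        up = np.zeros((H, C), dtype=np.float32)
        up[:C] = np.eye(C)
        up[C:] = np.eye(C)
        csam.linear_up.weight.data = up
        csam.linear_up.bias.data = np.zeros(H, dtype=np.float32)
        kernel = np.zeros((H, H, 3), dtype=np.float32)
        kernel[np.arange(H), np.arange(H), 1] = 1.0  # identity convolution
        csam.conv.weight.data = kernel
        csam.conv.bias.data = np.zeros(H, dtype=np.float32)
        down = np.concatenate([np.eye(C), np.eye(C)], axis=1).astype(np.float32) / 2
        csam.linear_down.weight.data = down
        csam.linear_down.bias.data = np.zeros(C, dtype=np.float32)
        x = RNG.normal(size=(2, 3, C, 16)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        w = csam.channel_weights(Tensor(x)).data
        w_perm = csam.channel_weights(Tensor(x[:, :, perm, :])).data
        np.testing.assert_allclose(w_perm, w[:, :, perm], atol=1e-6)


class TestChannelGateBaselines:
    def test_senet_saturated_gate_approaches_identity(self):
        se = SENet(8, np.random.default_rng(0))
        se.fc2.weight.data[:] = 0.0
        se.fc2.bias.data[:] = 30.0  # sigmoid saturates at 1
        x = Tensor(RNG.normal(size=(2, 3, 8, 16)).astype(np.float32))
        out, w = se(x)
        np.testing.assert_allclose(out.data, x.data, rtol=1e-5)

    @pytest.mark.parametrize("channels,expected", [(32, 3), (64, 3), (256, 5)])
    def test_eca_adaptive_kernel_rule(self, channels, expected):
        assert eca_kernel_size(channels) == expected

    @pytest.mark.parametrize("kind", ["csam", "senet", "ecanet"])
    def test_shared_shape_contract(self, kind):
        mech = make_channel_attention(kind, 32, np.random.default_rng(0))
        x = Tensor(RNG.normal(size=(2, 3, 32, 64)).astype(np.float32))
        out, w = mech(x)
        assert out.shape == x.shape
        assert w.shape == (2, 3, 32)

    def test_factory_none_and_unknown(self):
        assert make_channel_attention("none", 32, np.random.default_rng(0)) is None
        with pytest.raises(ValueError, match="unknown"):
            make_channel_attention("cbam", 32, np.random.default_rng(0))
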
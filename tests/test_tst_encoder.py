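import numpy as np
import pytest

from ehrfusion import nn
from ehrfusion.ehr_data import TemporalFeatures
from ehrfusion.tst_encoder import (
    Scaler,
    TSTConfig,
    TSTEncoder,
    apply_scaler,
    encode_sequence,
    feed_forward,
    fit_scaler,
    project_and_position,
    self_attention,
)


def _features(rows, mask=None):
    rows = np.asarray(rows, dtype=float)
    mask = np.ones(len(rows), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return TemporalFeatures(matrix=rows, mask=mask)


class TestScaler:
    def test_min_max_over_values(self):
        feats = [_features([[0.0, 1.0], [50.0, 2.0], [100.0, 0.5]])]
        s = fit_scaler(feats)
        np.testing.assert_array_equal(s.min, [0.0, 0.5])
        np.testing.assert_array_equal(s.max, [100.0, 2.0])

    def test_padding_rows_excluded(self):
        feats = [_features([[5.0, 5.0], [0.0, 0.0]], mask=[True, False])]
        s = fit_scaler(feats)
        np.testing.assert_array_equal(s.min, [5.0, 5.0])
        np.testing.assert_array_equal(s.max, [5.0, 5.0])
        assert s.constant_features.all()

    def test_brute_force_enumeration(self, rng):
        feats = [
            _features(rng.uniform(0, 100, size=(4, 2)), mask=rng.random(4) < 0.8)
            for _ in range(10)
        ]
        feats = [f for f in feats if f.mask.any()]
        s = fit_scaler(feats)
        all_rows = np.concatenate([f.matrix[f.mask] for f in feats])
        np.testing.assert_allclose(s.min, all_rows.min(axis=0))
        np.testing.assert_allclose(s.max, all_rows.max(axis=0))

    def test_no_valid_rows_raises(self):
        with pytest.raises(ValueError, match="no valid rows"):
            fit_scaler([_features([[1.0, 1.0]], mask=[False])])

    def test_apply_endpoints_midpoint_clipping_constants(self):
        s = Scaler(min=np.array([0.0, 3.0]), max=np.array([100.0, 3.0]))
        f = _features([[0.0, 3.0], [50.0, 3.0], [100.0, 3.0], [120.0, 3.0]])
        out = apply_scaler(f, s)
        np.testing.assert_array_equal(out.matrix[:, 0], [0.0, 0.5, 1.0, 1.0])
        np.testing.assert_array_equal(out.matrix[:, 1], [0.0, 0.0, 0.0, 0.0])

    def test_padding_rows_stay_zero(self):
        s = Scaler(min=np.array([0.0, 0.0]), max=np.array([10.0, 10.0]))
        out = apply_scaler(_features([[5.0, 5.0], [7.0, 7.0]], mask=[True, False]), s)
        np.testing.assert_array_equal(out.matrix[1], [0.0, 0.0])


class TestBuildingBlocks:
    def test_projection_zero_weights_give_pure_positional_encoding(self):
        f = _features([[0.3, 0.4], [0.5, 0.6]])
        out = project_and_position(f, np.zeros((6, 2)), np.zeros(6))
        np.testing.assert_allclose(out, nn.sinusoidal_positions(2, 6))
        # position 0: even channels sin(0)=0, odd channels cos(0)=1
        np.testing.assert_array_equal(out[0, 0::2], [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(out[0, 1::2], [1.0, 1.0, 1.0])

    def test_identical_features_at_different_positions_differ(self):
        f = _features([[0.5, 0.5], [0.5, 0.5]])
        rng = np.random.default_rng(0)
        out = project_and_position(f, rng.normal(size=(8, 2)), np.zeros(8))
        assert not np.allclose(out[0], out[1])

    def test_attention_uniform_over_identical_keys(self):
        Q = np.ones((3, 2))
        K = np.ones((3, 2))
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ctx, attn = self_attention(Q, K, V)
        np.testing.assert_allclose(attn, np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(ctx, np.tile(V.mean(axis=0), (3, 1)))

    def test_attention_hand_softmax(self):
        Q = np.array([[1.0], [0.0]])
        K = np.array([[1.0], [0.0]])
        V = np.array([[1.0], [0.0]])
        ctx, attn = self_attention(Q, K, V)
        np.testing.assert_allclose(attn[0], [0.73105858, 0.26894142], atol=1e-6)
        np.testing.assert_allclose(ctx[0, 0], 0.73105858, atol=1e-6)

    def test_attention_rows_sum_to_one_over_valid_keys(self, rng):
        Q, K, V = rng.normal(size=(3, 4, 2))
        mask = np.array([True, True, False, True])
        _, attn = self_attention(Q, K, V, mask)
        np.testing.assert_allclose(attn.sum(axis=-1), np.ones(4), atol=1e-9)
        assert np.all(attn[:, 2] == 0.0)

    def test_masking_equals_shorter_sequence(self, rng):
        Q, K, V = rng.normal(size=(3, 2, 4))
        ctx_masked, _ = self_attention(Q, K, V, np.array([True, False]))
        ctx_short, _ = self_attention(Q, K[:1], V[:1])
        np.testing.assert_allclose(ctx_masked, ctx_short, atol=1e-12)

    def test_fully_masked_keys_give_zero_context(self, rng):
        Q, K, V = rng.normal(size=(3, 2, 4))
        ctx, attn = self_attention(Q, K, V, np.array([False, False]))
        np.testing.assert_array_equal(ctx, np.zeros_like(ctx))
        np.testing.assert_array_equal(attn, np.zeros_like(attn))

    def test_ffn_zero_params_give_zero(self):
        out = feed_forward(np.ones((2, 3)), np.zeros((3, 4)), np.zeros(4),
                           np.zeros((4, 3)), np.zeros(3), "relu")
        np.testing.assert_array_equal(out, np.zeros((2, 3)))

    def test_ffn_dead_relu_unit_returns_output_bias(self):
        b2 = np.array([7.0])
        out = feed_forward(np.array([[1.0]]), np.array([[-1.0]]), np.zeros(1),
                           np.array([[5.0]]), b2, "relu")
        np.testing.assert_array_equal(out, [[7.0]])

    def test_gelu_vs_relu_gap_matches_closed_form(self):
        x = np.array([[2.0]])
        w1, b1 = np.array([[1.0]]), np.zeros(1)
        w2, b2 = np.array([[1.0]]), np.zeros(1)
        gelu_out = feed_forward(x, w1, b1, w2, b2, "gelu")[0, 0]
        relu_out = feed_forward(x, w1, b1, w2, b2, "relu")[0, 0]
        expected_gap = float(nn.gelu_scalar(2.0) - 2.0)
        np.testing.assert_allclose(gelu_out - relu_out, expected_gap, atol=1e-12)


class TestEncoder:
    def _encoder(self, norm="layer", **kw):
        config = TSTConfig(d_model=8, n_heads=1, n_layers=1, d_ffn=16, dropout=0.0,
                           max_len=6, norm=norm, **kw)
        return TSTEncoder(config, np.random.default_rng(42)), config

    def test_eval_determinism(self):
        enc, _ = self._encoder()
        scaler = Scaler(min=np.zeros(2), max=np.ones(2) * 100)
        f = _features([[10.0, 0.0], [20.0, 30.0]], mask=[True, True])
        np.testing.assert_array_equal(
            encode_sequence(f, scaler, enc), encode_sequence(f, scaler, enc)
        )

    @pytest.mark.parametrize("norm,atol", [("layer", 0.0), ("batch", 1e-6)])
    def test_padding_invariance(self, norm, atol):
        enc, _ = self._encoder(norm=norm)
        scaler = Scaler(min=np.zeros(2), max=np.ones(2) * 100)
        short = _features([[10.0, 0.0], [20.0, 30.0]])
        padded = _features(
            np.vstack([short.matrix, np.zeros((3, 2))]),
            mask=[True, True, False, False, False],
        )
        a = encode_sequence(short, scaler, enc)
        b = encode_sequence(padded, scaler, enc)
        if atol == 0.0:
            np.testing.assert_array_equal(a, b)
        else:
            np.testing.assert_allclose(a, b, atol=atol)

    def test_permutation_sensitivity(self, rng):
        enc, _ = self._encoder()
        scaler = Scaler(min=np.zeros(2), max=np.ones(2) * 100)
        rows = rng.uniform(0, 100, size=(4, 2))
        a = encode_sequence(_features(rows), scaler, enc)
        b = encode_sequence(_features(rows[::-1].copy()), scaler, enc)
        assert not np.allclose(a, b)

    def test_too_long_sequence_rejected(self):
        enc, config = self._encoder()
        scaler = Scaler(min=np.zeros(2), max=np.ones(2))
        f = _features(np.zeros((config.max_len + 1, 2)))
        with pytest.raises(ValueError, match="truncate"):
            encode_sequence(f, scaler, enc)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            TSTConfig(d_model=10, n_heads=4)
        with pytest.raises(ValueError, match="dropout"):
            TSTConfig(dropout=1.5)
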
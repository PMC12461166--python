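"""Missing-data encoders: sentinel substitution, masking, reweighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longicog.encoders import (
    LinearAttentionEncoder,
    TransformerImputationEncoder,
    embed_features,
    encode_baseline_linear,
    linear_attention_reweight,
    masked_attention_encode,
    reweight_with_scores,
)
from longicog.nn import count_parameters

K, H = 8, 16


@pytest.fixture()
def transformer():
    return TransformerImputationEncoder(K, H, np.random.default_rng(1))


@pytest.fixture()
def linear():
    return LinearAttentionEncoder(K, H, np.random.default_rng(1))


def _random_input(rng, k=K):
    mask = (rng.random(k) > 0.4).astype(float)
    values = np.where(mask > 0, rng.lognormal(0.5, 0.4, size=k), np.nan)
    return values, mask


class TestEmbedding:
    def test_shape_contract(self, transformer, rng):
        values, mask = _random_input(rng)
        assert embed_features(values, mask, transformer).shape == (K, H)

    def test_missing_cell_embeds_sentinel(self, transformer):
        values = np.array([2.0] + [np.nan] * (K - 1))
        mask = np.array([1.0] + [0.0] * (K - 1))
        emb = embed_features(values, mask, transformer)
        sentinel_emb = embed_features(np.full(K, -1.0), np.ones(K), transformer)
        np.testing.assert_array_equal(emb[1:], sentinel_emb[1:])

    def test_nonfinite_observed_value_rejected(self, transformer):
        values = np.array([np.inf] * K)
        with pytest.raises(ValueError, match="non-finite"):
            embed_features(values, np.ones(K), transformer)


class TestMaskedAttention:
    def test_single_observed_feature_dominates(self, transformer):
        """With one observed feature the softmax over keys is degenerate, so
        the output depends on that feature alone."""
        mask = np.zeros(K)
        mask[0] = 1.0
        a = np.full(K, np.nan)
        a[0] = 2.0
        b = a.copy()
        out_a = masked_attention_encode(a, mask, transformer)
        b_changed = np.nan_to_num(b, nan=123.0)  # junk in masked cells
        out_b = masked_attention_encode(b_changed, mask, transformer)
        np.testing.assert_array_equal(out_a, out_b)

    def test_masked_value_perturbation_is_invisible(self, transformer, rng):
        values, mask = _random_input(rng)
        junk = values.copy()
        junk[mask == 0] = rng.normal(size=int((mask == 0).sum())) * 50
        out1 = masked_attention_encode(np.nan_to_num(values, nan=0.0), mask,
                                       transformer)
        out2 = masked_attention_encode(junk, mask, transformer)
        np.testing.assert_array_equal(out1, out2)

    def test_all_missing_yields_zero_vector(self, transformer):
        out = masked_attention_encode(np.full(K, np.nan), np.zeros(K), transformer)
        np.testing.assert_array_equal(out, np.zeros(H))


class TestLinearAttention:
    def test_uniform_scores_give_uniform_weights(self):
        reweighted, w = reweight_with_scores([1.0, 2.0, 3.0, 4.0],
                                             [5.0, 5.0, 5.0, 5.0])
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_allclose(reweighted, [0.25, 0.5, 0.75, 1.0])

    def test_hand_computed_reweighting(self):
        reweighted, w = reweight_with_scores([2.0, 4.0], [3.0, 1.0])
        np.testing.assert_allclose(w, [0.75, 0.25])
        np.testing.assert_allclose(reweighted, [1.5, 1.0])

    def test_single_feature_identity(self):
        enc = LinearAttentionEncoder(1, 4, np.random.default_rng(0))
        values, mask = np.array([3.0]), np.array([1.0])
        reweighted, w = linear_attention_reweight(values, mask, enc)
        assert w[0] == pytest.approx(1.0)
        assert reweighted[0] == pytest.approx(3.0)

    def test_weights_sum_to_one(self, linear, rng):
        for _ in range(20):
            values, mask = _random_input(rng)
            _, w = linear_attention_reweight(values, mask, linear)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)
            assert (w > 0).all()

    def test_missing_invariance_via_sentinel(self, linear, rng):
        values, mask = _random_input(rng)
        junk = values.copy()
        junk[mask == 0] = 999.0
        out1 = encode_baseline_linear(np.nan_to_num(values, nan=-7.0), mask, linear)
        out2 = encode_baseline_linear(junk, mask, linear)
        np.testing.assert_array_equal(out1, out2)

    def test_permutation_consistency(self, linear, rng):
        values, mask = _random_input(rng)
        values = np.nan_to_num(values, nan=0.0)
        perm = rng.permutation(K)
        _, w = linear_attention_reweight(values, mask, linear)
        _, w_perm = linear_attention_reweight(values[perm], mask[perm], linear)
        np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_weight_normalization_property(seed):
    """Linear-attention weights form a probability vector for any input."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 12))
    enc = LinearAttentionEncoder(k, 8, np.random.default_rng(3))
    mask = (rng.random(k) > 0.5).astype(float)
    values = np.where(mask > 0, rng.lognormal(0, 1, size=k), np.nan)
    _, w = linear_attention_reweight(values, mask, enc)
    assert abs(w.sum() - 1.0) < 1e-6
    assert (w > 0).all()


def test_linear_encoder_has_fewer_parameters_at_equal_hidden():
    h = 64
    t = TransformerImputationEncoder(K, h, np.random.default_rng(0))
    l = LinearAttentionEncoder(K, h, np.random.default_rng(0))
    assert count_parameters(l) < count_parameters(t)
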
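"""Network building blocks vs brute-force loop oracles; checkpointing."""

import numpy as np
import pytest

from pmms.model import (
    ModelConfig,
    bilstm_encode,
    embed_tokens,
    encode_tokens,
    forward,
    forward_batch,
    init_parameters,
    kmer_vocab,
    load_checkpoint,
    loss,
    mlp_forward,
    multi_head,
    predict_proba,
    save_checkpoint,
    scaled_dot_attention,
    weight_attention,
)
from pmms.seq_io import tokenize_kmers
from pmms.static_features import STATIC_DIM


# --- independent loop transcriptions used as oracles -----------------------


def sdpa_naive(Q, K, V):
    L, d_k = Q.shape
    out = np.zeros((L, V.shape[1]))
    for i in range(L):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(L)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for j in range(L):
            out[i] += w[j] * V[j]
    return out


def multi_head_naive(F_B, params):
    t = {n: x.data for n, x in params.tensors.items()}
    heads = []
    for i in range(params.config.h):
        heads.append(sdpa_naive(F_B @ t["W_q"][i], F_B @ t["W_k"][i], F_B @ t["W_v"][i]))
    return np.concatenate(heads, axis=-1) @ t["W_o_attn"]


def weight_attention_naive(F_s, F_M, params):
    t = {n: x.data for n, x in params.tensors.items()}
    h_m = np.maximum(F_s @ t["W_inter"] + t["b_inter"], 0)
    out = np.zeros(STATIC_DIM)
    for i in range(F_M.shape[0]):
        h_i = np.maximum(F_M[i] @ t["w_conv"] + t["b_conv"], 0)
        alpha = 1.0 / (1.0 + np.exp(-(h_m @ h_i)))
        out += alpha * h_i
    return out


def lstm_naive(E, Wx, Wh, b, H):
    """Step-by-step scalar-gate LSTM recurrence (single direction)."""

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    h = np.zeros(H)
    c = np.zeros(H)
    outs = []
    for x in E:
        gates = x @ Wx + h @ Wh + b
        i, f, g, o = gates[:H], gates[H : 2 * H], gates[2 * H : 3 * H], gates[3 * H :]
        c = sig(f) * c + sig(i) * np.tanh(g)
        h = sig(o) * np.tanh(c)
        outs.append(h)
    return np.array(outs)


# --- tests -----------------------------------------------------------------


class TestEmbedding:
    def test_shape_and_lookup_semantics(self, tiny_params):
        toks = tokenize_kmers("AUUAUUGCC", 3)  # AUU appears at positions 0 and 3
        E = embed_tokens(toks, tiny_params)
        assert E.shape == (7, tiny_params.config.d_b)
        assert np.array_equal(E[0], E[3])

    def test_row_change_is_local(self, tiny_config):
        params = init_parameters(tiny_config)
        toks = tokenize_kmers("AUUAUUGCC", 3)
        before = embed_tokens(toks, params)
        vid = params.vocab["AUU"]
        params.tensors["embedding"].data[vid] += 1.0
        after = embed_tokens(toks, params)
        changed = np.abs(after - before).sum(axis=1) > 0
        assert list(np.nonzero(changed)[0]) == [0, 3]

    def test_vocab_covers_all_kmers(self):
        assert len(kmer_vocab(3)) == 64
        assert len(set(kmer_vocab(4).values())) == 256


class TestBiLSTM:
    def test_output_shape(self, tiny_params, rng):
        E = rng.normal(size=(11, tiny_params.config.d_b))
        assert bilstm_encode(E, tiny_params).shape == (11, tiny_params.config.d_b)

    def test_zero_weights_give_zero_output(self, tiny_config, rng):
        params = init_parameters(tiny_config)
        for name in ("lstm_f_Wx", "lstm_f_Wh", "b_lstm_f", "lstm_b_Wx", "lstm_b_Wh", "b_lstm_b"):
            params.tensors[name].data[...] = 0.0
        E = rng.normal(size=(5, tiny_config.d_b))
        out = bilstm_encode(E, params)
        # zero gates: c stays 0, h = sigmoid(0)*tanh(0) = 0 at every step
        assert np.abs(out).max() == 0.0
        H = tiny_config.d_b
        ref = lstm_naive(E, np.zeros((H, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H), H)
        assert np.abs(ref).max() == 0.0

    def test_matches_scalar_recurrence_oracle(self, tiny_params, rng):
        H = tiny_params.config.d_b
        t = {n: x.data for n, x in tiny_params.tensors.items()}
        E = rng.normal(size=(6, H))
        fwd = lstm_naive(E, t["lstm_f_Wx"], t["lstm_f_Wh"], t["b_lstm_f"], H)
        bwd = lstm_naive(E[::-1], t["lstm_b_Wx"], t["lstm_b_Wh"], t["b_lstm_b"], H)[::-1]
        assert np.abs(bilstm_encode(E, tiny_params) - (fwd + bwd)).max() < 1e-12

    def test_single_position(self, tiny_params, rng):
        E = rng.normal(size=(1, tiny_params.config.d_b))
        out = bilstm_encode(E, tiny_params)
        assert out.shape == (1, tiny_params.config.d_b)


class TestAttention:
    def test_single_query_returns_value_row(self, rng):
        Q, K, V = rng.normal(size=(3, 1, 4))
        assert np.allclose(scaled_dot_attention(Q, K, V)[0], V[0])

    def test_identical_keys_give_uniform_weights(self, rng):
        L = 6
        K = np.tile(rng.normal(size=4), (L, 1))
        Q = rng.normal(size=(L, 4))
        V = rng.normal(size=(L, 4))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (L, 1)))

    def test_matches_naive_loops(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 6))
            Q = rng.normal(size=(L, 4))
            K = rng.normal(size=(L, 4))
            V = rng.normal(size=(L, 3))
            assert np.abs(scaled_dot_attention(Q, K, V) - sdpa_naive(Q, K, V)).max() < 1e-10

    def test_all_masked_rejected(self, rng):
        Q = K = V = rng.normal(size=(3, 4))
        with pytest.raises(ValueError):
            scaled_dot_attention(Q, K, V, mask=np.zeros(3))


class TestMultiHead:
    def test_output_width_is_static_dim(self, tiny_params, rng):
        for L in (1, 5, 17):
            F_B = rng.normal(size=(L, tiny_params.config.d_b))
            assert multi_head(F_B, tiny_params).shape == (L, STATIC_DIM)

    def test_single_head_reduces_to_sdpa(self, rng):
        cfg = ModelConfig(k=3, d_b=8, d_k=4, d_v=4, h=1, seed=5)
        params = init_parameters(cfg)
        t = {n: x.data for n, x in params.tensors.items()}
        F_B = rng.normal(size=(6, 8))
        direct = sdpa_naive(F_B @ t["W_q"][0], F_B @ t["W_k"][0], F_B @ t["W_v"][0]) @ t["W_o_attn"]
        assert np.abs(multi_head(F_B, params) - direct).max() < 1e-10

    def test_matches_naive_loops(self, tiny_params, rng):
        for _ in range(100):
            L = int(rng.integers(1, 6))
            F_B = rng.normal(size=(L, tiny_params.config.d_b))
            got = multi_head(F_B, tiny_params)
            assert np.abs(got - multi_head_naive(F_B, tiny_params)).max() < 1e-10


class TestWeightAttention:
    def test_zero_affinity_gives_half_weights(self, tiny_config, rng):
        params = init_parameters(tiny_config)
        params.tensors["W_inter"].data[...] = 0.0
        params.tensors["b_inter"].data[...] = 0.0  # h_m = ReLU(0) = 0
        F_M = rng.normal(size=(7, STATIC_DIM))
        F_s = rng.normal(size=STATIC_DIM)
        got = weight_attention(F_s, F_M, params)
        t = {n: x.data for n, x in params.tensors.items()}
        h_i = np.maximum(F_M @ t["w_conv"] + t["b_conv"], 0)
        assert np.allclose(got, 0.5 * h_i.sum(axis=0))

    def test_single_position(self, tiny_params, rng):
        F_M = rng.normal(size=(1, STATIC_DIM))
        F_s = rng.normal(size=STATIC_DIM)
        got = weight_attention(F_s, F_M, tiny_params)
        assert np.allclose(got, weight_attention_naive(F_s, F_M, tiny_params))

    def test_matches_naive_loops(self, tiny_params, rng):
        for _ in range(100):
            L = int(rng.integers(1, 8))
            F_M = rng.normal(size=(L, STATIC_DIM))
            F_s = rng.normal(size=STATIC_DIM)
            got = weight_attention(F_s, F_M, tiny_params)
            assert np.abs(got - weight_attention_naive(F_s, F_M, tiny_params)).max() < 1e-10

    def test_empty_sequence_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            weight_attention(np.zeros(STATIC_DIM), np.zeros((0, STATIC_DIM)), tiny_params)


class TestMLPAndSoftmax:
    def test_zero_parameters_give_zero_logits(self, tiny_config):
        params = init_parameters(tiny_config)
        for n in params.tensors:
            if n.startswith(("mlp_", "b_mlp", "W_out", "b_out")):
                params.tensors[n].data[...] = 0.0
        z = mlp_forward(np.ones(tiny_config.d_f), params)
        assert np.array_equal(z, np.zeros(2))

    def test_matches_naive_loops(self, tiny_params, rng):
        t = {n: x.data for n, x in tiny_params.tensors.items()}
        x = rng.normal(size=tiny_params.config.d_f)
        h = x
        for i in range(len(tiny_params.config.mlp_hidden_dims)):
            h = np.maximum(
                np.array([h @ t[f"mlp_W{i}"][:, j] for j in range(t[f"mlp_W{i}"].shape[1])])
                + t[f"b_mlp{i}"],
                0,
            )
        z_ref = np.array([h @ t["W_out"][:, j] for j in range(2)]) + t["b_out"]
        assert np.abs(mlp_forward(x, tiny_params) - z_ref).max() < 1e-12

    def test_dimension_mismatch_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            mlp_forward(np.zeros(10), tiny_params)

    @pytest.mark.parametrize(
        "z,expected",
        [
            ((0.0, 0.0), (0.5, 0.5)),
            ((np.log(3), 0.0), (0.75, 0.25)),
            ((1000.0, 0.0), (1.0, 0.0)),
        ],
    )
    def test_predict_proba(self, z, expected):
        p = predict_proba(np.array(z))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p.sum() == pytest.approx(1.0)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        assert loss(np.array([[0.0, 1.0]]), np.array([1])) == 0.0

    def test_uniform_prediction_is_log_two(self):
        p = np.full((4, 2), 0.5)
        assert loss(p, np.array([0, 1, 0, 1])) == pytest.approx(np.log(2))

    def test_l2_monotone_in_lambda(self, tiny_params):
        p = np.full((2, 2), 0.5)
        y = np.array([0, 1])
        assert loss(p, y, tiny_params, lam=1e-2) > loss(p, y, tiny_params, lam=0.0)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            val = loss(np.array([[1.0, 0.0]]), np.array([1]))
        assert np.isfinite(val)


class TestForward:
    def test_probability_and_feature_contract(self, tiny_params, small_dataset, rng):
        rec = small_dataset[0]
        F_s = rng.normal(size=STATIC_DIM)
        F_f, p = forward(rec, F_s, tiny_params)
        assert F_f.shape == (tiny_params.config.d_f,)
        assert p.shape == (2,) and p.sum() == pytest.approx(1.0)
        # purity: identical inputs give identical outputs
        F_f2, p2 = forward(rec, F_s, tiny_params)
        assert np.array_equal(F_f, F_f2) and np.array_equal(p, p2)

    def test_padding_invariance(self, tiny_params, small_dataset, rng):
        recs = small_dataset[:2]
        toks = [tokenize_kmers(r.precursor, tiny_params.config.k) for r in recs]
        ids, mask = encode_tokens(toks, tiny_params)
        F_s = rng.normal(size=(2, STATIC_DIM))
        _, z1 = forward_batch(tiny_params, ids, mask, F_s)
        pad = np.full((2, 6), tiny_params.pad_id, dtype=np.int64)
        ids2 = np.concatenate([ids, pad], axis=1)
        mask2 = np.concatenate([mask, np.zeros((2, 6))], axis=1)
        _, z2 = forward_batch(tiny_params, ids2, mask2, F_s)
        assert np.abs(z1.data - z2.data).max() < 1e-9


class TestCheckpoint:
    def test_round_trip(self, tiny_params, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_params)
        back = load_checkpoint(path, expect_config=tiny_params.config)
        assert back.config == tiny_params.config
        assert back.vocab == tiny_params.vocab
        for n, t in tiny_params.tensors.items():
            assert np.array_equal(back.tensors[n].data, t.data)

    def test_config_mismatch_fails_loudly(self, tiny_params, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_params)
        other = ModelConfig(k=4, d_b=8, d_k=4, d_v=4, h=2, seed=7)
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(path, expect_config=other)

    def test_d_output_must_match_static_dim(self):
        with pytest.raises(ValueError, match="static feature dimension"):
            ModelConfig(d_output=40)
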
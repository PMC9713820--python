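"""The essentiality classifier network.

Architecture (per precursor sequence):

1. overlapping k-mer tokens (stride 1) → learned token embeddings, width d_b;
2. BiLSTM over the token sequence; the per-position output F_B is the
   element-wise sum of the forward and backward hidden states (width d_b);
3. multi-head scaled dot-product self-attention over F_B (h heads, widths
   d_k/d_v), heads concatenated and projected to width d_output = 38,
   giving the attention feature F_M;
4. weight-attention fusion with the standardized 38-dim static feature F_s:
   h_m = ReLU(W_inter·F_s + b_inter), h_i = ReLU(w_conv·F_M_i + b_conv),
   α_i = sigmoid(h_mᵀ h_i), and F_W = Σ_i α_i·h_i over unmasked positions;
5. F_f = concat(F_s, F_W) (width 76) → MLP (ReLU hidden layers) → 2 logits
   → softmax probability of essentiality.

Training minimizes mean cross-entropy plus an L2 penalty (λ/2)·Σ‖W‖² over
weight matrices (biases excluded), with Adam.

The computation is expressed on :class:`pmms.autodiff.Tensor`, so a single
forward definition serves prediction, training and the finite-difference
gradient checks.  The public functions below accept/return plain NumPy
arrays for single sequences; batched tensor-level variants (suffix ``_t``)
operate on padded batches with masks.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, softmax, stack
from .seq_io import PreMiRNARecord, TokenSequence, tokenize_kmers
from .static_features import STATIC_DIM

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "kmer_vocab",
    "init_parameters",
    "embed_tokens",
    "bilstm_encode",
    "scaled_dot_attention",
    "multi_head",
    "weight_attention",
    "mlp_forward",
    "predict_proba",
    "loss",
    "forward",
    "forward_batch",
    "batch_loss_t",
    "encode_tokens",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults follow the published configuration."""

    k: int = 4
    d_b: int = 128
    d_k: int = 64
    d_v: int = 64
    h: int = 4
    d_output: int = STATIC_DIM
    mlp_hidden_dims: tuple[int, ...] = (76,)
    lambda_l2: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.d_output != STATIC_DIM:
            # the weight-attention inner product h_mᵀh_i requires the attention
            # output width to equal the static feature width
            raise ValueError(
                f"d_output must equal the static feature dimension {STATIC_DIM}"
            )
        for name in ("k", "d_b", "d_k", "d_v", "h"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "mlp_hidden_dims", tuple(self.mlp_hidden_dims))

    @classmethod
    def compact(cls, seed: int = 0) -> "ModelConfig":
        """Compact configuration for desk-scale experiments.

        A narrower encoder (d_b=16, d_k=d_v=8), larger batches, a short
        schedule and stronger L2 — sized so a full five-fold cross-validation
        on a few hundred records runs in minutes on one CPU while the small
        sample is regularized against overfitting (see docs/methods.md).
        """
        return cls(
            k=4,
            d_b=16,
            d_k=8,
            d_v=8,
            h=4,
            epochs=15,
            batch_size=32,
            learning_rate=3e-3,
            lambda_l2=5e-2,
            seed=seed,
        )

    @property
    def d_f(self) -> int:
        return STATIC_DIM + self.d_output

    @property
    def vocab_size(self) -> int:
        return 4**self.k

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden_dims"] = list(self.mlp_hidden_dims)
        return d


def kmer_vocab(k: int) -> dict[str, int]:
    """All 4^k k-mers over A,U,C,G in lexicographic order → token ids."""
    return {
        "".join(t): i
        for i, t in enumerate(itertools.product("ACGU", repeat=k))
    }


@dataclass
class ModelParameters:
    """All learned tensors, the vocabulary and the config they belong to."""

    config: ModelConfig
    tensors: dict[str, Tensor]
    vocab: dict[str, int]
    loss_history: list[float] = field(default_factory=list)

    @property
    def pad_id(self) -> int:
        return len(self.vocab)

    def weight_names(self) -> list[str]:
        return [n for n in self.tensors if not n.startswith("b_")]

    def trainable(self) -> list[tuple[str, Tensor]]:
        return sorted(self.tensors.items())


def init_parameters(config: ModelConfig) -> ModelParameters:
    """Seeded random initialization (Glorot for projections, +1 forget bias)."""
    rng = np.random.default_rng(config.seed)
    H, D = config.d_b, config.d_b

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=shape)

    def lstm_bias():
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget gate open at init
        return b

    t: dict[str, np.ndarray] = {
        "embedding": rng.normal(0.0, 0.1, size=(config.vocab_size + 1, config.d_b)),
        "lstm_f_Wx": glorot(D, 4 * H),
        "lstm_f_Wh": glorot(H, 4 * H),
        "b_lstm_f": lstm_bias(),
        "lstm_b_Wx": glorot(D, 4 * H),
        "lstm_b_Wh": glorot(H, 4 * H),
        "b_lstm_b": lstm_bias(),
        "W_q": np.stack([glorot(config.d_b, config.d_k) for _ in range(config.h)]),
        "W_k": np.stack([glorot(config.d_b, config.d_k) for _ in range(config.h)]),
        "W_v": np.stack([glorot(config.d_b, config.d_v) for _ in range(config.h)]),
        "W_o_attn": glorot(config.h * config.d_v, config.d_output),
        # fusion branch starts near-quiet (scaled-down init): the classifier
        # can exploit the standardized static features immediately and grow
        # the learned-sequence contribution as training warrants it
        "W_inter": 0.3 * glorot(STATIC_DIM, STATIC_DIM),
        "b_inter": np.zeros(STATIC_DIM),
        "w_conv": 0.3 * glorot(config.d_output, STATIC_DIM),
        "b_conv": np.zeros(STATIC_DIM),
    }
    prev = config.d_f
    for i, width in enumerate(config.mlp_hidden_dims):
        t[f"mlp_W{i}"] = glorot(prev, width)
        t[f"b_mlp{i}"] = np.zeros(width)
        prev = width
    t["W_out"] = glorot(prev, 2)
    t["b_out"] = np.zeros(2)
    tensors = {n: Tensor(v, requires_grad=True, name=n) for n, v in t.items()}
    return ModelParameters(config=config, tensors=tensors, vocab=kmer_vocab(config.k))


# ---------------------------------------------------------------------------
# token encoding


def encode_tokens(
    token_seqs: Sequence[TokenSequence], params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Map token sequences to padded id and mask arrays (B, L_max)."""
    if not token_seqs:
        raise ValueError("empty batch")
    lengths = [len(ts) for ts in token_seqs]
    L = max(lengths)
    ids = np.full((len(token_seqs), L), params.pad_id, dtype=np.int64)
    mask = np.zeros((len(token_seqs), L))
    for b, ts in enumerate(token_seqs):
        for i, tok in enumerate(ts.tokens):
            if tok not in params.vocab:
                raise KeyError(f"token {tok!r} not in the {params.config.k}-mer vocabulary")
            ids[b, i] = params.vocab[tok]
        mask[b, : len(ts)] = 1.0
    return ids, mask


# ---------------------------------------------------------------------------
# tensor-level (batched) building blocks


def _lstm_run_t(E: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor, H: int) -> Tensor:
    """Unidirectional LSTM over (B, L, D) inputs; returns (B, L, H) states."""
    B, L, _ = E.shape
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    outs = []
    for t in range(L):
        x = E[(slice(None), t)]
        gates = x @ Wx + h @ Wh + b
        i = gates[(slice(None), slice(0, H))].sigmoid()
        f = gates[(slice(None), slice(H, 2 * H))].sigmoid()
        g = gates[(slice(None), slice(2 * H, 3 * H))].tanh()
        o = gates[(slice(None), slice(3 * H, 4 * H))].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs.append(h)
    return stack(outs, axis=1)


def _reverse_indices(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample index map reversing the real (unmasked) prefix in place."""
    B, L = mask.shape
    lengths = mask.sum(axis=1).astype(np.int64)
    t = np.arange(L)[None, :]
    rev = np.where(t < lengths[:, None], lengths[:, None] - 1 - t, t)
    bidx = np.repeat(np.arange(B)[:, None], L, axis=1)
    return bidx, rev


def bilstm_encode_t(E: Tensor, params: ModelParameters, mask: np.ndarray) -> Tensor:
    """BiLSTM feature F_B: element-wise sum of forward and backward passes."""
    H = params.config.d_b
    t = params.tensors
    fwd = _lstm_run_t(E, t["lstm_f_Wx"], t["lstm_f_Wh"], t["b_lstm_f"], H)
    bidx, rev = _reverse_indices(mask)
    E_rev = E[(bidx, rev)]
    bwd_rev = _lstm_run_t(E_rev, t["lstm_b_Wx"], t["lstm_b_Wh"], t["b_lstm_b"], H)
    bwd = bwd_rev[(bidx, rev)]  # the reversal map is an involution on the prefix
    return fwd + bwd


def scaled_dot_attention_t(Q: Tensor, K: Tensor, V: Tensor, mask: np.ndarray) -> Tensor:
    """softmax(QKᵀ/√d_k)V with masked keys receiving −∞ pre-softmax."""
    d_k = Q.shape[-1]
    if not mask.any(axis=-1).all():
        raise ValueError("a sequence with all positions masked has no attention target")
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    bias = (mask[..., None, :] - 1.0) * 1e9  # 0 for real keys, -1e9 for padding
    return softmax(scores + Tensor(bias), axis=-1) @ V


def multi_head_t(F_B: Tensor, params: ModelParameters, mask: np.ndarray) -> Tensor:
    """Self-attention (Q=K=V=F_B), h heads, concatenated, projected to d_output."""
    t = params.tensors
    heads = []
    for i in range(params.config.h):
        Q = F_B @ t["W_q"][i]
        K = F_B @ t["W_k"][i]
        V = F_B @ t["W_v"][i]
        heads.append(scaled_dot_attention_t(Q, K, V, mask))
    return concat(heads, axis=-1) @ t["W_o_attn"]


def weight_attention_t(
    F_s_std: Tensor, F_M: Tensor, params: ModelParameters, mask: np.ndarray
) -> Tensor:
    """Sigmoid-gated sum of attention features, gated by affinity to F_s."""
    t = params.tensors
    B = F_s_std.shape[0]
    h_m = (F_s_std @ t["W_inter"] + t["b_inter"]).relu()  # (B, 38)
    h_i = (F_M @ t["w_conv"] + t["b_conv"]).relu()  # (B, L, 38)
    alpha = (h_m.reshape(B, 1, -1) * h_i).sum(axis=-1).sigmoid()  # (B, L)
    gated = alpha.reshape(B, -1, 1) * h_i * Tensor(mask[:, :, None])
    return gated.sum(axis=1)  # (B, 38)


def mlp_forward_t(F_f: Tensor, params: ModelParameters) -> Tensor:
    t = params.tensors
    hcur = F_f
    for i in range(len(params.config.mlp_hidden_dims)):
        hcur = (hcur @ t[f"mlp_W{i}"] + t[f"b_mlp{i}"]).relu()
    return hcur @ t["W_out"] + t["b_out"]


def forward_batch(
    params: ModelParameters,
    token_ids: np.ndarray,
    mask: np.ndarray,
    F_s_std: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Padded-batch forward pass; returns (F_f (B, 76), logits z (B, 2))."""
    E = params.tensors["embedding"][token_ids]
    F_B = bilstm_encode_t(E, params, mask)
    F_M = multi_head_t(F_B, params, mask)
    Fs = Tensor(np.atleast_2d(F_s_std))
    F_W = weight_attention_t(Fs, F_M, params, mask)
    F_f = concat([Fs, F_W], axis=-1)
    z = mlp_forward_t(F_f, params)
    return F_f, z


def batch_loss_t(
    z: Tensor, labels: np.ndarray, params: ModelParameters, lam: float
) -> Tensor:
    """Mean cross-entropy from logits + (λ/2)·Σ‖W‖² (numerically stable)."""
    B = z.shape[0]
    shift = np.max(z.data, axis=-1, keepdims=True)
    zs = z - Tensor(shift)
    log_norm = zs.exp().sum(axis=-1, keepdims=True).log()
    logp = zs - log_norm
    onehot = np.zeros((B, 2))
    onehot[np.arange(B), labels] = 1.0
    ce = -(Tensor(onehot) * logp).sum() * (1.0 / B)
    if lam > 0:
        reg = None
        for name in params.weight_names():
            w = params.tensors[name]
            term = (w * w).sum()
            reg = term if reg is None else reg + term
        ce = ce + reg * (lam / 2.0)
    return ce


# ---------------------------------------------------------------------------
# public single-sequence NumPy surface


def embed_tokens(tokens: TokenSequence, params: ModelParameters) -> np.ndarray:
    """Look up the (L, d_b) embedding matrix for one token sequence."""
    ids, _ = encode_tokens([tokens], params)
    return params.tensors["embedding"].data[ids[0]]


def bilstm_encode(E: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Encode one (L, d_b) embedded sequence to its (L, d_b) BiLSTM feature."""
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2:
        raise ValueError("expected a single (L, d_b) matrix")
    mask = np.ones((1, E.shape[0]))
    return bilstm_encode_t(Tensor(E[None]), params, mask).data[0]


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if mask is None:
        mask = np.ones(K.shape[0])
    return scaled_dot_attention_t(
        Tensor(Q[None]), Tensor(K[None]), Tensor(V[None]), np.asarray(mask)[None]
    ).data[0]


def multi_head(
    F_B: np.ndarray, params: ModelParameters, mask: np.ndarray | None = None
) -> np.ndarray:
    F_B = np.asarray(F_B, dtype=np.float64)
    if mask is None:
        mask = np.ones(F_B.shape[0])
    return multi_head_t(Tensor(F_B[None]), params, np.asarray(mask)[None]).data[0]


def weight_attention(
    F_s_std: np.ndarray,
    F_M: np.ndarray,
    params: ModelParameters,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    F_M = np.asarray(F_M, dtype=np.float64)
    if F_M.shape[0] == 0:
        raise ValueError("weight attention needs at least one sequence position")
    if mask is None:
        mask = np.ones(F_M.shape[0])
    return weight_attention_t(
        Tensor(np.atleast_2d(F_s_std)), Tensor(F_M[None]), params, np.asarray(mask)[None]
    ).data[0]


def mlp_forward(F_f: np.ndarray, params: ModelParameters) -> np.ndarray:
    F_f = np.asarray(F_f, dtype=np.float64)
    if F_f.shape[-1] != params.config.d_f:
        raise ValueError(
            f"final feature must have dimension {params.config.d_f}, got {F_f.shape[-1]}"
        )
    return mlp_forward_t(Tensor(np.atleast_2d(F_f)), params).data[0]


def predict_proba(z: np.ndarray) -> np.ndarray:
    """Stable softmax over the 2 logits; rows sum to 1."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def loss(
    p: np.ndarray,
    y: np.ndarray,
    params: ModelParameters | None = None,
    lam: float = 0.0,
) -> float:
    """Mean cross-entropy of predicted probabilities + (λ/2)·Σ‖W‖².

    ``y`` may be one-hot (N, 2) or integer labels (N,).  A probability of
    exactly 0 at the true label is clamped at 1e-12 with a warning.  Training
    uses the logit-level :func:`batch_loss_t` instead; this is the
    probability-level definition for reporting and testing.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    if y.ndim == 1:
        onehot = np.zeros_like(p)
        onehot[np.arange(len(y)), y.astype(int)] = 1.0
    else:
        onehot = y.astype(np.float64)
    true_p = (p * onehot).sum(axis=-1)
    if (true_p <= 0).any():
        warnings.warn("probability 0 at the true label; clamping at 1e-12")
        true_p = np.clip(true_p, 1e-12, None)
    ce = float(-np.log(true_p).mean())
    if params is not None and lam > 0:
        ce += lam / 2.0 * sum(
            float((params.tensors[n].data ** 2).sum()) for n in params.weight_names()
        )
    return ce


def forward(
    record: PreMiRNARecord,
    F_s_std: np.ndarray,
    params: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline for one record: returns (F_f (76,), p (2,))."""
    toks = tokenize_kmers(record.precursor, params.config.k)
    ids, mask = encode_tokens([toks], params)
    F_f, z = forward_batch(params, ids, mask, np.atleast_2d(F_s_std))
    return F_f.data[0], predict_proba(z.data[0])


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path: str | Path, params: ModelParameters) -> None:
    """Write config + tensors + vocabulary to an .npz checkpoint."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": params.config.to_dict(),
        "vocab": params.vocab,
        "loss_history": params.loss_history,
    }
    arrays = {f"tensor__{n}": t.data for n, t in params.tensors.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, expect_config: ModelConfig | None = None) -> ModelParameters:
    """Load a checkpoint; fails loudly on version or config mismatch."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta['version']} != supported {CHECKPOINT_VERSION}"
            )
        config = ModelConfig(**{**meta["config"], "mlp_hidden_dims": tuple(meta["config"]["mlp_hidden_dims"])})
        if expect_config is not None and config != expect_config:
            raise ValueError("checkpoint config does not match the expected config")
        tensors = {
            n[len("tensor__"):]: Tensor(data[n], requires_grad=True, name=n[len("tensor__"):])
            for n in data.files
            if n.startswith("tensor__")
        }
    return ModelParameters(
        config=config,
        tensors=tensors,
        vocab={k: int(v) for k, v in meta["vocab"].items()},
        loss_history=list(meta.get("loss_history", [])),
    )
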
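"""Missing-data feature encoders for the baseline view.

Raw coding is strictly positive, so a negative sentinel (-1) makes
missingness linearly separable in input space.  Both encoders substitute the
sentinel for missing cells *before* any computation touches the stored
value, which is what makes their outputs exactly invariant to whatever a
masked cell happens to contain.

Two arms are provided, selected by the ``imputation`` config enum:

``transformer``
    Each feature scalar is embedded into R^H by a shared 1->H projection and
    passed through stacked masked multi-head self-attention layers: a
    feature's representation is a softmax-weighted average over the
    *observed* features (masked positions get -inf logits and so zero
    weight).  The observed positions' outputs are mean-pooled into one
    H-vector.  An all-missing input yields the zero vector and a flag.

``linear_attention``
    A lighter scheme: embed each (sentinel-substituted) scalar, score it
    with f(x) = S . phi . T(x) reduced to a scalar, pass scores through exp
    so they are strictly positive, normalise them to weights summing to 1,
    and reweight the input scalars; a single K->H projection then produces
    the latent vector.  This arm has far fewer parameters than the stacked
    attention encoder at equal hidden size.
"""

from __future__ import annotations

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = [
    "TransformerImputationEncoder",
    "LinearAttentionEncoder",
    "embed_features",
    "masked_attention_encode",
    "linear_attention_reweight",
    "encode_baseline_linear",
]

SENTINEL = -1.0


def _substitute_sentinel(values: np.ndarray, mask: np.ndarray,
                         sentinel: float) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=float)
    out = np.where(mask > 0, values, sentinel)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite observed value passed to encoder")
    return out


class _AttentionLayer(Module):
    def __init__(self, hidden_size: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if hidden_size % n_heads != 0:
            raise ValueError("hidden size must be divisible by the head count")
        self.h = hidden_size
        self.n_heads = n_heads
        self.d_k = hidden_size // n_heads
        self.q = Linear(hidden_size, hidden_size, rng)
        self.k = Linear(hidden_size, hidden_size, rng)
        self.v = Linear(hidden_size, hidden_size, rng)
        self.out = Linear(hidden_size, hidden_size, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, K, H = x.shape
        nh, dk = self.n_heads, self.d_k

        def split(t: Tensor) -> Tensor:  # (B,K,H) -> (B,nh,K,dk)
            return t.reshape(B, K, nh, dk).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))  # (B,nh,K,K)
        key_mask = mask[:, None, None, :].astype(bool)  # broadcast over heads/queries
        attn = scores.masked_softmax(np.broadcast_to(key_mask, scores.shape))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, K, H)
        return x + self.out(ctx)  # residual


class TransformerImputationEncoder(Module):
    """Masked scaled-dot-product attention over features (see module doc)."""

    def __init__(self, n_features: int, hidden_size: int, rng: np.random.Generator,
                 n_heads: int = 4, n_layers: int = 3, sentinel: float = SENTINEL):
        super().__init__()
        self.n_features = n_features
        self.hidden_size = hidden_size
        self.sentinel = sentinel
        self.input_proj = Linear(1, hidden_size, rng)
        self.layers = [_AttentionLayer(hidden_size, n_heads, rng)
                       for _ in range(n_layers)]

    def embed(self, values: np.ndarray, mask: np.ndarray) -> Tensor:
        """Shared scalar->H projection of sentinel-substituted inputs;
        returns a (B, K, H) tensor."""
        x = _substitute_sentinel(values, mask, self.sentinel)
        return self.input_proj(Tensor(x[..., None]))

    def __call__(self, values: np.ndarray, mask: np.ndarray) -> Tensor:
        mask = np.asarray(mask, dtype=float)
        x = self.embed(values, mask)
        for layer in self.layers:
            x = layer(x, mask)
        # mean-pool over observed feature positions only
        m = Tensor(mask[..., None])
        denom = np.maximum(mask.sum(axis=-1, keepdims=True), 1.0)
        pooled = (x * m).sum(axis=1) * Tensor(1.0 / denom)
        # all-missing samples: zero vector (callers may flag via mask.sum()==0)
        has_any = (mask.sum(axis=-1, keepdims=True) > 0).astype(float)
        return pooled * Tensor(has_any)


class LinearAttentionEncoder(Module):
    """Sentinel + learned positive reweighting + single K->H projection."""

    def __init__(self, n_features: int, hidden_size: int, rng: np.random.Generator,
                 sentinel: float = SENTINEL):
        super().__init__()
        self.n_features = n_features
        self.hidden_size = hidden_size
        self.sentinel = sentinel
        self.input_proj = Linear(1, hidden_size, rng)
        self.map_t = Linear(hidden_size, hidden_size, rng, bias=False)
        self.map_s = Linear(hidden_size, hidden_size, rng, bias=False)
        self.output_proj = Linear(n_features, hidden_size, rng)

    def scores(self, values: np.ndarray, mask: np.ndarray) -> Tensor:
        """Strictly positive per-feature scores exp(mean_H S.relu(T(emb)))."""
        x = _substitute_sentinel(values, mask, self.sentinel)
        emb = self.input_proj(Tensor(x[..., None]))          # (B, K, H)
        f = self.map_s(self.map_t(emb).relu())               # S . phi . T
        return f.mean(axis=-1).exp()                         # (B, K)

    def reweight(self, values: np.ndarray, mask: np.ndarray
                 ) -> tuple[Tensor, Tensor]:
        """Returns (reweighted values, weights); weights sum to 1 per row."""
        x = _substitute_sentinel(values, mask, self.sentinel)
        s = self.scores(values, mask)
        w = s / s.sum(axis=-1, keepdims=True)
        return Tensor(x) * w, w

    def __call__(self, values: np.ndarray, mask: np.ndarray) -> Tensor:
        reweighted, _ = self.reweight(values, mask)
        return self.output_proj(reweighted)


# -- functional views used throughout the test-suite -----------------------

def embed_features(values: np.ndarray, mask: np.ndarray,
                   encoder: TransformerImputationEncoder) -> np.ndarray:
    """(K,) scalars -> (K, H) embeddings with sentinel substitution."""
    return encoder.embed(values[None, :], mask[None, :]).data[0]


def masked_attention_encode(values: np.ndarray, mask: np.ndarray,
                            encoder: TransformerImputationEncoder) -> np.ndarray:
    """(K,) -> (H,) latent through the masked attention stack."""
    return encoder(values[None, :], mask[None, :]).data[0]


def linear_attention_reweight(values: np.ndarray, mask: np.ndarray,
                              encoder: LinearAttentionEncoder
                              ) -> tuple[np.ndarray, np.ndarray]:
    """(K,) -> (reweighted (K,), weights (K,)); weights sum to 1."""
    reweighted, w = encoder.reweight(values[None, :], mask[None, :])
    return reweighted.data[0], w.data[0]


def encode_baseline_linear(values: np.ndarray, mask: np.ndarray,
                           encoder: LinearAttentionEncoder) -> np.ndarray:
    """(K,) -> (H,) latent through the linear-attention arm."""
    return encoder(values[None, :], mask[None, :]).data[0]


def reweight_with_scores(values: np.ndarray, scores: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Reference reweighting given externally supplied positive scores:
    w_k = s_k / sum(s), x'_k = x_k * w_k."""
    scores = np.asarray(scores, dtype=float)
    w = scores / scores.sum()
    return np.asarray(values, dtype=float) * w, w
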
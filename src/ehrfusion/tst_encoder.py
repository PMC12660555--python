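"""Time-series transformer (TST) over visit duration / inter-visit gap.

The visit timeline enters as a w x 2 matrix (duration, gap in hours) with a
validity mask.  The encoder min-max scales the features with statistics
fitted on the training split, projects each row into d_model dimensions
(u_t = W_p x_t + b_p), adds fixed sinusoidal positional encodings, runs a
stack of post-norm transformer blocks with a padding mask so attention never
sees padded rows, mean-pools the valid positions into z-tilde, and applies a
final affine map z_b = W_o z-tilde + b_o.

Normalization is configurable: ``batch`` (default) computes batch-norm-style
per-feature statistics over each sequence's valid positions only, which
handles the heavy-tailed hour scales of clinical timelines; ``layer`` is the
standard transformer choice.  The feed-forward activation is GELU by default
with ReLU available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .ehr_data import TemporalFeatures


@dataclass
class TSTConfig:
    d_model: int = 64
    n_heads: int = 8
    n_layers: int = 3
    d_ffn: int = 256
    dropout: float = 0.10
    max_len: int = 16
    norm: str = "batch"            # "batch" | "layer"
    activation: str = "gelu"       # "gelu" | "relu"
    m: int = 2

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.norm not in ("batch", "layer"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.activation not in ("gelu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if min(self.d_model, self.n_heads, self.n_layers, self.d_ffn, self.max_len, self.m) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass
class Scaler:
    """Per-feature min/max fitted on the training split's valid rows only."""

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self):
        self.min = np.asarray(self.min, dtype=np.float64)
        self.max = np.asarray(self.max, dtype=np.float64)
        if np.any(self.max < self.min):
            raise ValueError("max must be >= min elementwise")

    @property
    def constant_features(self) -> np.ndarray:
        return self.max == self.min


def fit_scaler(train_features: list[TemporalFeatures]) -> Scaler:
    """Min/max over valid (masked-in) rows of the training set."""
    rows = [f.matrix[f.mask] for f in train_features if f.mask.any()]
    if not rows:
        raise ValueError("cannot fit scaler: no valid rows in the training features")
    stacked = np.concatenate(rows, axis=0)
    return Scaler(min=stacked.min(axis=0), max=stacked.max(axis=0))


def apply_scaler(features: TemporalFeatures, scaler: Scaler) -> TemporalFeatures:
    """x-tilde = (x - min) / (max - min), clipped to [0, 1].

    Out-of-range test values clip to the endpoints; constant features map to
    0; padding rows remain zero.
    """
    span = scaler.max - scaler.min
    safe_span = np.where(span == 0.0, 1.0, span)
    scaled = np.clip((features.matrix - scaler.min) / safe_span, 0.0, 1.0)
    scaled[:, scaler.constant_features] = 0.0
    scaled[~features.mask] = 0.0
    return TemporalFeatures(matrix=scaled, mask=features.mask.copy())


class TSTEncoder(nn.Module):
    """Masked transformer encoder producing the temporal embedding z_b."""

    def __init__(self, config: TSTConfig, rng: np.random.Generator):
        self.config = config
        self.input_proj = nn.Linear(config.m, config.d_model, rng)
        self.layers = [
            nn.TransformerLayer(
                config.d_model, config.n_heads, config.d_ffn,
                activation=config.activation, norm=config.norm, rng=rng,
            )
            for _ in range(config.n_layers)
        ]
        self.output_proj = nn.Linear(config.d_model, config.d_model, rng)
        self._pos = nn.sinusoidal_positions(config.max_len, config.d_model)

    def forward_batch(
        self,
        matrix: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        """(B, w, m) scaled features + (B, w) mask -> (B, d_model) embeddings."""
        B, w, m = matrix.shape
        if w > self.config.max_len:
            raise ValueError(
                f"sequence length {w} exceeds max_len {self.config.max_len}; "
                "truncate upstream with extract_temporal_features"
            )
        x = self.input_proj(nn.Tensor(matrix)) + self._pos[:w]
        dropout = self.config.dropout if training else 0.0
        for layer in self.layers:
            x = layer(x, mask, dropout=dropout, rng=rng if training else None)
        mf = mask[:, :, None].astype(np.float64)
        cnt = np.maximum(mf.sum(axis=1), 1.0)
        pooled = (x * mf).sum(axis=1) * (1.0 / cnt)
        return self.output_proj(pooled)


def encode_sequence(
    features: TemporalFeatures, scaler: Scaler, encoder: TSTEncoder
) -> np.ndarray:
    """Scale one patient's features and run the encoder in eval mode."""
    scaled = apply_scaler(features, scaler)
    out = encoder.forward_batch(scaled.matrix[None], scaled.mask[None], training=False)
    return out.data[0]


# ---------------------------------------------------------------------------
# Standalone building blocks (array-in / array-out views of the same math)
# ---------------------------------------------------------------------------


def project_and_position(
    scaled: TemporalFeatures, weight: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """u'_t = W_p x-tilde_t + b_p + p_t with fixed sinusoidal p_t; W_p is (d, m)."""
    weight = np.asarray(weight, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if weight.shape[1] != scaled.matrix.shape[1]:
        raise ValueError(f"W_p shape {weight.shape} incompatible with m={scaled.matrix.shape[1]}")
    u = scaled.matrix @ weight.T + bias
    return u + nn.sinusoidal_positions(scaled.w, weight.shape[0])


def self_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention for one head on plain arrays.

    Returns (context, attention_weights).  Masked-out key positions receive
    -inf before the row-wise softmax so each attention row is a probability
    distribution over valid keys; if every key is masked the context row is
    defined as zero.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    d_k = Q.shape[-1]
    scores = Q @ K.T / np.sqrt(d_k)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        scores = np.where(mask[None, :], scores, -np.inf)
    # a fully masked row is all -inf; the nan from (-inf) - (-inf) is zeroed below
    with np.errstate(invalid="ignore"):
        shifted = scores - np.max(scores, axis=-1, keepdims=True, initial=-np.inf)
        e = np.exp(shifted)
    e = np.where(np.isfinite(scores), e, 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    attn = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    return attn @ V, attn


def feed_forward(
    x: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
    activation: str = "gelu",
) -> np.ndarray:
    """FFN(x) = act(x W_1 + b_1) W_2 + b_2 with configurable nonlinearity."""
    x = np.asarray(x, dtype=np.float64)
    h = x @ w1 + b1
    if activation == "relu":
        h = np.maximum(h, 0.0)
    elif activation == "gelu":
        h = nn.gelu_scalar(h)
    else:
        raise ValueError(f"unknown activation {activation!r}")
    return h @ w2 + b2
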
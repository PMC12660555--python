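"""Semantic text encoding: document -> hidden vector h_a -> disease logits z_a.

The contract is the reusable piece: an encoder maps an
:class:`~ehrfusion.text_assembly.InputDocument` to a fixed-dimension hidden
vector, and a trainable affine projection maps that vector into the disease
label space (z_a = W h_a + b).  The default encoder is a compact trainable
transformer over hashed tokens — small enough to train on a laptop CPU —
pooled at the last non-pad token to mirror the final hidden state of an
autoregressive decoder.  Externally hosted large language models plug in
through the same adapter protocol.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from . import nn
from .text_assembly import InputDocument

BOS_TOKEN_ID = 0  # always prepended; the encoding path for empty text


@dataclass
class EncoderConfig:
    kind: str = "compact"          # "compact" | "external-adapter"
    d_llm: int = 32
    vocab_size: int = 2048
    n_layers: int = 1
    n_heads: int = 2
    d_ffn: int = 64
    max_tokens: int = 64
    pooling: str = "last"          # "last" | "mean"
    seed: int = 0

    def __post_init__(self):
        if self.d_llm < 1:
            raise ValueError("d_llm must be >= 1")
        if self.pooling not in ("last", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


@runtime_checkable
class EncoderAdapter(Protocol):
    """Protocol for pluggable text encoders.

    ``d_llm`` declares the embedding dimension; ``trainable`` whether the
    training loop should collect its parameters; ``encode_batch`` must be
    deterministic in eval mode and honor the configured pooling contract
    (the vector stands for the document's final hidden state).
    """

    d_llm: int
    trainable: bool

    def encode_batch(self, docs: list[InputDocument], training: bool = False): ...


def hash_token(token: str, vocab_size: int) -> int:
    """Deterministic token -> bucket id in [1, vocab_size); 0 is reserved for BOS/pad."""
    h = int.from_bytes(hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest(), "big")
    return 1 + h % (vocab_size - 1)


def tokenize(text: str, config: EncoderConfig) -> list[int]:
    ids = [BOS_TOKEN_ID]
    ids += [hash_token(t, config.vocab_size) for t in text.split()]
    return ids[: config.max_tokens]


class CompactTextEncoder(nn.Module):
    """Small self-attention stack over hashed token embeddings.

    Token ids come from a fixed hash (no tokenizer model to ship), embeddings
    plus fixed sinusoidal positions feed ``n_layers`` post-norm transformer
    blocks with layer normalization, and the document vector is the hidden
    state at the last non-pad token (or the masked mean, by config).
    Fully determined by ``config.seed``.
    """

    trainable = True

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.d_llm = config.d_llm
        rng = np.random.default_rng(config.seed)
        self.embedding = nn.Parameter(rng.normal(0.0, 1.0, size=(config.vocab_size, config.d_llm)))
        self.layers = [
            nn.TransformerLayer(
                config.d_llm, config.n_heads, config.d_ffn,
                activation="gelu", norm="layer", rng=rng,
            )
            for _ in range(config.n_layers)
        ]
        self._pos = nn.sinusoidal_positions(config.max_tokens, config.d_llm)

    def batch_ids(self, docs: list[InputDocument]) -> tuple[np.ndarray, np.ndarray]:
        seqs = [tokenize(d.text, self.config) for d in docs]
        L = max(len(s) for s in seqs)
        ids = np.zeros((len(seqs), L), dtype=np.int64)
        mask = np.zeros((len(seqs), L), dtype=bool)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = True
        return ids, mask

    def forward_ids(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        x = nn.gather_rows(self.embedding, ids) + self._pos[: ids.shape[1]]
        drop_rng = rng if training else None
        for layer in self.layers:
            x = layer(x, mask, dropout=dropout if training else 0.0, rng=drop_rng)
        if self.config.pooling == "mean":
            m = mask[:, :, None].astype(np.float64)
            return (x * m).sum(axis=1) * (1.0 / m.sum(axis=1))
        last = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
        return x[np.arange(ids.shape[0]), last]

    def encode_batch(self, docs: list[InputDocument], training: bool = False) -> nn.Tensor:
        ids, mask = self.batch_ids(docs)
        return self.forward_ids(ids, mask, training=training)


class FixedVectorEncoder:
    """Adapter stub returning precomputed vectors keyed by document text.

    Stands in for an externally hosted language model in conformance tests
    and offline pipelines where embeddings were computed elsewhere.
    """

    trainable = False

    def __init__(self, d_llm: int, table: dict[str, np.ndarray], default: np.ndarray | None = None):
        self.d_llm = d_llm
        self.table = {k: np.asarray(v, dtype=np.float64) for k, v in table.items()}
        self.default = np.zeros(d_llm) if default is None else np.asarray(default)

    def encode_batch(self, docs: list[InputDocument], training: bool = False) -> nn.Tensor:
        vecs = np.stack([self.table.get(d.text, self.default) for d in docs])
        return nn.Tensor(vecs)

    def parameters(self):
        return []


class SemanticProjection(nn.Module):
    """Affine map from encoder space to disease-logit space: z_a = W h_a + b."""

    def __init__(self, d_llm: int, d_labels: int, rng: np.random.Generator):
        self.lin = nn.Linear(d_llm, d_labels, rng)

    def __call__(self, h_a: nn.Tensor) -> nn.Tensor:
        return self.lin(h_a)


def encode_text(doc: InputDocument, encoder: CompactTextEncoder) -> np.ndarray:
    """Single-document convenience wrapper (eval mode): returns h_a as an array."""
    return encoder.encode_batch([doc], training=False).data[0]


def project_semantic(h_a: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """z_a = W h_a + b on plain arrays; W is (d_labels, d_llm)."""
    weight = np.asarray(weight, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    h_a = np.asarray(h_a, dtype=np.float64)
    if weight.shape[1] != h_a.shape[-1] or weight.shape[0] != bias.shape[0]:
        raise ValueError(
            f"shape mismatch: weight {weight.shape}, bias {bias.shape}, h_a {h_a.shape}"
        )
    return h_a @ weight.T + bias
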
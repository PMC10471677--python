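"""Dual-channel graph-convolutional encoder with attention fusion and
adversarial domain classifier.

Architecture
------------
Each domain graph is encoded twice with the same stacked two-layer graph
convolution sigma(S X W): once with the normalized self-loop adjacency
(local consistency) and once with the normalized random-walk PPMI operator
(global consistency). The two channel embeddings Z_A and Z_P are fused
per node by a learned two-way attention: raw features are projected by a
shared matrix J to the embedding width, each channel is scored by
v' tanh(W_att [z || JX] + b), and a per-node softmax over the two scores
gives convex weights, Z = att_A * Z_A + att_P * Z_P.

All encoder and attention parameters are shared between the source and
target domains (the point of transfer); classification runs through three
heads: a source label head, a target label head, and a binary domain head
fed through a gradient-reversal layer so that minimizing the domain loss
pushes the shared encoder toward domain-invariant embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import FeatureTable, NormalizedOperator

__all__ = [
    "ModelConfig",
    "DualEmbeddings",
    "AttentionWeights",
    "DAMGCN",
    "conv_layer",
    "gradient_reversal",
]

_ACTIVATIONS = {
    "relu": ad.relu,
    "tanh": ad.tanh,
    "identity": lambda x: x,
}


@dataclass(frozen=True)
class ModelConfig:
    """Encoder/head sizes; defaults follow the 128-16 two-hidden-layer setup."""

    n_features: int = 25
    n_classes: int = 2
    hidden1: int = 128
    hidden2: int = 16
    dropout: float = 0.5
    activation: str = "relu"
    domain_hidden: int = 16
    share_attention: bool = True  # one attention scorer for both domains

    def __post_init__(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1:
            raise ValueError("hidden sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class DualEmbeddings:
    """Per-domain channel outputs and their attention-fused combination."""

    Z_A: np.ndarray
    Z_P: np.ndarray
    Z: np.ndarray
    domain_tag: str = "source"


@dataclass
class AttentionWeights:
    """Per-node channel weights; att_A + att_P = 1 elementwise."""

    att_A: np.ndarray
    att_P: np.ndarray


def conv_layer(x: Tensor, op: NormalizedOperator, weight: Tensor,
               bias: Tensor | None = None, activation: str = "relu") -> Tensor:
    """One graph convolution: sigma(S X W [+ b]) with S a normalized operator."""
    if x.shape[1] != weight.shape[0]:
        raise ValueError(
            f"feature width {x.shape[1]} does not match weight rows {weight.shape[0]}")
    out = ad.matmul(ad.matmul(ad.constant(op.matrix), x), weight)
    if bias is not None:
        out = out + bias
    return _ACTIVATIONS[activation](out)


def gradient_reversal(z: Tensor, lam: float) -> Tensor:
    """Identity forward; gradient scaled by -lam on the way back."""
    return ad.gradient_reversal(z, lam)


@dataclass
class _Linear:
    w: Tensor
    b: Tensor

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class DAMGCN:
    """The trainable cross-domain model.

    One instance holds a single set of encoder, attention and head
    parameters; both domains are pushed through the same weight objects.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        d, h1, h2 = cfg.n_features, cfg.hidden1, cfg.hidden2

        def lin(fan_in: int, fan_out: int) -> _Linear:
            return _Linear(ad.parameter(ad.glorot_uniform(rng, fan_in, fan_out)),
                           ad.parameter(np.zeros(fan_out)))

        # channel weights: local (adjacency) and global (PPMI), each 2 layers
        self.local1, self.local2 = lin(d, h1), lin(h1, h2)
        self.global1, self.global2 = lin(d, h1), lin(h1, h2)
        # attention: shared projection J plus a small tanh scorer
        self.J = ad.parameter(ad.glorot_uniform(rng, d, h2))
        self.att = {"shared": self._make_scorer(rng)}
        if not cfg.share_attention:
            self.att = {"source": self._make_scorer(rng),
                        "target": self._make_scorer(rng)}
        # heads
        self.head_source = lin(h2, cfg.n_classes)
        self.head_target = lin(h2, cfg.n_classes)
        self.domain_hidden = lin(h2, cfg.domain_hidden)
        self.domain_out = lin(cfg.domain_hidden, 1)

    def _make_scorer(self, rng: np.random.Generator) -> dict[str, Tensor]:
        h2 = self.cfg.hidden2
        return {
            "W": ad.parameter(ad.glorot_uniform(rng, 2 * h2, h2)),
            "b": ad.parameter(np.zeros(h2)),
            "v": ad.parameter(ad.glorot_uniform(rng, h2, 1)),
        }

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for lin in (self.local1, self.local2, self.global1, self.global2,
                    self.head_source, self.head_target,
                    self.domain_hidden, self.domain_out):
            params.extend(lin.params())
        params.append(self.J)
        for scorer in self.att.values():
            params.extend(scorer.values())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]

    # -- forward pieces ---------------------------------------------------
    def _encode_channel(self, x: Tensor, op: NormalizedOperator,
                        layer1: _Linear, layer2: _Linear, training: bool,
                        rng: np.random.Generator | None) -> Tensor:
        act = self.cfg.activation
        z = conv_layer(x, op, layer1.w, layer1.b, act)
        if training and self.cfg.dropout > 0:
            z = ad.dropout_mask(z, self.cfg.dropout, rng)
        z = conv_layer(z, op, layer2.w, layer2.b, act)
        if training and self.cfg.dropout > 0:
            z = ad.dropout_mask(z, self.cfg.dropout, rng)
        return z

    def encode(self, features: FeatureTable, op_A: NormalizedOperator,
               op_P: NormalizedOperator, *, training: bool = False,
               rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Run both channels; returns (Z_A, Z_P) as tape tensors."""
        x = ad.constant(features.values)
        z_a = self._encode_channel(x, op_A, self.local1, self.local2, training, rng)
        z_p = self._encode_channel(x, op_P, self.global1, self.global2, training, rng)
        return z_a, z_p

    def attention_fuse(self, z_a: Tensor, z_p: Tensor, features: FeatureTable,
                       domain_tag: str) -> tuple[Tensor, AttentionWeights]:
        """Per-node two-way softmax attention over the channel embeddings."""
        if z_a.shape != z_p.shape:
            raise ValueError("channel embeddings must share a shape")
        key = ad.matmul(ad.constant(features.values), self.J)  # N x h2
        if key.shape[1] != z_a.shape[1]:
            raise ValueError("projected features do not match embedding width")
        scorer = self.att["shared" if "shared" in self.att else domain_tag]
        s_a = self._score(z_a, key, scorer)
        s_p = self._score(z_p, key, scorer)
        att = ad.softmax(_stack_cols(s_a, s_p), axis=1)
        att_a = take_col(att, 0)
        att_p = take_col(att, 1)
        z = att_a * z_a + att_p * z_p
        return z, AttentionWeights(att_A=att_a.data.ravel().copy(),
                                   att_P=att_p.data.ravel().copy())

    def _score(self, z: Tensor, key: Tensor, scorer: dict[str, Tensor]) -> Tensor:
        joined = _concat_cols(z, key)
        hidden = ad.tanh(ad.matmul(joined, scorer["W"]) + scorer["b"])
        return ad.matmul(hidden, scorer["v"])  # N x 1

    def forward(self, features: FeatureTable, op_A: NormalizedOperator,
                op_P: NormalizedOperator | None, domain_tag: str, *,
                training: bool = False, rng: np.random.Generator | None = None,
                use_global: bool = True) -> tuple[Tensor, DualEmbeddings, AttentionWeights | None]:
        """Full encoder pass; with ``use_global=False`` this is a plain GCN."""
        x = ad.constant(features.values)
        if not use_global:
            z_a = self._encode_channel(x, op_A, self.local1, self.local2,
                                       training, rng)
            emb = DualEmbeddings(Z_A=z_a.data.copy(),
                                 Z_P=np.zeros_like(z_a.data),
                                 Z=z_a.data.copy(), domain_tag=domain_tag)
            return z_a, emb, None
        if op_P is None:
            raise ValueError("op_P is required unless use_global=False")
        z_a, z_p = self.encode(features, op_A, op_P, training=training, rng=rng)
        z, att = self.attention_fuse(z_a, z_p, features, domain_tag)
        emb = DualEmbeddings(Z_A=z_a.data.copy(), Z_P=z_p.data.copy(),
                             Z=z.data.copy(), domain_tag=domain_tag)
        return z, emb, att

    def classify(self, z: Tensor, head: str) -> Tensor:
        """Label heads -> row-stochastic class probabilities; domain head ->
        per-node probability of coming from the target domain."""
        if head == "source":
            return ad.softmax(self.head_source(z), axis=1)
        if head == "target":
            return ad.softmax(self.head_target(z), axis=1)
        if head == "domain":
            h = ad.relu(self.domain_hidden(z))
            return ad.sigmoid(self.domain_out(h))
        raise ValueError(f"unknown head {head!r}; expected source|target|domain")


# small column helpers kept here because only the attention block needs them

def _concat_cols(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    na = a.data.shape[1]

    def bwd(g: np.ndarray) -> None:
        ad._accum(a, g[:, :na])
        ad._accum(b, g[:, na:])

    return Tensor(out, parents=(a, b), backward=bwd)


def _stack_cols(a: Tensor, b: Tensor) -> Tensor:
    """Stack two N x 1 score columns into N x 2."""
    return _concat_cols(a, b)


def take_col(x: Tensor, j: int) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        acc = np.zeros_like(x.data)
        acc[:, j:j + 1] = g
        ad._accum(x, acc)

    return Tensor(x.data[:, j:j + 1].copy(), parents=(x,), backward=bwd)
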
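"""Joint training of the cross-domain model.

The objective combines three terms,

    L = L_S + gamma1 * L_DA + gamma2 * L_T,

where L_S and L_T are cross-entropy losses of the source and target label
heads on their respective (stratified) training splits, and L_DA is the
binary cross-entropy of the domain classifier over all source and target
nodes, fed through the gradient-reversal layer so the shared encoder is
pushed to make the two domains indistinguishable. gamma2 weights the
target term (an optional second balance parameter; set ``strict_total``
to recover the plain unweighted sum). The adversarial strength lambda
ramps with training progress p in [0, 1]:

    corrected : lambda(p) = min(2 / (1 + exp(-10 p)) - 1, 0.1)
    as_printed: lambda(p) = min(1 / (1 + exp(-10 p)) - 1, 0.1)

"as_printed" reproduces a published form of the ramp verbatim; it is
negative for every p (its first branch never exceeds 0), which turns the
adversary cooperative, so "corrected" — the standard sigmoid ramp capped
at 0.1 — is the default. Optimization is full-batch Adam at a fixed
learning rate; ablation variants drop the target loss (``no_target``),
the whole global PPMI channel plus attention (``no_global``), or the
domain adversary (``no_domain``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import LabeledGraph, NormalizedOperator, normalize_adjacency
from .model import DAMGCN, ModelConfig, gradient_reversal
from .walk_pmi import WalkConfig, ppmi_operator

logger = logging.getLogger("damgcn")

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "TrainedModel",
    "source_loss",
    "target_loss",
    "domain_loss",
    "lambda_schedule",
    "train_damgcn",
    "save_loss_trace",
]

VARIANTS = ("full", "no_target", "no_global", "no_domain")
_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    lr: float = 3e-3
    k: int = 6
    gamma1: float = 1.0
    gamma2: float = 0.8
    seed: int = 21
    train_fraction: float = 0.6
    variant: str = "full"
    lambda_mode: str = "corrected"
    strict_total: bool = False  # force gamma2 = 1 (plain unweighted sum)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("balance parameters must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.lambda_mode not in ("corrected", "as_printed"):
            raise ValueError("lambda_mode must be 'corrected' or 'as_printed'")

    @property
    def effective_gamma2(self) -> float:
        return 1.0 if self.strict_total else self.gamma2


@dataclass
class LossBreakdown:
    epoch: int
    L_S: float
    L_DA: float
    L_T: float
    total: float
    lambda_value: float


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to evaluate it reproducibly."""

    model: DAMGCN
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    source: LabeledGraph
    target: LabeledGraph
    op_A: dict[str, NormalizedOperator]
    op_P: dict[str, NormalizedOperator | None]
    splits: dict[str, tuple[np.ndarray, np.ndarray]]  # tag -> (train, test)
    history: list[LossBreakdown] = field(default_factory=list)

    def embed(self, tag: str) -> np.ndarray:
        """Fused (or local-only, for no_global) embedding in eval mode."""
        graph = self.source if tag == "source" else self.target
        z, _, _ = self.model.forward(
            graph.features, self.op_A[tag], self.op_P[tag], tag,
            training=False, use_global=self.train_cfg.variant != "no_global")
        return z.data

    def predict_proba(self, tag: str) -> np.ndarray:
        graph = self.source if tag == "source" else self.target
        z, _, _ = self.model.forward(
            graph.features, self.op_A[tag], self.op_P[tag], tag,
            training=False, use_global=self.train_cfg.variant != "no_global")
        return self.model.classify(z, tag).data


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def _cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=np.intp)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels disagree in length")
    p_true = ad.gather_cols(probs, labels)
    if np.any(p_true.data < _EPS):
        logger.warning("clamping %d true-class probabilities below %.0e",
                       int((p_true.data < _EPS).sum()), _EPS)
    return -1.0 * ad.mean(ad.log(p_true, eps=_EPS))


def source_loss(probs: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of the source label head on its training nodes."""
    return _cross_entropy(_as_tensor(probs), labels)


def target_loss(probs: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Same contract as :func:`source_loss`, over target training nodes."""
    return _cross_entropy(_as_tensor(probs), labels)


def domain_loss(domain_probs: Tensor | np.ndarray,
                domain_labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all source + target nodes."""
    probs = _as_tensor(domain_probs)
    m = np.asarray(domain_labels, dtype=np.float64).reshape(-1, 1)
    if probs.data.ndim == 1:
        raise ValueError("domain probabilities must be a column (N x 1)")
    if probs.shape[0] != m.shape[0]:
        raise ValueError("domain predictions and labels disagree in length")
    pos = ad.constant(m) * ad.log(probs, eps=_EPS)
    neg = ad.constant(1.0 - m) * ad.log(_one_minus(probs), eps=_EPS)
    return -1.0 * ad.mean(pos + neg)


def _one_minus(x: Tensor) -> Tensor:
    return 1.0 + (-x)


def _as_tensor(x: Tensor | np.ndarray) -> Tensor:
    return x if isinstance(x, Tensor) else ad.constant(np.asarray(x, dtype=np.float64))


def lambda_schedule(p: float, mode: str = "corrected") -> float:
    """Adversarial adaptation rate at training progress ``p`` in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        logger.warning("training progress p=%.3f outside [0, 1]; clamping", p)
        p = min(max(p, 0.0), 1.0)
    if mode == "corrected":
        return float(min(2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0, 0.1))
    if mode == "as_printed":
        return float(min(1.0 / (1.0 + np.exp(-10.0 * p)) - 1.0, 0.1))
    raise ValueError("mode must be 'corrected' or 'as_printed'")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, train_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test index split (sorted indices)."""
    idx = np.arange(labels.shape[0])
    counts = np.bincount(labels)
    if np.any(counts[counts > 0] < 2):
        raise ValueError("every class needs at least 2 members to stratify")
    train, test = train_test_split(idx, train_size=train_fraction,
                                   stratify=labels, random_state=seed)
    return np.sort(train), np.sort(test)


def train_damgcn(source: LabeledGraph, target: LabeledGraph,
                 model_cfg: ModelConfig | None = None,
                 train_cfg: TrainConfig | None = None,
                 walk_cfg: WalkConfig | None = None) -> TrainedModel:
    """Fit the joint objective with full-batch Adam; returns the fitted
    model together with its per-epoch loss trace.

    All randomness (weight init, dropout masks, walk sampling, splits)
    derives from ``train_cfg.seed``, so identical configurations yield
    identical loss traces and predictions.
    """
    train_cfg = train_cfg or TrainConfig()
    if source.features.n_features != target.features.n_features:
        raise ValueError("source and target must share one feature dimensionality "
                         "(the encoder weights are shared)")
    n_classes = max(source.n_classes, target.n_classes)
    if model_cfg is None:
        model_cfg = ModelConfig(n_features=source.features.n_features,
                                n_classes=n_classes)

    ss = np.random.SeedSequence(train_cfg.seed)
    s_init, s_drop, s_walk_s, s_walk_t, s_split = ss.spawn(5)
    init_rng = np.random.default_rng(s_init)
    drop_rng = np.random.default_rng(s_drop)
    split_seed = int(s_split.generate_state(1)[0] % (2 ** 31))

    use_global = train_cfg.variant != "no_global"
    use_domain = train_cfg.variant != "no_domain"
    use_target = train_cfg.variant != "no_target"

    op_A = {"source": normalize_adjacency(source.adjacency),
            "target": normalize_adjacency(target.adjacency)}
    op_P: dict[str, NormalizedOperator | None] = {"source": None, "target": None}
    if use_global:
        base = walk_cfg or WalkConfig()
        op_P["source"] = ppmi_operator(
            source.adjacency,
            WalkConfig(base.walks_per_node, base.walk_length, base.window,
                       int(s_walk_s.generate_state(1)[0] % (2 ** 31))))
        op_P["target"] = ppmi_operator(
            target.adjacency,
            WalkConfig(base.walks_per_node, base.walk_length, base.window,
                       int(s_walk_t.generate_state(1)[0] % (2 ** 31))))

    splits = {
        "source": stratified_split(source.labels, train_cfg.train_fraction, split_seed),
        "target": stratified_split(target.labels, train_cfg.train_fraction,
                                   split_seed + 1),
    }

    model = DAMGCN(model_cfg, init_rng)
    opt = ad.Adam(model.parameters(), lr=train_cfg.lr)
    gamma1, gamma2 = train_cfg.gamma1, train_cfg.effective_gamma2
    # domain labels: source nodes 0, target nodes 1 (the loss is symmetric)
    m = np.concatenate([np.zeros(source.n_nodes), np.ones(target.n_nodes)])

    history: list[LossBreakdown] = []
    for epoch in range(train_cfg.epochs):
        p = epoch / (train_cfg.epochs - 1) if train_cfg.epochs > 1 else 1.0
        lam = lambda_schedule(p, train_cfg.lambda_mode)

        z_s, _, _ = model.forward(source.features, op_A["source"], op_P["source"],
                                  "source", training=True, rng=drop_rng,
                                  use_global=use_global)
        z_t, _, _ = model.forward(target.features, op_A["target"], op_P["target"],
                                  "target", training=True, rng=drop_rng,
                                  use_global=use_global)

        probs_s = model.classify(ad.take_rows(z_s, splits["source"][0]), "source")
        loss_s = source_loss(probs_s, source.labels[splits["source"][0]])
        total = loss_s
        loss_t_val = 0.0
        if use_target:
            probs_t = model.classify(ad.take_rows(z_t, splits["target"][0]), "target")
            loss_t = target_loss(probs_t, target.labels[splits["target"][0]])
            total = total + gamma2 * loss_t
            loss_t_val = loss_t.item()
        loss_da_val = 0.0
        if use_domain:
            z_all = ad.concat_rows([gradient_reversal(z_s, lam),
                                    gradient_reversal(z_t, lam)])
            loss_da = domain_loss(model.classify(z_all, "domain"), m)
            total = total + gamma1 * loss_da
            loss_da_val = loss_da.item()

        opt.zero_grad()
        total.backward()
        opt.step()
        history.append(LossBreakdown(epoch=epoch, L_S=loss_s.item(),
                                     L_DA=loss_da_val, L_T=loss_t_val,
                                     total=total.item(), lambda_value=lam))

    return TrainedModel(model=model, model_cfg=model_cfg, train_cfg=train_cfg,
                        source=source, target=target, op_A=op_A, op_P=op_P,
                        splits=splits, history=history)


def save_loss_trace(history: list[LossBreakdown], path: str | Path,
                    delimiter: str = "\t") -> None:
    """Write the per-epoch trace: epoch, L_S, L_DA, L_T, total, lambda."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["epoch", "L_S", "L_DA", "L_T", "total", "lambda"]) + "\n")
        for rec in history:
            fh.write(delimiter.join([
                str(rec.epoch), f"{rec.L_S:.10g}", f"{rec.L_DA:.10g}",
                f"{rec.L_T:.10g}", f"{rec.total:.10g}",
                f"{rec.lambda_value:.10g}"]) + "\n")
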
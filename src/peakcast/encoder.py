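"""Contrastive MLP encoder for cell-type-aware embeddings.

Training pairs are built by drawing, twice and independently, one random
cell per cell type: positions aligned across the two draws are positive
instances (same type), all cross-type combinations within the pair are
negatives.  For a pair with per-type embeddings ``Za, Zb`` (K x d) the loss
is

    loss = -log [ sum_i exp(sim(z_a_i, z_b_i)/tau)
                  / sum_{i != j} exp(sim(z_a_i, z_b_j)/tau) ]

with ``sim`` the cosine similarity and ``tau`` a temperature.  Unlike
standard InfoNCE, all K positives are aggregated inside a single log and
the denominator contains only cross-type terms; the ratio can exceed one,
so the loss can be negative.  We implement the formula verbatim.

The network is a two-layer perceptron: input (p') -> hidden layer whose
width and initial weights come from an :class:`~peakcast.prior.InitBundle`
(128 random units + 100 PCA-initialized units, plus 100 more when a
reference is supplied) -> rectifier -> linear output (default 64).  All
parameters are trained with Adam.  Forward, backward and the optimizer are
implemented directly in NumPy: the model is small, runs single-threaded in
seconds, and exact control of the arithmetic keeps training bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .preprocess import NormalizedMatrix
from .prior import InitBundle

logger = logging.getLogger(__name__)

EPS_NORM = 1e-8

__all__ = [
    "EncoderConfig",
    "Embedding",
    "Encoder",
    "cosine_similarity",
    "sample_pairs",
    "contrastive_loss",
    "contrastive_loss_grad",
    "train_encoder",
    "embed",
]


@dataclass
class EncoderConfig:
    """Hyperparameters of the contrastive encoder.

    ``temperature`` controls how sharply the loss distinguishes positives
    from negatives; ``n_pairs`` is the total number of sampled training
    pairs, consumed once in mini-batches of ``pairs_per_step``.
    """

    output_dim: int = 64
    temperature: float = 0.5
    n_pairs: int = 10000
    pairs_per_step: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.output_dim < 2:
            raise ValueError("output_dim must be at least 2")
        if self.n_pairs < 1 or self.pairs_per_step < 1:
            raise ValueError("n_pairs and pairs_per_step must be positive")


@dataclass
class Embedding:
    vectors: np.ndarray  # N x d
    cell_ids: list[str]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with an epsilon-guarded norm."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return float(
        (u @ v) / ((np.linalg.norm(u) + EPS_NORM) * (np.linalg.norm(v) + EPS_NORM))
    )


def sample_pairs(
    labels: Sequence[str],
    n_pairs: int = 10000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw type-balanced training pairs.

    Returns an integer array of shape (n_pairs, 2, K): for each pair, two
    independent draws of one uniformly random cell per type, types in
    canonical (sorted) order.  A type with a single cell contributes that
    cell on both sides (a self positive pair).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels are required to sample pairs")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    types = sorted(set(labels))
    lab_arr = np.asarray(labels, dtype=object)
    by_type = [np.flatnonzero(lab_arr == t) for t in types]
    for t, idx in zip(types, by_type):
        if idx.size == 1:
            logger.warning("cell type %r has a single cell; positives are self-pairs", t)
    K = len(types)
    pairs = np.empty((n_pairs, 2, K), dtype=np.int64)
    for k, idx in enumerate(by_type):
        pairs[:, 0, k] = rng.choice(idx, size=n_pairs, replace=True)
        pairs[:, 1, k] = rng.choice(idx, size=n_pairs, replace=True)
    return pairs


def _normalize_rows(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=-1, keepdims=True)
    return Z / (norms + EPS_NORM), norms


def _pair_loss_grad(
    Za: np.ndarray, Zb: np.ndarray, tau: float, want_grad: bool
) -> tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    """Loss (and gradients) for a batch of pairs.

    ``Za, Zb`` have shape (B, K, d).  Returns per-pair losses (B,) and, when
    requested, gradients of the summed loss w.r.t. the raw embeddings.
    """
    B, K, d = Za.shape
    if K < 2:
        raise ValueError("contrastive loss needs at least 2 cell types")
    Na, norm_a = _normalize_rows(Za)
    Nb, norm_b = _normalize_rows(Zb)
    S = np.einsum("bkd,bld->bkl", Na, Nb) / tau
    diag = np.einsum("bkk->bk", S)
    # log-sum-exp over the diagonal (positives) and off-diagonal (negatives)
    m_num = diag.max(axis=1, keepdims=True)
    num = np.exp(diag - m_num)
    lse_num = m_num[:, 0] + np.log(num.sum(axis=1))
    off_mask = ~np.eye(K, dtype=bool)
    off = S[:, off_mask]  # (B, K*(K-1))
    m_den = off.max(axis=1, keepdims=True)
    den = np.exp(off - m_den)
    lse_den = m_den[:, 0] + np.log(den.sum(axis=1))
    losses = -(lse_num - lse_den)
    if not want_grad:
        return losses, None, None
    # dL/dS: -softmax over positives on the diagonal, +softmax over negatives off it
    G = np.zeros_like(S)
    p_num = num / num.sum(axis=1, keepdims=True)
    q_den = den / den.sum(axis=1, keepdims=True)
    G[:, off_mask] = q_den
    bi = np.arange(B)[:, None]
    ki = np.arange(K)[None, :]
    G[bi, ki, ki] = -p_num
    G /= tau
    dNa = np.einsum("bkl,bld->bkd", G, Nb)
    dNb = np.einsum("bkl,bkd->bld", G, Na)

    def back_norm(dN, N, norms):
        s = 1.0 / (norms + EPS_NORM)
        proj = np.sum(dN * N, axis=-1, keepdims=True)
        safe = np.maximum(norms, EPS_NORM)
        return dN * s - N * proj / safe

    return losses, back_norm(dNa, Na, norm_a), back_norm(dNb, Nb, norm_b)


def contrastive_loss(Za: np.ndarray, Zb: np.ndarray, tau: float = 0.5) -> float:
    """Contrastive loss for one training pair (K x d embeddings per side)."""
    Za = np.asarray(Za, dtype=np.float64)[None]
    Zb = np.asarray(Zb, dtype=np.float64)[None]
    if Za.shape != Zb.shape:
        raise ValueError("embedding sides must have the same shape")
    losses, _, _ = _pair_loss_grad(Za, Zb, tau, want_grad=False)
    loss = float(losses[0])
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite contrastive loss")
    return loss


def contrastive_loss_grad(
    Za: np.ndarray, Zb: np.ndarray, tau: float = 0.5
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients w.r.t. both embedding sides."""
    Za = np.asarray(Za, dtype=np.float64)[None]
    Zb = np.asarray(Zb, dtype=np.float64)[None]
    losses, dZa, dZb = _pair_loss_grad(Za, Zb, tau, want_grad=True)
    return float(losses[0]), dZa[0], dZb[0]


class Encoder:
    """Trained two-layer perceptron mapping normalized cells to embeddings."""

    def __init__(
        self,
        W1: np.ndarray,
        b1: np.ndarray,
        W2: np.ndarray,
        b2: np.ndarray,
        config: EncoderConfig,
        block_names: Optional[list[str]] = None,
        loss_history: Optional[list[float]] = None,
    ):
        self.W1 = W1
        self.b1 = b1
        self.W2 = W2
        self.b2 = b2
        self.config = config
        self.block_names = block_names or []
        self.loss_history = loss_history or []

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.W1.shape[1]

    def hidden_pre_activation(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W1 + self.b1

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = np.maximum(self.hidden_pre_activation(X), 0.0)
        return H @ self.W2 + self.b2

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            loss_history=np.asarray(self.loss_history),
            block_names=np.asarray(self.block_names, dtype=object),
        )
        manifest = path.with_suffix(".json")
        manifest.write_text(json.dumps({"config": asdict(self.config)}))

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"),
                       allow_pickle=True)
        cfg = EncoderConfig(**json.loads(path.with_suffix(".json").read_text())["config"])
        return cls(
            W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"],
            config=cfg,
            block_names=list(data["block_names"]),
            loss_history=list(data["loss_history"]),
        )


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_encoder(
    train_norm: NormalizedMatrix,
    labels: Optional[Sequence[str]],
    init: InitBundle,
    cfg: EncoderConfig,
) -> Encoder:
    """Train the contrastive encoder on a normalized training matrix.

    A single pass is made over ``cfg.n_pairs`` type-balanced pairs in
    mini-batches of ``cfg.pairs_per_step``, minimizing the batch-mean
    contrastive loss with Adam.  Fully deterministic for a fixed seed.
    """
    if labels is None:
        labels = train_norm.labels
    if labels is None:
        raise ValueError("labels are required for contrastive training")
    labels = list(labels)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("contrastive training needs at least 2 cell types")
    X = train_norm.cells_by_peaks()  # N x p'
    p = X.shape[1]
    if init.input_dim != p:
        raise ValueError(
            f"init bundle expects input dim {init.input_dim}, matrix has {p}"
        )
    rng = np.random.default_rng(cfg.seed)
    pairs = sample_pairs(labels, cfg.n_pairs, seed=rng)

    W1, b1 = init.stacked()
    W1 = W1.copy()
    b1 = b1.copy()
    H = W1.shape[1]
    limit = np.sqrt(6.0 / (H + cfg.output_dim))
    W2 = rng.uniform(-limit, limit, size=(H, cfg.output_dim))
    b2 = np.zeros(cfg.output_dim)

    params = [W1, b1, W2, b2]
    opt = _Adam(params, lr=cfg.learning_rate)
    K = pairs.shape[2]
    history: list[float] = []
    for start in range(0, cfg.n_pairs, cfg.pairs_per_step):
        batch = pairs[start : start + cfg.pairs_per_step]
        B = batch.shape[0]
        idx = batch.reshape(-1)  # (B*2*K,)
        Xb = X[idx]
        pre = Xb @ W1 + b1
        Hb = np.maximum(pre, 0.0)
        Z = (Hb @ W2 + b2).reshape(B, 2, K, -1)
        losses, dZa, dZb = _pair_loss_grad(
            Z[:, 0], Z[:, 1], cfg.temperature, want_grad=True
        )
        mean_loss = float(losses.mean())
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"non-finite loss at pair offset {start} (batch size {B})"
            )
        history.append(mean_loss)
        dZ = np.stack([dZa, dZb], axis=1).reshape(B * 2 * K, -1) / B
        dHb = (dZ @ W2.T) * (pre > 0)
        gW2 = Hb.T @ dZ
        gb2 = dZ.sum(axis=0)
        gW1 = Xb.T @ dHb
        gb1 = dHb.sum(axis=0)
        opt.step([gW1, gb1, gW2, gb2])
    logger.info(
        "trained encoder: %d batches, first/last batch loss %.4f / %.4f",
        len(history), history[0], history[-1],
    )
    return Encoder(
        W1=W1, b1=b1, W2=W2, b2=b2, config=cfg,
        block_names=[blk.name for blk in init.blocks],
        loss_history=history,
    )


def embed(encoder: Encoder, m: NormalizedMatrix) -> Embedding:
    """Deterministic forward pass of a normalized matrix through the encoder."""
    X = m.cells_by_peaks()
    if X.shape[1] != encoder.input_dim:
        raise ValueError(
            f"matrix has {X.shape[1]} peaks, encoder expects {encoder.input_dim}"
        )
    Z = encoder.forward(X)
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite embedding values")
    return Embedding(vectors=Z, cell_ids=list(m.cell_ids))
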
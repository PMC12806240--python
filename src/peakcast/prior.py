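"""Prior knowledge via bootstrap pseudo-samples and PCA weight initialization.

The encoder's second layer is partly initialized with PCA projections so
that, before any gradient step, a subset of its units already computes a
denoised linear embedding of the data.  Two sources feed this prior:

* the training set itself — within each cell type, cells are repeatedly
  resampled with replacement (default 500 draws, 1000 replicates) and
  averaged into pseudo-cells, and PCA (default 100 components) is fit on
  the pooled pseudo-sample;
* optionally an external reference matrix, aligned to the training peak
  space and TF-IDF-normalized, on which PCA is fit directly.

The bootstrap operates in TF-IDF space (the space the encoder consumes) so
the PCA weights live in the encoder's input coordinates.  PCA centering is
absorbed into the unit biases, which makes each PCA-initialized unit output
exactly the centered PCA score of its input; the weights remain trainable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSample",
    "PCAProjection",
    "InitBundle",
    "build_prior_sample",
    "fit_pca",
    "make_init_bundle",
]


@dataclass
class PriorSample:
    """Bootstrap pseudo-cells: features (p') by pooled pseudo-cells."""

    means: np.ndarray
    type_of_column: list[str]
    n_draws: int
    n_replicates: int


@dataclass
class PCAProjection:
    """Centered PCA: ``components`` is features (p') by components."""

    components: np.ndarray
    mean_vector: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project cell-by-feature rows onto the components."""
        return (X - self.mean_vector) @ self.components


@dataclass
class InitBlock:
    name: str
    weights: np.ndarray  # p' x width
    bias: np.ndarray  # width
    trainable: bool = True


@dataclass
class InitBundle:
    """Ordered second-layer weight blocks: random + PCA-derived."""

    blocks: list[InitBlock]

    @property
    def total_width(self) -> int:
        return sum(b.weights.shape[1] for b in self.blocks)

    @property
    def input_dim(self) -> int:
        return self.blocks[0].weights.shape[0]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        W = np.hstack([b.weights for b in self.blocks])
        b = np.concatenate([b.bias for b in self.blocks])
        return W, b


def build_prior_sample(
    train_norm: NormalizedMatrix,
    labels: Optional[Sequence[str]] = None,
    n_draws: int = 500,
    n_replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    pooling: str = "per_type",
) -> PriorSample:
    """Bootstrap pseudo-cells from the normalized training matrix.

    For each replicate and each cell type, ``n_draws`` cells of that type
    are drawn with replacement and averaged into one pseudo-cell.  With
    ``pooling="per_type"`` (default) the pooled sample stacks one
    pseudo-cell per type per replicate (K x n_replicates columns), which
    preserves type structure for the downstream PCA; ``"per_replicate"``
    instead averages the K pseudo-cells within each replicate to a single
    column.
    """
    if labels is None:
        labels = train_norm.labels
    if labels is None:
        raise ValueError("training labels are required to build the prior")
    labels = list(labels)
    if len(labels) != train_norm.n_cells:
        raise ValueError("labels length does not match the matrix")
    if pooling not in ("per_type", "per_replicate"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    types = sorted(set(labels))
    X = np.asarray(train_norm.values.todense(), dtype=np.float64)  # p' x N
    columns = []
    col_types = []
    per_type_cols = {}
    for t in types:
        idx = np.flatnonzero(np.asarray(labels, dtype=object) == t)
        if idx.size == 0:
            raise ValueError(f"cell type {t!r} has no cells")
        # Drawing n_draws cells with replacement and averaging is equivalent
        # to a multinomial weight vector over the type's cells.
        weights = rng.multinomial(n_draws, np.full(idx.size, 1.0 / idx.size),
                                  size=n_replicates).astype(np.float64)
        pseudo = X[:, idx] @ (weights.T / n_draws)  # p' x n_replicates
        per_type_cols[t] = pseudo
    if pooling == "per_type":
        for r in range(n_replicates):
            for t in types:
                columns.append(per_type_cols[t][:, r])
                col_types.append(t)
        means = np.column_stack(columns)
    else:
        means = np.mean([per_type_cols[t] for t in types], axis=0)
        col_types = ["pooled"] * n_replicates
    return PriorSample(
        means=means, type_of_column=col_types,
        n_draws=n_draws, n_replicates=n_replicates,
    )


def fit_pca(
    matrix: np.ndarray,
    n_components: int = 100,
    seed: int | None = 0,
) -> PCAProjection:
    """Centered PCA on a features-by-samples matrix.

    If ``n_components`` exceeds the feasible rank it is truncated with a
    warning rather than failing: small prior samples should still yield a
    usable (lower-dimensional) initialization.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n_features, n_samples = matrix.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    feasible = min(n_samples - 1, n_features)
    k = n_components
    if k > feasible:
        logger.warning(
            "requested %d components but feasible rank is %d; truncating",
            n_components, feasible,
        )
        k = feasible
    pca = PCA(n_components=k, random_state=seed)
    pca.fit(matrix.T)
    return PCAProjection(
        components=pca.components_.T.copy(),
        mean_vector=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def make_init_bundle(
    pca_train: PCAProjection,
    pca_reference: Optional[PCAProjection] = None,
    random_width: int = 128,
    seed: int | np.random.Generator = 0,
) -> InitBundle:
    """Package PCA projections and a random block as second-layer init.

    PCA blocks carry the component matrix as weights with bias
    ``-(mean . components)`` so each unit's pre-activation equals the
    centered PCA score.  The random block uses a uniform fan-based scale.
    Without a reference the layer is random(128) + pca_train(100) = 228
    units; a reference appends a third 100-unit block (total 328).
    """
    if random_width <= 0:
        raise ValueError("random_width must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    p = pca_train.components.shape[0]
    limit = np.sqrt(6.0 / (p + random_width))
    blocks = [
        InitBlock(
            name="random",
            weights=rng.uniform(-limit, limit, size=(p, random_width)),
            bias=np.zeros(random_width),
        ),
        InitBlock(
            name="pca_train",
            weights=pca_train.components.copy(),
            bias=-(pca_train.mean_vector @ pca_train.components),
        ),
    ]
    if pca_reference is not None:
        if pca_reference.components.shape[0] != p:
            raise ValueError(
                "reference PCA dimension does not match training dimension"
            )
        blocks.append(
            InitBlock(
                name="pca_reference",
                weights=pca_reference.components.copy(),
                bias=-(pca_reference.mean_vector @ pca_reference.components),
            )
        )
    return InitBundle(blocks=blocks)
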
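"""The reference-guided annotation estimator.

:class:`ContrastiveAnnotator` is a scikit-learn-compatible classifier tying
the whole pipeline together: training-peak selection, TF-IDF normalization,
bootstrap-prior PCA weight initialization (optionally augmented with an
external reference matrix), contrastive MLP training, and cosine-similarity
label transfer with optional entropy-based novel-type detection.

It follows sklearn conventions — ``fit(X, y)`` / ``predict(X)`` on
cell-by-peak matrices, ``get_params``/``set_params``, fitted attributes with
a trailing underscore — so it composes with sklearn model selection.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .annotate import (
    NOVEL_LABEL,
    PredictionResult,
    cluster_test_cells,
    flag_novel,
    predict_known,
)
from .encoder import Embedding, EncoderConfig, embed, train_encoder
from .preprocess import NormalizedMatrix, PeakSelector, TfidfNormalizer
from .prior import build_prior_sample, fit_pca, make_init_bundle

logger = logging.getLogger(__name__)

__all__ = ["ContrastiveAnnotator"]


def _sub_seeds(random_state: int) -> dict[str, int]:
    """Fan one global seed out to named, independent component seeds."""
    ss = np.random.SeedSequence(random_state)
    names = ["bootstrap", "pca", "init", "encoder", "leiden"]
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, c in zip(names, children)
    }


class ContrastiveAnnotator(BaseEstimator, ClassifierMixin):
    """Cell-type annotation by contrastive embedding and label transfer.

    Parameters
    ----------
    min_cell_fraction
        Keep peaks open in at least this fraction of training cells (0.03).
    n_draws, n_replicates
        Bootstrap prior: cells drawn with replacement per pseudo-cell (500)
        and number of replicates (1000).
    n_components
        PCA components for the prior and reference projections (100).
    random_width
        Randomly initialized units in the hidden layer (128); PCA blocks add
        100 units each, so the layer is 228 wide without a reference and 328
        with one.
    output_dim, temperature, n_pairs, pairs_per_step, learning_rate
        Contrastive encoder hyperparameters.
    alpha, entropy_threshold, n_pcs, knn_k
        Novel-type detection: Leiden cluster count target ``alpha * K``,
        mean-entropy cutoff, PCA depth and neighbor count for the test graph.
    prior_pooling
        ``"per_type"`` keeps one pseudo-cell per type per bootstrap
        replicate; ``"per_replicate"`` averages types within a replicate.
    idf_from_train
        Reuse training IDF weights when transforming test data (ablation).
    random_state
        Global seed, fanned out to all stochastic components.
    """

    def __init__(
        self,
        min_cell_fraction: float = 0.03,
        n_draws: int = 500,
        n_replicates: int = 1000,
        n_components: int = 100,
        random_width: int = 128,
        output_dim: int = 64,
        temperature: float = 0.5,
        n_pairs: int = 10000,
        pairs_per_step: int = 64,
        learning_rate: float = 1e-3,
        alpha: float = 1.5,
        entropy_threshold: float = 0.7,
        n_pcs: int = 100,
        knn_k: int = 15,
        prior_pooling: str = "per_type",
        idf_from_train: bool = False,
        random_state: int = 0,
    ):
        self.min_cell_fraction = min_cell_fraction
        self.n_draws = n_draws
        self.n_replicates = n_replicates
        self.n_components = n_components
        self.random_width = random_width
        self.output_dim = output_dim
        self.temperature = temperature
        self.n_pairs = n_pairs
        self.pairs_per_step = pairs_per_step
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.entropy_threshold = entropy_threshold
        self.n_pcs = n_pcs
        self.knn_k = knn_k
        self.prior_pooling = prior_pooling
        self.idf_from_train = idf_from_train
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, reference=None):
        """Fit on a cell-by-peak count matrix and per-cell type labels.

        ``reference``, when given, is a cell-by-peak matrix over the same
        peak space (align it first if it is not); its PCA projection becomes
        an extra hidden-layer block.
        """
        X = sp.csr_matrix(X)
        y = np.asarray(list(y), dtype=object)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length does not match the number of cells")
        self.classes_ = np.asarray(sorted(set(y.tolist())), dtype=object)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 cell types to train")
        self.n_features_in_ = X.shape[1]
        seeds = _sub_seeds(self.random_state)
        self._seeds_ = seeds

        self.selector_ = PeakSelector(self.min_cell_fraction).fit(X)
        Xs = self.selector_.transform(X)
        self.tfidf_ = TfidfNormalizer(idf_from_train=self.idf_from_train).fit(Xs)
        train_norm = self._normalized(Xs, labels=y.tolist())

        prior = build_prior_sample(
            train_norm,
            labels=y.tolist(),
            n_draws=self.n_draws,
            n_replicates=self.n_replicates,
            seed=seeds["bootstrap"],
            pooling=self.prior_pooling,
        )
        pca_train = fit_pca(prior.means, self.n_components, seed=seeds["pca"])
        pca_ref = None
        if reference is not None:
            ref = sp.csr_matrix(reference)
            if ref.shape[1] != self.n_features_in_:
                raise ValueError(
                    "reference peak space differs from the training peak space"
                )
            ref_norm = TfidfNormalizer().fit_transform(self.selector_.transform(ref))
            ref_dense = np.asarray(ref_norm.todense(), dtype=np.float64)
            pca_ref = fit_pca(ref_dense.T, self.n_components, seed=seeds["pca"])
        init = make_init_bundle(
            pca_train, pca_ref, random_width=self.random_width, seed=seeds["init"]
        )
        self.init_bundle_ = init
        self.hidden_width_ = init.total_width
        cfg = EncoderConfig(
            output_dim=self.output_dim,
            temperature=self.temperature,
            n_pairs=self.n_pairs,
            pairs_per_step=self.pairs_per_step,
            learning_rate=self.learning_rate,
            seed=seeds["encoder"],
        )
        self.encoder_ = train_encoder(train_norm, y.tolist(), init, cfg)
        self.train_embedding_ = embed(self.encoder_, train_norm)
        self.train_labels_ = y.tolist()
        return self

    # -------------------------------------------------------------- helpers

    def _normalized(self, X_selected: sp.csr_matrix, labels=None,
                    cell_ids=None) -> NormalizedMatrix:
        V = self.tfidf_.transform(X_selected)
        n = V.shape[0]
        return NormalizedMatrix(
            values=sp.csr_matrix(V.T),
            peaks=[str(i) for i in self.selector_.selected_indices_],
            cell_ids=cell_ids or [f"cell{j}" for j in range(n)],
            labels=labels,
        )

    def _check_test(self, X) -> NormalizedMatrix:
        check_is_fitted(self, "encoder_")
        X = sp.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} peaks, fit used {self.n_features_in_}"
            )
        Xs = self.selector_.transform(X)
        present = np.asarray((Xs != 0).sum(axis=0)).ravel() > 0
        missing = 1.0 - present.mean()
        if missing >= 1.0:
            raise ValueError("test matrix has no signal on any selected peak")
        if missing > 0.9:
            logger.warning(
                "test matrix lacks signal on %.0f%% of selected peaks",
                100 * missing,
            )
        return self._normalized(Xs)

    # ---------------------------------------------------------- predictions

    def annotate(self, X, detect_novel: bool = False) -> list[PredictionResult]:
        """Full per-cell results: label, similarity profile, entropy, cluster."""
        test_norm = self._check_test(X)
        test_emb = embed(self.encoder_, test_norm)
        results = predict_known(
            test_emb, self.train_embedding_, self.train_labels_,
            temperature=self.temperature,
        )
        if detect_novel:
            clusters = cluster_test_cells(
                test_norm,
                n_type=self.classes_.size,
                alpha=self.alpha,
                n_pcs=self.n_pcs,
                knn_k=self.knn_k,
                seed=self._seeds_["leiden"],
            )
            results = flag_novel(results, clusters, threshold=self.entropy_threshold)
        return results

    def predict(self, X) -> np.ndarray:
        """Closed-set labels (one of the training types per cell)."""
        return np.asarray(
            [r.predicted_type for r in self.annotate(X, detect_novel=False)],
            dtype=object,
        )

    def predict_open(self, X) -> np.ndarray:
        """Open-set labels: training types plus the reserved name "novel"."""
        return np.asarray(
            [r.predicted_type for r in self.annotate(X, detect_novel=True)],
            dtype=object,
        )

    def decision_function(self, X) -> np.ndarray:
        """Per-type mean cosine-similarity profiles (n_cells x K)."""
        results = self.annotate(X, detect_novel=False)
        return np.vstack([r.profile.per_type_mean for r in results])

    def transform(self, X) -> np.ndarray:
        """Contrastive embeddings of the cells (n_cells x output_dim)."""
        return embed(self.encoder_, self._check_test(X)).vectors

    def score(self, X, y) -> float:
        from .metrics import accuracy

        return accuracy(list(y), list(self.predict(X)))
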
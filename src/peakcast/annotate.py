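"""Label transfer and open-set (novel cell type) detection.

A test cell is labelled with the training type whose cells are, on average,
most cosine-similar to it in the learned embedding space.  The per-type
mean-similarity profile also yields an uncertainty score: similarities are
converted to probabilities by a softmax and the Shannon entropy of the
resulting distribution, normalized by ln K, gives a value in [0, 1].  In
the full pipeline the softmax temperature equals the model's contrastive
temperature tau — the training loss already treats sim/tau as logits, so
softmax(s/tau) is the model's own probabilistic reading of a similarity
profile.  Cells of a type never seen in training match nothing well, so
their profiles are comparatively flat and their entropy high.

Novel-type detection is cluster-level rather than per-cell: the test set is
clustered (Leiden on a k-nearest-neighbor graph over PCA of the normalized
test matrix, with the cluster count targeted at ``round(alpha * n_type)``,
alpha = 1.5 by default) and every cell in a cluster whose mean prediction
entropy, measured in nats, strictly exceeds the threshold (default 0.7) is
re-labelled "novel".  The nats scale makes the fixed 0.7 cutoff sit between
confidently matched cells (whose entropy is bounded below by the simplex
geometry of K mutually separated embedding clusters, about 0.65 nats at
K = 4) and unmatched ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoder import EPS_NORM, Embedding
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

NOVEL_LABEL = "novel"

__all__ = [
    "SimilarityProfile",
    "PredictionResult",
    "predict_known",
    "prediction_entropy",
    "cluster_test_cells",
    "flag_novel",
    "NOVEL_LABEL",
]


@dataclass
class SimilarityProfile:
    per_type_mean: np.ndarray
    type_names: list[str]


@dataclass
class PredictionResult:
    cell_id: str
    predicted_type: str
    profile: SimilarityProfile
    entropy: float
    cluster_id: int = -1


def _unit_rows(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    return Z / (norms + EPS_NORM)


def predict_known(
    test_emb: Embedding,
    train_emb: Embedding,
    train_labels: Sequence[str],
    temperature: float = 1.0,
) -> list[PredictionResult]:
    """Closed-set annotation by per-type mean cosine similarity.

    Ties in the profile maximum are broken towards the alphabetically first
    type name and logged.
    """
    train_labels = list(train_labels)
    if len(train_labels) != train_emb.vectors.shape[0]:
        raise ValueError("train labels length does not match embeddings")
    if test_emb.vectors.shape[1] != train_emb.vectors.shape[1]:
        raise ValueError("embedding dimensionalities differ")
    types = sorted(set(train_labels))
    lab = np.asarray(train_labels, dtype=object)
    trainN = _unit_rows(train_emb.vectors)
    # mean cosine to a type = dot with the mean of that type's unit vectors
    type_means = np.vstack([trainN[lab == t].mean(axis=0) for t in types])
    for t in types:
        if not np.any(lab == t):
            raise ValueError(f"training type {t!r} has no cells")
    testN = _unit_rows(test_emb.vectors)
    profiles = testN @ type_means.T  # n_test x K
    results = []
    for i, cid in enumerate(test_emb.cell_ids):
        row = profiles[i]
        best = int(np.argmax(row))
        ties = np.flatnonzero(row == row[best])
        if ties.size > 1:
            logger.info(
                "cell %s: tie between %s; keeping %s",
                cid, [types[j] for j in ties], types[best],
            )
        prof = SimilarityProfile(per_type_mean=row.copy(), type_names=list(types))
        results.append(
            PredictionResult(
                cell_id=cid,
                predicted_type=types[best],
                profile=prof,
                entropy=prediction_entropy(prof, temperature=temperature),
            )
        )
    return results


def prediction_entropy(
    profile: SimilarityProfile | np.ndarray, temperature: float = 1.0
) -> float:
    """Normalized entropy of the softmax of per-type mean similarities.

    Similarities can be negative, so a softmax (with the given temperature)
    converts the profile to a probability vector; Shannon entropy is then
    divided by ln K to land in [0, 1] regardless of the number of types.
    The pipeline passes the model's contrastive temperature here.
    """
    s = (
        profile.per_type_mean
        if isinstance(profile, SimilarityProfile)
        else np.asarray(profile, dtype=np.float64)
    )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    K = s.shape[0]
    if K < 2:
        raise ValueError("entropy needs at least 2 types")
    z = s / temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / np.log(K))


def target_cluster_count(n_type: int, alpha: float = 1.5) -> int:
    """Number of Leiden clusters to aim for: alpha * n_type, rounded half-up."""
    return int(np.floor(alpha * n_type + 0.5))


def cluster_test_cells(
    test_norm: NormalizedMatrix,
    n_type: int,
    alpha: float = 1.5,
    n_pcs: int = 100,
    knn_k: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden clustering of test cells at a targeted cluster count.

    PCA (up to ``n_pcs`` components, truncated to the feasible rank) of the
    normalized test matrix feeds a k-nearest-neighbor graph; the Leiden
    resolution is found by bisection on [1e-3, 50] until the cluster count
    equals ``round(alpha * n_type)`` (at most 40 iterations; the closest
    achievable count is accepted and logged if the exact target is not
    attained).
    """
    import igraph
    import leidenalg
    import scanpy as sc
    from anndata import AnnData
    from sklearn.decomposition import PCA

    target = target_cluster_count(n_type, alpha)
    X = test_norm.cells_by_peaks()
    n_cells = X.shape[0]
    if n_cells < target:
        raise ValueError(
            f"{n_cells} cells cannot form {target} clusters"
        )
    k = min(n_pcs, n_cells - 1, X.shape[1])
    scores = PCA(n_components=k, random_state=seed).fit_transform(X)
    adata = AnnData(X=scores.astype(np.float32))
    sc.pp.neighbors(
        adata, n_neighbors=min(knn_k, n_cells - 1), use_rep="X",
        random_state=seed,
    )
    conn = adata.obsp["connectivities"].tocoo()
    mask = conn.row < conn.col
    g = igraph.Graph(
        n=n_cells,
        edges=list(zip(conn.row[mask], conn.col[mask])),
        edge_attrs={"weight": conn.data[mask]},
    )

    def leiden(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)

    lo, hi = 1e-3, 50.0
    best = leiden(lo)
    best_gap = abs(len(set(best)) - target)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        memb = leiden(mid)
        count = len(set(memb))
        gap = abs(count - target)
        if gap < best_gap:
            best, best_gap = memb, gap
        if count == target:
            return memb
        if count < target:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "Leiden bisection did not reach %d clusters; closest count %d",
        target, len(set(best)),
    )
    return best


def flag_novel(
    results: list[PredictionResult],
    clusters: np.ndarray,
    threshold: float = 0.7,
    scale: str = "nats",
) -> list[PredictionResult]:
    """Re-label every cell in a high-mean-entropy cluster as novel.

    A cluster is flagged when its mean prediction entropy is strictly above
    ``threshold``; other cells keep their argmax labels.  With
    ``scale="nats"`` (default) the stored normalized entropies are converted
    back to nats (multiplied by ln K) before comparison, so the canonical
    0.7 cutoff has a K-independent meaning in absolute information units;
    ``scale="normalized"`` compares on the [0, 1] scale directly.  Cluster
    ids are recorded on the results either way.
    """
    clusters = np.asarray(clusters)
    if clusters.shape[0] != len(results):
        raise ValueError("cluster assignment length does not match results")
    if scale not in ("nats", "normalized"):
        raise ValueError(f"unknown entropy scale {scale!r}")
    entropies = np.asarray([r.entropy for r in results])
    if scale == "nats":
        K = len(results[0].profile.type_names)
        entropies = entropies * np.log(K)
    flagged = set()
    for c in np.unique(clusters):
        members = clusters == c
        if entropies[members].mean() > threshold:
            flagged.add(int(c))
    out = []
    for r, c in zip(results, clusters):
        out.append(
            PredictionResult(
                cell_id=r.cell_id,
                predicted_type=NOVEL_LABEL if int(c) in flagged else r.predicted_type,
                profile=r.profile,
                entropy=r.entropy,
                cluster_id=int(c),
            )
        )
    return out
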
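"""Peak selection and TF-IDF normalization.

scCAS count matrices are near-binary and extremely sparse; the standard
normalization treats cells as documents and peaks as terms.  The importance
of peak ``i`` for cell ``j`` is

    x'_ij = ( x_ij / sum_i x_ij ) * ln( n / sum_j x_ij )

(term frequency within the cell times log inverse total accessibility of
the peak, with ``n`` the number of cells in the matrix being transformed),
followed by per-cell L2 normalization

    v_ij = x'_ij / sqrt( sum_i x'_ij^2 ).

Note the IDF uses raw row sums, not binarized document frequency; a peak
whose total count exceeds ``n`` therefore gets a negative weight.  We keep
the formula as-is rather than clipping.  Zero totals are guarded: an
all-zero cell stays all-zero, and a zero-total peak contributes nothing.

Peak selection retains peaks with at least one read count in at least a
fraction ``min_cell_fraction`` (default 3%) of training cells; the selected
indices are the only preprocessing state carried from training to the
reference and test sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_io import PeakMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSelector",
    "TfidfNormalizer",
    "PreprocessModel",
    "NormalizedMatrix",
    "fit_peak_selection",
    "tfidf_transform",
]


class PeakSelector(BaseEstimator, TransformerMixin):
    """Select peaks open in at least ``min_cell_fraction`` of cells.

    Operates on cell-by-peak arrays (sklearn orientation).  A peak is kept
    when the number of cells with a count of at least one reaches
    ``min_cell_fraction * n_cells``, compared against the exact real-valued
    threshold (no rounding of the cutoff).
    """

    def __init__(self, min_cell_fraction: float = 0.03):
        self.min_cell_fraction = min_cell_fraction

    def fit(self, X, y=None):
        if not 0 < self.min_cell_fraction <= 1:
            raise ValueError("min_cell_fraction must be in (0, 1]")
        X = sp.csc_matrix(X)
        n_cells = X.shape[0]
        if n_cells < 1:
            raise ValueError("need at least one cell")
        cells_with_signal = (X >= 1).sum(axis=0).A1
        threshold = self.min_cell_fraction * n_cells
        self.support_ = cells_with_signal >= threshold
        self.selected_indices_ = np.flatnonzero(self.support_)
        if self.selected_indices_.size == 0:
            raise ValueError(
                "no peak passes the selection threshold; lower min_cell_fraction"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        X = sp.csc_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} peaks, selector was fit on {self.n_features_in_}"
            )
        return X[:, self.selected_indices_].tocsr()

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class TfidfNormalizer(BaseEstimator, TransformerMixin):
    """TF-IDF with per-cell L2 normalization, on cell-by-peak arrays.

    By default each matrix is transformed with its own statistics (``n`` and
    peak totals of the matrix at hand), matching how training and test sets
    are each normalized internally; only the selected-peak indices travel
    between datasets.  With ``idf_from_train=True`` the IDF weights fitted on
    the training matrix are reused at transform time (an ablation switch).
    """

    def __init__(self, idf_from_train: bool = False):
        self.idf_from_train = idf_from_train

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        self.n_features_in_ = X.shape[1]
        self.idf_ = self._idf(X)
        return self

    @staticmethod
    def _idf(X: sp.csr_matrix) -> np.ndarray:
        n_cells = X.shape[0]
        peak_totals = np.asarray(X.sum(axis=0)).ravel()
        idf = np.zeros_like(peak_totals, dtype=np.float64)
        nz = peak_totals > 0
        idf[nz] = np.log(n_cells / peak_totals[nz])
        return idf

    def transform(self, X):
        X = sp.csr_matrix(X).astype(np.float64)
        if X.nnz and X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.idf_from_train:
            check_is_fitted(self, "idf_")
            if X.shape[1] != self.n_features_in_:
                raise ValueError("peak dimension differs from the fitted matrix")
            idf = self.idf_
        else:
            idf = self._idf(X)
        cell_totals = np.asarray(X.sum(axis=1)).ravel()
        inv_tot = np.divide(
            1.0, cell_totals, out=np.zeros_like(cell_totals, dtype=np.float64),
            where=cell_totals > 0,
        )
        tf = sp.diags(inv_tot) @ X
        xprime = tf @ sp.diags(idf)
        xprime = sp.csr_matrix(xprime)
        norms = np.sqrt(np.asarray(xprime.multiply(xprime).sum(axis=1)).ravel())
        inv_norm = np.divide(
            1.0, norms, out=np.zeros_like(norms), where=norms > 0
        )
        return sp.csr_matrix(sp.diags(inv_norm) @ xprime)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


@dataclass
class PreprocessModel:
    """Frozen preprocessing state: which training peaks were selected.

    Serialized as a JSON sidecar so prediction runs reproduce the selection
    bit-exactly.
    """

    selected_rows: np.ndarray
    selected_peaks: list[str]
    min_cell_fraction: float = 0.03

    def __post_init__(self):
        self.selected_rows = np.asarray(self.selected_rows, dtype=int)
        if self.selected_rows.size == 0:
            raise ValueError("empty peak selection")
        if np.any(np.diff(self.selected_rows) <= 0):
            raise ValueError("selected_rows must be strictly increasing")
        if len(self.selected_peaks) != self.selected_rows.size:
            raise ValueError("selected_peaks inconsistent with selected_rows")

    def apply(self, m: PeakMatrix) -> PeakMatrix:
        """Restrict a peak-by-cell matrix to the selected training peaks."""
        if int(self.selected_rows.max()) >= m.n_peaks:
            raise ValueError("matrix has fewer peaks than the selection expects")
        return m.subset_peaks(self.selected_rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_rows": self.selected_rows.tolist(),
            "selected_peaks": self.selected_peaks,
            "min_cell_fraction": self.min_cell_fraction,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            selected_rows=np.asarray(payload["selected_rows"], dtype=int),
            selected_peaks=payload["selected_peaks"],
            min_cell_fraction=payload["min_cell_fraction"],
        )


@dataclass
class NormalizedMatrix:
    """TF-IDF-normalized values, peaks as rows, cells as columns."""

    values: sp.csr_matrix
    peaks: list[str]
    cell_ids: list[str]
    labels: Optional[list[str]] = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_by_peaks(self) -> np.ndarray:
        """Dense cell-by-peak array for the encoder."""
        return np.asarray(self.values.T.todense(), dtype=np.float64)


def fit_peak_selection(train: PeakMatrix, min_cell_fraction: float = 0.03) -> PreprocessModel:
    """Fit the training peak selection on a peak-by-cell matrix."""
    sel = PeakSelector(min_cell_fraction=min_cell_fraction).fit(train.counts.T)
    rows = sel.selected_indices_
    keys = train.peak_keys
    logger.info(
        "peak selection: kept %d/%d peaks at min_cell_fraction=%g",
        rows.size, train.n_peaks, min_cell_fraction,
    )
    return PreprocessModel(
        selected_rows=rows,
        selected_peaks=[keys[i] for i in rows],
        min_cell_fraction=min_cell_fraction,
    )


def tfidf_transform(m: PeakMatrix) -> NormalizedMatrix:
    """TF-IDF-normalize a (selection-restricted) peak-by-cell matrix."""
    vals = TfidfNormalizer().fit_transform(m.counts.T)
    return NormalizedMatrix(
        values=sp.csr_matrix(vals.T),
        peaks=m.peak_keys,
        cell_ids=m.cell_ids,
        labels=m.labels,
    )
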
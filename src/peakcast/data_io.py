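"""Readers and writers for peak-by-cell matrices.

The on-disk convention follows common scATAC-seq practice: a sparse
matrix-market file with peaks as rows and cells as columns, a BED file
giving the genomic interval of each peak (same order as the matrix rows),
and a two-column TSV mapping cell barcodes to cell-type labels.  Peaks are
identified by their canonical ``chrom:start-end`` string (0-based,
half-open, BED convention); matching between datasets is exact string
matching on that key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakMatrix",
    "read_peak_matrix",
    "write_peak_matrix",
    "align_to_peaks",
    "from_anndata",
]


@dataclass(frozen=True)
class Peak:
    """A genomic interval used as an accessibility feature."""

    chrom: str
    start: int
    end: int

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_key(cls, key: str) -> "Peak":
        chrom, rest = key.rsplit(":", 1)
        start, end = rest.split("-")
        return cls(chrom, int(start), int(end))


@dataclass
class PeakMatrix:
    """A peak-by-cell count matrix with peak coordinates and optional labels.

    ``counts`` is a ``scipy.sparse.csr_matrix`` of shape (p peaks, N cells)
    with non-negative entries.  ``labels``, when present, holds one cell-type
    name per cell.
    """

    counts: sp.csr_matrix
    peaks: list[Peak]
    cell_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        p, n = self.counts.shape
        if len(self.peaks) != p:
            raise ValueError(
                f"matrix has {p} rows but {len(self.peaks)} peaks were given"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"matrix has {n} columns but {len(self.cell_ids)} cell ids were given"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        keys = [pk.key for pk in self.peaks]
        seen: set[str] = set()
        for k in keys:
            if k in seen:
                raise ValueError(f"duplicate canonical peak: {k}")
            seen.add(k)
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError(
                    f"{len(self.labels)} labels for {n} cells"
                )
            if any(not isinstance(l, str) or not l for l in self.labels):
                raise ValueError("labels must be non-empty strings")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def peak_keys(self) -> list[str]:
        return [pk.key for pk in self.peaks]

    def subset_cells(self, index: np.ndarray) -> "PeakMatrix":
        index = np.asarray(index)
        return PeakMatrix(
            counts=self.counts[:, index].tocsr(),
            peaks=self.peaks,
            cell_ids=[self.cell_ids[i] for i in index],
            labels=None if self.labels is None else [self.labels[i] for i in index],
        )

    def subset_peaks(self, rows: Sequence[int]) -> "PeakMatrix":
        rows = np.asarray(rows)
        return PeakMatrix(
            counts=self.counts[rows, :].tocsr(),
            peaks=[self.peaks[i] for i in rows],
            cell_ids=self.cell_ids,
            labels=self.labels,
        )


def _read_bed(peaks_path: Path) -> list[Peak]:
    peaks = []
    with open(peaks_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with fewer than 3 columns: {line!r}")
            peaks.append(Peak(parts[0], int(parts[1]), int(parts[2])))
    return peaks


def read_peak_matrix(
    matrix_path: str | Path,
    peaks_path: str | Path,
    labels_path: str | Path | None = None,
    transpose: bool = False,
) -> PeakMatrix:
    """Read an MTX + BED (+ labels TSV) triple into a :class:`PeakMatrix`.

    Parameters
    ----------
    matrix_path
        Sparse matrix-market file, peaks as rows unless ``transpose``.
    peaks_path
        BED file; the first three columns define the peaks, in matrix-row
        order.
    labels_path
        Optional TSV with header ``cell_id<TAB>cell_type``.  Required for
        training data, optional for test data.
    transpose
        Set when the matrix on disk is cell-by-peak.
    """
    counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
    if transpose:
        counts = counts.T.tocsr()
    peaks = _read_bed(Path(peaks_path))
    if counts.shape[0] != len(peaks):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but BED file has "
            f"{len(peaks)} peaks"
        )
    cell_ids = [f"cell{j}" for j in range(counts.shape[1])]
    labels = None
    if labels_path is not None:
        tbl = pd.read_csv(labels_path, sep="\t", dtype=str)
        if tbl.shape[1] < 2:
            raise ValueError("labels TSV needs columns cell_id and cell_type")
        if len(tbl) != counts.shape[1]:
            raise ValueError(
                f"matrix has {counts.shape[1]} cells but labels file has "
                f"{len(tbl)} rows"
            )
        cell_ids = tbl.iloc[:, 0].tolist()
        labels = tbl.iloc[:, 1].tolist()
    return PeakMatrix(counts=counts, peaks=peaks, cell_ids=cell_ids, labels=labels)


def write_peak_matrix(m: PeakMatrix, out_dir: str | Path, prefix: str = "matrix") -> dict:
    """Write a :class:`PeakMatrix` as MTX + BED (+ labels TSV); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mtx = out / f"{prefix}.mtx"
    bed = out / f"{prefix}_peaks.bed"
    scipy.io.mmwrite(mtx, m.counts.tocoo())
    with open(bed, "w") as fh:
        for pk in m.peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
    paths = {"matrix": mtx, "peaks": bed}
    if m.labels is not None:
        tsv = out / f"{prefix}_labels.tsv"
        pd.DataFrame({"cell_id": m.cell_ids, "cell_type": m.labels}).to_csv(
            tsv, sep="\t", index=False
        )
        paths["labels"] = tsv
    return paths


def align_to_peaks(ref: PeakMatrix, target_peaks: Sequence[Peak | str]) -> PeakMatrix:
    """Project a reference matrix onto a target peak space.

    Rows of the result follow ``target_peaks`` order; peaks absent from the
    reference become all-zero rows.  Raises if no peak matches at all, since
    a reference sharing no feature space carries no usable prior.
    """
    if len(target_peaks) == 0:
        raise ValueError("target peak list is empty")
    targets = [pk if isinstance(pk, Peak) else Peak.from_key(pk) for pk in target_peaks]
    ref_index = {pk.key: i for i, pk in enumerate(ref.peaks)}
    rows = sp.lil_matrix((len(targets), ref.n_cells), dtype=ref.counts.dtype)
    matched = 0
    ref_csr = ref.counts.tocsr()
    for out_i, pk in enumerate(targets):
        src = ref_index.get(pk.key)
        if src is not None:
            rows[out_i, :] = ref_csr[src, :]
            matched += 1
    frac = matched / len(targets)
    logger.info("align_to_peaks: matched %d/%d target peaks (%.3f)", matched, len(targets), frac)
    if matched == 0:
        raise ValueError("reference shares no peaks with the target peak space")
    return PeakMatrix(
        counts=rows.tocsr(),
        peaks=targets,
        cell_ids=ref.cell_ids,
        labels=ref.labels,
    )


def from_anndata(path: str | Path, label_key: str = "cell_type") -> PeakMatrix:
    """Thin adapter for a containerized single-cell matrix file (.h5ad).

    Expects cells in ``obs`` and peaks in ``var`` with either a
    ``chrom/start/end`` triple or ``chrom:start-end`` var names.  Failures
    here never block the MTX path; callers should catch and fall back.
    """
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = sp.csr_matrix(adata.X).T.tocsr()  # AnnData is cell-by-feature
    if {"chrom", "start", "end"}.issubset(adata.var.columns):
        peaks = [
            Peak(str(c), int(s), int(e))
            for c, s, e in zip(adata.var["chrom"], adata.var["start"], adata.var["end"])
        ]
    else:
        peaks = [Peak.from_key(v) for v in adata.var_names]
    labels = (
        adata.obs[label_key].astype(str).tolist()
        if label_key in adata.obs.columns
        else None
    )
    return PeakMatrix(
        counts=X, peaks=peaks, cell_ids=adata.obs_names.tolist(), labels=labels
    )
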
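"""Synthetic scCAS-like data with known ground truth.

Real single-cell chromatin accessibility matrices are near-binary and
extremely sparse (typically ~99% zeros), with each cell type distinguished
by a modest set of type-specific accessible peaks.  The generator emulates
exactly that structure: every type owns a contiguous signature block of
peaks where entries are accessible at a high foreground rate ``q1``, while
all other entries fire at a low background rate ``q0``.  Adjacent types'
blocks can overlap by a tunable ``shared_fraction``, making signature
overlap — and hence annotation difficulty — a single monotone knob.
Cell-type imbalance is set directly through ``cells_per_type``, and extra
sparsification is available via an entry-wise dropout that zeroes nonzero
entries with a fixed probability, mimicking lower sequencing depth.

What the generator does not emulate: batch effects, fragment-level counts,
co-accessibility between distant peaks, or peak-calling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .data_io import Peak, PeakMatrix

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "simulate_dataset", "apply_dropout", "drop_types"]


@dataclass
class SimConfig:
    """Configuration of the synthetic scCAS generator.

    Defaults target the regimes of typical published scATAC-seq collections:
    sparsity around 0.99, a handful of cell types, mild imbalance.
    """

    n_types: int = 5
    cells_per_type: Sequence[int] = (200, 200, 200, 200, 200)
    n_peaks: int = 5000
    peaks_per_type: int = 100
    background_rate: float = 0.005
    foreground_rate: float = 0.2
    shared_fraction: float = 0.2
    dropout_rate: float = 0.0
    count_model: str = "bernoulli"  # or "poisson"
    poisson_fg: float = 1.5
    poisson_bg: float = 0.05
    novel_types: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        if not self.background_rate < self.foreground_rate <= 1:
            raise ValueError("need background_rate < foreground_rate <= 1")
        if not 0 <= self.shared_fraction < 1:
            raise ValueError("shared_fraction must be in [0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.peaks_per_type * self.n_types > self.n_peaks:
            raise ValueError("peaks_per_type * n_types exceeds n_peaks")
        if sum(self.cells_per_type) < self.n_types:
            raise ValueError("need at least one cell per type")
        if self.count_model not in ("bernoulli", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")

    @property
    def type_names(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_types)]

    def signature_block(self, k: int) -> tuple[int, int]:
        """Half-open peak-index range of type k's accessible signature."""
        offset = int(round(self.peaks_per_type * (1.0 - self.shared_fraction)))
        offset = max(offset, 1)
        start = k * offset
        return start, start + self.peaks_per_type


def _make_peaks(p: int) -> list[Peak]:
    return [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(p)]


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[PeakMatrix, PeakMatrix, dict]:
    """Generate a (train, test, truth) triple under ``cfg``.

    Cells are split 50/50 into train and test, stratified by type; types in
    ``cfg.novel_types`` are removed from the training half only.  The truth
    dict records the signature blocks, type labels and the config used.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_peaks
    blocks = {t: cfg.signature_block(k) for k, t in enumerate(cfg.type_names)}
    cols = []
    labels = []
    for k, t in enumerate(cfg.type_names):
        n_k = cfg.cells_per_type[k]
        lo, hi = blocks[t]
        if cfg.count_model == "bernoulli":
            block = (rng.random((hi - lo, n_k)) < cfg.foreground_rate).astype(np.int64)
            bg = (rng.random((p, n_k)) < cfg.background_rate).astype(np.int64)
        else:
            block = rng.poisson(cfg.poisson_fg, size=(hi - lo, n_k))
            bg = rng.poisson(cfg.poisson_bg, size=(p, n_k))
        bg[lo:hi, :] = block
        cols.append(bg)
        labels.extend([t] * n_k)
    counts = np.concatenate(cols, axis=1)
    n = counts.shape[1]
    cell_ids = [f"cell{j:05d}" for j in range(n)]
    full = PeakMatrix(
        counts=sp.csr_matrix(counts),
        peaks=_make_peaks(p),
        cell_ids=cell_ids,
        labels=labels,
    )
    if cfg.dropout_rate > 0:
        full = apply_dropout(full, cfg.dropout_rate, seed=rng)

    lab_arr = np.asarray(labels, dtype=object)
    train_idx, test_idx = [], []
    for t in cfg.type_names:
        idx = np.flatnonzero(lab_arr == t)
        perm = rng.permutation(idx)
        half = len(perm) // 2
        train_idx.extend(perm[:half])
        test_idx.extend(perm[half:])
    train = full.subset_cells(np.sort(train_idx))
    test = full.subset_cells(np.sort(test_idx))
    novel = list(cfg.novel_types)
    if novel:
        train = drop_types(train, novel)
    truth = {
        "signature_blocks": {t: list(b) for t, b in blocks.items()},
        "novel_types": novel,
        "train_labels": train.labels,
        "test_labels": test.labels,
        "config": {
            "n_types": cfg.n_types,
            "cells_per_type": list(cfg.cells_per_type),
            "n_peaks": cfg.n_peaks,
            "peaks_per_type": cfg.peaks_per_type,
            "background_rate": cfg.background_rate,
            "foreground_rate": cfg.foreground_rate,
            "shared_fraction": cfg.shared_fraction,
            "dropout_rate": cfg.dropout_rate,
            "count_model": cfg.count_model,
            "seed": cfg.seed,
        },
    }
    return train, test, truth


def apply_dropout(
    m: PeakMatrix, rate: float, seed: int | np.random.Generator = 0
) -> PeakMatrix:
    """Zero each nonzero entry independently with probability ``rate``.

    Mimics reduced coverage: zeros stay zero, signal is thinned.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return m
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    counts = m.counts.tocsr(copy=True)
    keep = rng.random(counts.nnz) >= rate
    counts.data = counts.data * keep
    counts.eliminate_zeros()
    return PeakMatrix(
        counts=counts, peaks=m.peaks, cell_ids=m.cell_ids, labels=m.labels
    )


def drop_types(train: PeakMatrix, types_to_remove: Sequence[str]) -> PeakMatrix:
    """Remove all cells of the named types (novel-type withholding protocol)."""
    if train.labels is None:
        raise ValueError("matrix has no labels")
    present = set(train.labels)
    for t in types_to_remove:
        if t not in present:
            logger.warning("type %r not present in the matrix; nothing to remove", t)
    remove = set(types_to_remove)
    keep = np.asarray([l not in remove for l in train.labels])
    return train.subset_cells(np.flatnonzero(keep))
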
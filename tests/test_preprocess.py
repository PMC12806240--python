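import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from peakcast.data_io import PeakMatrix
from peakcast.preprocess import (
    NormalizedMatrix,
    PeakSelector,
    PreprocessModel,
    TfidfNormalizer,
    fit_peak_selection,
    tfidf_transform,
)

from conftest import make_peaks, random_peak_matrix


def naive_tfidf(X):
    """Independent double-loop implementation of the TF-IDF + L2 transform."""
    X = np.asarray(X, dtype=float)
    p, n = X.shape
    col_sums = X.sum(axis=0)
    row_sums = X.sum(axis=1)
    xp = np.zeros_like(X)
    for i in range(p):
        for j in range(n):
            if X[i, j] == 0 or col_sums[j] == 0 or row_sums[i] == 0:
                continue
            xp[i, j] = (X[i, j] / col_sums[j]) * np.log(n / row_sums[i])
    v = np.zeros_like(xp)
    for j in range(n):
        norm = np.sqrt((xp[:, j] ** 2).sum())
        if norm > 0:
            v[:, j] = xp[:, j] / norm
    return v


def as_pm(dense, labels=None):
    dense = np.asarray(dense)
    return PeakMatrix(
        counts=sp.csr_matrix(dense),
        peaks=make_peaks(dense.shape[0]),
        cell_ids=[f"c{j}" for j in range(dense.shape[1])],
        labels=labels,
    )


class TestPeakSelection:
    def test_threshold_counting(self):
        # peak0 open in 3 cells (3 >= 0.03*100), peak1 in 2 (< 3), peak2 in 50, peak3 in 0
        X = np.zeros((4, 100))
        X[0, :3] = 1
        X[1, :2] = 1
        X[2, :50] = 1
        model = fit_peak_selection(as_pm(X), min_cell_fraction=0.03)
        assert model.selected_rows.tolist() == [0, 2]

    def test_tiny_fraction_keeps_all_signalled_peaks(self):
        X = np.eye(5)
        model = fit_peak_selection(as_pm(X), min_cell_fraction=1e-9)
        assert model.selected_rows.tolist() == [0, 1, 2, 3, 4]

    def test_matches_brute_force(self, rng):
        pm = random_peak_matrix(rng, p=200, n=60, density=0.05, with_labels=False)
        frac = 0.05
        X = pm.counts.toarray()
        expected = [
            i for i in range(200)
            if sum(1 for j in range(60) if X[i, j] >= 1) >= frac * 60
        ]
        model = fit_peak_selection(pm, min_cell_fraction=frac)
        assert model.selected_rows.tolist() == expected

    def test_empty_selection_raises(self):
        X = np.zeros((3, 100))
        X[0, 0] = 1
        with pytest.raises(ValueError, match="lower min_cell_fraction"):
            fit_peak_selection(as_pm(X), min_cell_fraction=0.5)

    def test_selection_is_idempotent(self, rng):
        pm = random_peak_matrix(rng, p=100, n=40, density=0.2, with_labels=False)
        model = fit_peak_selection(pm, min_cell_fraction=0.05)
        restricted = model.apply(pm)
        again = fit_peak_selection(restricted, min_cell_fraction=0.05)
        assert again.selected_rows.tolist() == list(range(restricted.n_peaks))

    def test_model_json_round_trip(self, rng, tmp_path):
        pm = random_peak_matrix(rng, p=60, n=30, density=0.2, with_labels=False)
        model = fit_peak_selection(pm)
        model.to_json(tmp_path / "prep.json")
        back = PreprocessModel.from_json(tmp_path / "prep.json")
        assert np.array_equal(back.selected_rows, model.selected_rows)
        assert back.selected_peaks == model.selected_peaks
        assert back.min_cell_fraction == model.min_cell_fraction


class TestTfidf:
    def test_hand_computed_identity_case(self):
        out = tfidf_transform(as_pm([[1, 0], [0, 1]]))
        dense = out.values.toarray()
        # x' = [[ln2, 0], [0, ln2]]; after L2 each column is a unit basis vector
        assert np.allclose(dense, np.eye(2), atol=1e-12)

    def test_zero_column_stays_zero(self):
        out = tfidf_transform(as_pm([[1, 0], [2, 0]]))
        assert np.allclose(out.values.toarray()[:, 1], 0)

    def test_matches_naive_double_loop(self, rng):
        pm = random_peak_matrix(rng, p=100, n=30, density=0.1, with_labels=False)
        out = tfidf_transform(pm).values.toarray()
        expected = naive_tfidf(pm.counts.toarray())
        assert np.allclose(out, expected, atol=1e-10)

    def test_nonzero_columns_have_unit_norm(self, rng):
        pm = random_peak_matrix(rng, p=80, n=25, density=0.15, with_labels=False)
        out = tfidf_transform(pm).values.toarray()
        norms = np.linalg.norm(out, axis=0)
        nonzero = pm.counts.toarray().sum(axis=0) > 0
        assert np.allclose(norms[nonzero], 1.0, atol=1e-6)
        assert np.allclose(norms[~nonzero], 0.0)

    def test_count_scaling_acts_only_through_idf(self, rng):
        # term frequencies cancel a global scale; only the IDF argument sees
        # it: x'(cX) = tf(X) * (log(n / rowsum) - log c) entrywise
        X = (rng.random((40, 12)) < 0.2).astype(float) + (rng.random((40, 12)) < 0.05)
        X[:, 0] = 0
        c = 3.0
        n = X.shape[1]
        col = X.sum(axis=0, keepdims=True)
        row = X.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            tf = np.where(col > 0, X / col, 0.0)
            idf = np.where(row > 0, np.log(n / row) - np.log(c), 0.0)
        expected = tf * idf
        norms = np.linalg.norm(expected, axis=0, keepdims=True)
        expected = np.divide(expected, norms, out=np.zeros_like(expected),
                             where=norms > 0)
        got = tfidf_transform(as_pm(c * X)).values.toarray()
        assert np.allclose(got, expected, atol=1e-10)

    def test_negative_entries_rejected(self):
        t = TfidfNormalizer()
        with pytest.raises(ValueError, match="non-negative"):
            t.transform(sp.csr_matrix(np.array([[1.0, -1.0]])))

    def test_idf_from_train_reuses_weights(self, rng):
        Xtr = sp.csr_matrix((rng.random((30, 50)) < 0.3).astype(float))
        Xte = sp.csr_matrix((rng.random((10, 50)) < 0.3).astype(float))
        frozen = TfidfNormalizer(idf_from_train=True).fit(Xtr)
        fresh = TfidfNormalizer().fit(Xte)
        out_frozen = frozen.transform(Xte).toarray()
        out_fresh = fresh.transform(Xte).toarray()
        assert not np.allclose(out_frozen, out_fresh)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_tfidf_norm_property_random_matrices(seed):
    """Every nonzero cell maps to a unit vector; zero cells stay zero."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(rng.integers(2, 15), rng.integers(2, 10)))
    out = tfidf_transform(as_pm(X)).values.toarray()
    norms = np.linalg.norm(out, axis=0)
    for j in range(X.shape[1]):
        if X[:, j].sum() > 0 and naive_tfidf(X)[:, j].any():
            assert abs(norms[j] - 1.0) < 1e-6
        else:
            assert norms[j] < 1e-12
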
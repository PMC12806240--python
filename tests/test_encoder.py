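import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import silhouette_score

from peakcast.encoder import (
    Encoder,
    EncoderConfig,
    contrastive_loss,
    contrastive_loss_grad,
    cosine_similarity,
    embed,
    sample_pairs,
    train_encoder,
)
from peakcast.preprocess import tfidf_transform
from peakcast.prior import build_prior_sample, fit_pca, make_init_bundle


def naive_loss(Za, Zb, tau):
    """Direct double-loop evaluation of the contrastive objective."""
    K = Za.shape[0]

    def cos(u, v):
        return (u @ v) / ((np.linalg.norm(u) + 1e-8) * (np.linalg.norm(v) + 1e-8))

    num = sum(np.exp(cos(Za[i], Zb[i]) / tau) for i in range(K))
    den = sum(
        np.exp(cos(Za[i], Zb[j]) / tau)
        for i in range(K)
        for j in range(K)
        if i != j
    )
    return -np.log(num / den)


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, -3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel(self):
        assert cosine_similarity([2, 0], [-5, 0]) == pytest.approx(-1.0, abs=1e-6)

    def test_scale_invariance(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        assert cosine_similarity(u, v) == pytest.approx(
            cosine_similarity(10 * u, 0.1 * v), abs=1e-6
        )


class TestSamplePairs:
    def test_single_cell_types_give_fixed_pair(self):
        pairs = sample_pairs(["A", "B", "C"], n_pairs=20, seed=0)
        assert pairs.shape == (20, 2, 3)
        assert np.all(pairs[:, 0, :] == [0, 1, 2])
        assert np.all(pairs[:, 1, :] == [0, 1, 2])

    def test_alignment_and_determinism(self):
        labels = ["b"] * 5 + ["a"] * 4 + ["c"] * 3
        p1 = sample_pairs(labels, n_pairs=100, seed=3)
        p2 = sample_pairs(labels, n_pairs=100, seed=3)
        assert np.array_equal(p1, p2)
        lab = np.asarray(labels)
        # canonical order a, b, c in each slot, on both sides
        for k, t in enumerate(["a", "b", "c"]):
            assert set(lab[p1[:, 0, k]]) == {t}
            assert set(lab[p1[:, 1, k]]) == {t}

    def test_within_type_sampling_is_uniform(self):
        m = 5
        labels = ["A"] * m + ["B"]
        n = 100_000
        pairs = sample_pairs(labels, n_pairs=n, seed=1)
        freq = np.bincount(pairs[:, 0, 0], minlength=m) / n
        se = np.sqrt((1 / m) * (1 - 1 / m) / n)
        assert np.all(np.abs(freq[:m] - 1 / m) <= 3 * se)

    def test_empty_labels_raise(self):
        with pytest.raises(ValueError):
            sample_pairs([], n_pairs=5)


class TestContrastiveLoss:
    def test_orthogonal_positive_pairs_k2(self):
        Z = np.eye(2)
        # positives at similarity 1, negatives at 0: loss = -log(2e/2) = -1
        assert contrastive_loss(Z, Z, tau=1.0) == pytest.approx(-1.0, abs=1e-6)

    def test_identical_embeddings_k2_give_zero(self):
        # with K=2, numerator (2 positives) and denominator (2 negatives)
        # coincide when every embedding is the same vector, so loss = -log 1
        Z = np.tile([1.0, 2.0, 3.0], (2, 1))
        assert contrastive_loss(Z, Z, tau=0.5) == pytest.approx(0.0, abs=1e-9)

    def test_identical_embeddings_general_k(self):
        # for K types the positive/negative count ratio is 1/(K-1)
        Z = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert contrastive_loss(Z, Z, tau=0.5) == pytest.approx(np.log(3), abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        K, d = rng.integers(2, 7), rng.integers(2, 10)
        Za, Zb = rng.normal(size=(K, d)), rng.normal(size=(K, d))
        tau = float(rng.uniform(0.1, 2.0))
        assert contrastive_loss(Za, Zb, tau) == pytest.approx(
            naive_loss(Za, Zb, tau), abs=1e-10
        )

    def test_single_type_raises(self):
        with pytest.raises(ValueError, match="2 cell types"):
            contrastive_loss(np.ones((1, 3)), np.ones((1, 3)), 1.0)

    def test_rotation_invariance(self, rng):
        K, d = 5, 8
        Za, Zb = rng.normal(size=(K, d)), rng.normal(size=(K, d))
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        assert contrastive_loss(Za @ Q, Zb @ Q, 0.7) == pytest.approx(
            contrastive_loss(Za, Zb, 0.7), abs=1e-10
        )

    def test_type_slot_permutation_invariance(self, rng):
        K, d = 6, 5
        Za, Zb = rng.normal(size=(K, d)), rng.normal(size=(K, d))
        perm = rng.permutation(K)
        assert contrastive_loss(Za[perm], Zb[perm], 0.5) == pytest.approx(
            contrastive_loss(Za, Zb, 0.5), abs=1e-10
        )

    def test_loss_decreases_as_positives_tighten(self):
        # Za on basis e0..e2, Zb rotated towards Za in orthogonal planes:
        # cross-type similarities stay 0 while positives rise with cos(theta)
        K, d = 3, 6
        Za = np.eye(K, d)
        losses = []
        for theta in [1.2, 0.8, 0.4, 0.1]:
            Zb = np.cos(theta) * np.eye(K, d)
            for i in range(K):
                Zb[i, K + i] = np.sin(theta)
            losses.append(contrastive_loss(Za, Zb, tau=0.5))
        assert np.all(np.diff(losses) < 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        K, d = 4, 5
        Za, Zb = rng.normal(size=(K, d)), rng.normal(size=(K, d))
        tau = 0.5
        _, dZa, dZb = contrastive_loss_grad(Za, Zb, tau)
        h = 1e-6
        for Z, dZ in ((Za, dZa), (Zb, dZb)):
            for idx in [(0, 0), (1, 3), (3, 4), (2, 2)]:
                Zp, Zm = Z.copy(), Z.copy()
                Zp[idx] += h
                Zm[idx] -= h
                if Z is Za:
                    num = (contrastive_loss(Zp, Zb, tau) - contrastive_loss(Zm, Zb, tau)) / (2 * h)
                else:
                    num = (contrastive_loss(Za, Zp, tau) - contrastive_loss(Za, Zm, tau)) / (2 * h)
                denom = max(abs(num), abs(dZ[idx]), 1e-8)
                assert abs(num - dZ[idx]) / denom < 1e-5


def _prep(dataset, n_components=20, seed=0):
    train, test, _ = dataset
    model_peaks = None
    from peakcast.preprocess import fit_peak_selection

    sel = fit_peak_selection(train)
    train_norm = tfidf_transform(sel.apply(train))
    prior = build_prior_sample(train_norm, train.labels, n_draws=30,
                               n_replicates=30, seed=seed)
    pca = fit_pca(prior.means, n_components, seed=seed)
    init = make_init_bundle(pca, random_width=32, seed=seed)
    return train, train_norm, init


class TestTraining:
    def test_loss_improves_on_separable_fixture(self, easy_dataset):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=16, n_pairs=400, pairs_per_step=32, seed=0)
        enc = train_encoder(train_norm, train.labels, init, cfg)
        assert enc.loss_history[-1] < enc.loss_history[0]

    def test_fixed_seed_reproducible(self, easy_dataset):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=8, n_pairs=200, pairs_per_step=32, seed=4)
        e1 = train_encoder(train_norm, train.labels, init, cfg)
        e2 = train_encoder(train_norm, train.labels, init, cfg)
        assert np.array_equal(e1.W1, e2.W1)
        assert np.array_equal(e1.W2, e2.W2)

    def test_training_improves_silhouette(self, easy_dataset):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=16, n_pairs=600, pairs_per_step=32, seed=0)
        trained = train_encoder(train_norm, train.labels, init, cfg)
        rng = np.random.default_rng(99)
        W1, b1 = init.stacked()
        untrained = Encoder(
            W1=W1, b1=b1,
            W2=rng.uniform(-0.1, 0.1, size=(init.total_width, cfg.output_dim)),
            b2=np.zeros(cfg.output_dim),
            config=cfg,
        )
        labels = train.labels
        before = silhouette_score(embed(untrained, train_norm).vectors, labels)
        after = silhouette_score(embed(trained, train_norm).vectors, labels)
        assert after > before

    def test_save_load_round_trip(self, easy_dataset, tmp_path):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=8, n_pairs=100, pairs_per_step=32, seed=1)
        enc = train_encoder(train_norm, train.labels, init, cfg)
        enc.save(tmp_path / "enc.npz")
        back = Encoder.load(tmp_path / "enc.npz")
        assert np.array_equal(back.W1, enc.W1)
        assert back.config == enc.config
        X = train_norm.cells_by_peaks()
        assert np.array_equal(back.forward(X), enc.forward(X))


class TestEmbed:
    def test_shape_and_duplicates(self, easy_dataset):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=12, n_pairs=100, pairs_per_step=32, seed=2)
        enc = train_encoder(train_norm, train.labels, init, cfg)
        emb = embed(enc, train_norm)
        assert emb.vectors.shape == (train_norm.n_cells, 12)
        # identical inputs embed identically
        X = train_norm.cells_by_peaks()
        z = enc.forward(np.vstack([X[0], X[0]]))
        assert np.array_equal(z[0], z[1])

    def test_zero_cell_gives_finite_embedding(self, easy_dataset):
        train, train_norm, init = _prep(easy_dataset)
        cfg = EncoderConfig(output_dim=8, n_pairs=100, pairs_per_step=32, seed=2)
        enc = train_encoder(train_norm, train.labels, init, cfg)
        z = enc.forward(np.zeros((1, enc.input_dim)))
        assert np.all(np.isfinite(z))
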
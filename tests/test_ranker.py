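"""The latent-score model: probabilities, loss, training, cross-validation."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

import molpref as mp

from conftest import make_linear_problem


def random_model(dim=12, seed=0, **kw):
    """A model with a non-trivial head (the default head starts at zero)."""
    model = mp.ScoreModel(dim, hidden_sizes=(16, 8), seed=seed, **kw)
    rng = np.random.default_rng(seed + 1)
    model.W[-1] = rng.normal(size=model.W[-1].shape)
    return model


def linear_model(weight=1.0, bias=0.0):
    """No hidden layers: s(x) = weight * x + bias on 1-d features."""
    model = mp.ScoreModel(1, hidden_sizes=())
    model.W[-1][0, 0] = weight
    model.b[-1][0] = bias
    return model


class TestPairProbability:
    def test_identical_features_give_half(self):
        model = random_model()
        x = np.random.default_rng(0).normal(size=(5, 12))
        assert np.allclose(mp.pair_probability(model, x, x), 0.5)

    def test_sigma_of_unit_delta(self):
        model = linear_model()
        # s_i = 0, s_j = 1 -> p(i > j) = sigma(1); swapped -> sigma(-1)
        p = mp.pair_probability(model, np.array([[0.0]]), np.array([[1.0]]))
        assert np.allclose(p, 0.7310585786300049)
        q = mp.pair_probability(model, np.array([[1.0]]), np.array([[0.0]]))
        assert np.allclose(q, 0.2689414213699951)

    def test_antisymmetry_machine_precision(self):
        model = random_model()
        rng = np.random.default_rng(3)
        Xi = rng.normal(size=(1000, 12))
        Xj = rng.normal(size=(1000, 12))
        total = (mp.pair_probability(model, Xi, Xj)
                 + mp.pair_probability(model, Xj, Xi))
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_lower_score_is_preferred(self):
        model = linear_model()
        # molecule i scores -2 (better), j scores +2: i should win often
        p = mp.pair_probability(model, np.array([[-2.0]]), np.array([[2.0]]))
        assert p > 0.9

    def test_dimension_mismatch_raises(self):
        model = random_model(dim=12)
        with pytest.raises(mp.DimensionError):
            model.score(np.zeros((3, 7)))


class TestLoss:
    def test_uninformed_model_gives_ln2(self):
        """A freshly initialized model is uninformed: loss is exactly ln 2."""
        model = mp.ScoreModel(12, hidden_sizes=(16, 8), reg_lambda=0.0)
        rng = np.random.default_rng(0)
        Xi, Xj = rng.normal(size=(2, 20, 12))
        y = np.array([0, 1] * 10, dtype=float)
        assert mp.pair_loss(model, Xi, Xj, y) == pytest.approx(math.log(2))

    def test_single_pair_confident_correct(self):
        model = linear_model()
        # delta = s_j - s_i = 1, label 1 -> loss = -ln(sigma(1))
        loss = mp.pair_loss(model, np.array([[0.0]]), np.array([[1.0]]),
                            [1], reg_lambda=0.0)
        assert loss == pytest.approx(-math.log(1 / (1 + math.exp(-1))), abs=1e-10)
        assert loss == pytest.approx(0.3133, abs=1e-4)

    def test_perfect_confident_predictions_vanish(self):
        model = linear_model(weight=50.0)
        Xi = np.array([[0.0], [1.0]])
        Xj = np.array([[1.0], [0.0]])
        y = [1, 0]  # lower-scoring member preferred in both pairs
        assert mp.pair_loss(model, Xi, Xj, y, reg_lambda=0.0) < 1e-10

    def test_regularizer_adds_squared_norm(self):
        model = linear_model(bias=2.0)
        x = np.array([[0.0]])
        base = mp.pair_loss(model, x, x, [1], reg_lambda=0.0)
        reg = mp.pair_loss(model, x, x, [1], reg_lambda=0.5)
        # two legs, each score 2 -> lambda * (4 + 4)
        assert reg - base == pytest.approx(0.5 * 8.0)

    def test_bad_labels_raise(self):
        model = random_model()
        x = np.zeros((1, 12))
        with pytest.raises(mp.LabelError):
            mp.pair_loss(model, x, x, [2])
        with pytest.raises(mp.LabelError):
            mp.pair_loss(model, np.zeros((0, 12)), np.zeros((0, 12)), [])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        model = random_model(dim=5, seed=7)
        Xi = rng.normal(size=(4, 5))
        Xj = rng.normal(size=(4, 5))
        y = np.array([1.0, 0.0, 1.0, 1.0])
        B = 4

        def loss_fn():
            return mp.pair_loss(model, Xi, Xj, y, reg_lambda=0.01)

        # analytic gradients (no dropout)
        X = np.vstack([Xi, Xj])
        cache = {}
        s = model.forward(X, cache=cache)
        delta = s[B:] - s[:B]
        p = 1 / (1 + np.exp(-delta))
        g = (p - y) / B
        ds = np.concatenate([-g, g]) + 2 * 0.01 * s
        gW, gb = model._backward(cache, None, ds)

        eps = 1e-6
        for k in [0, len(model.W) - 1]:
            w = model.W[k]
            idx = (0, 0)
            orig = w[idx]
            w[idx] = orig + eps
            up = loss_fn()
            w[idx] = orig - eps
            down = loss_fn()
            w[idx] = orig
            assert gW[k][idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4,
                                               abs=1e-8)


class TestTraining:
    def test_recovers_noiseless_oracle(self):
        X, s_star, ai, bj, _ = make_linear_problem(seed=1, beta=8.0)
        y = (s_star[ai] < s_star[bj]).astype(float)  # noiseless labels
        cfg = mp.TrainConfig(seed=1, epochs=80, hidden_sizes=(32, 16))
        model = mp.train(X[ai], X[bj], y, cfg)
        p = mp.pair_probability(model, X[ai], X[bj])
        assert roc_auc_score(y, p) > 0.95
        # learned scores track the ground truth ordering
        rho = spearmanr(model.score(X), s_star).statistic
        assert rho > 0.8

    def test_reproducible_under_seed(self):
        X, _, ai, bj, y = make_linear_problem(seed=2)
        cfg = mp.TrainConfig(seed=5, epochs=5, hidden_sizes=(16, 8))
        m1 = mp.train(X[ai], X[bj], y, cfg)
        m2 = mp.train(X[ai], X[bj], y, cfg)
        for w1, w2 in zip(m1.W, m2.W):
            assert np.array_equal(w1, w2)

    def test_strong_regularizer_shrinks_scores(self):
        X, _, ai, bj, y = make_linear_problem(seed=3)
        small = mp.TrainConfig(seed=3, epochs=40, hidden_sizes=(16, 8),
                               reg_lambda=1e-6)
        large = mp.TrainConfig(seed=3, epochs=40, hidden_sizes=(16, 8),
                               reg_lambda=10.0)
        s_small = mp.train(X[ai], X[bj], y, small).score(X)
        s_large = mp.train(X[ai], X[bj], y, large).score(X)
        assert np.abs(s_large).mean() < np.abs(s_small).mean()

    def test_empty_pairs_raise(self):
        with pytest.raises(mp.LabelError):
            mp.train(np.zeros((0, 4)), np.zeros((0, 4)), [])

    def test_dropout_off_scoring_deterministic(self):
        model = random_model()
        x = np.random.default_rng(1).normal(size=(8, 12))
        assert np.array_equal(model.score(x), model.score(x))
        # one stochastic pass differs from the deterministic one
        s_mc = mp.latent_score(model, x, dropout_active=True, seed=0)
        assert not np.allclose(s_mc, model.score(x))


class TestCrossValidation:
    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X, _, ai, bj, _ = make_linear_problem(seed=4, n_pairs=400)
        y = rng.integers(0, 2, size=400).astype(float)  # labels carry no signal
        cfg = mp.TrainConfig(seed=4, epochs=15, hidden_sizes=(16, 8), n_folds=5)
        res = mp.cross_validate(X[ai], X[bj], y, cfg)
        assert 0.35 < res["mean"] < 0.65
        assert len(res["fold_auroc"]) == 5

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            mp.cross_validate(np.zeros((3, 2)), np.zeros((3, 2)), [0, 1, 1],
                              mp.TrainConfig(n_folds=5))


class TestScoring:
    def test_clamp(self):
        assert mp.clamp_score(12.0, 9.0) == 9.0
        assert mp.clamp_score(-12.0, 9.0) == -9.0
        assert np.array_equal(mp.clamp_score(np.array([-20.0, 0.5, 20.0]), 9.0),
                              [-9.0, 0.5, 9.0])

    def test_library_filtering_and_determinism(self, small_pool):
        smiles = small_pool["smiles_canonical"].head(12).tolist()
        feat = mp.Featurizer().fit(smiles)
        model = mp.ScoreModel(feat.spec.n_features, hidden_sizes=(8,), seed=0)
        lib = smiles[:4] + ["CC(=O)Nc1ccc(O)cc1"]  # paracetamol: MW 151
        s1, dropped = mp.score_library(model, feat, lib)
        s2, _ = mp.score_library(model, feat, lib)
        assert np.array_equal(s1["score"], s2["score"])
        assert any("mw_min" in r for r in dropped["reasons"])
        # without the applicability-domain filter everything is scored
        s3, dropped3 = mp.score_library(model, feat, lib, apply_filters=False)
        assert len(dropped3) == 0 and len(s3) == len(lib)

    def test_checkpoint_roundtrip(self, tmp_path, small_pool):
        smiles = small_pool["smiles_canonical"].head(6).tolist()
        feat = mp.Featurizer().fit(smiles)
        model = mp.ScoreModel(feat.spec.n_features, hidden_sizes=(8,), seed=1)
        path = tmp_path / "model.npz"
        mp.save_checkpoint(path, model, feat)
        model2, feat2 = mp.load_checkpoint(path)
        X = feat2.transform(smiles)
        assert np.allclose(model.score(feat.transform(smiles)), model2.score(X))
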
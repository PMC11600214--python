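"""Distance-matrix model: forward contract, loss, training, evaluation."""

import warnings

import numpy as np
import pytest

from transpath import fixtures as fx
from transpath import models as md
from transpath.featurize import ContactMasks, DistanceFeature


@pytest.fixture(scope="module")
def tiny_config():
    return md.HesConfig(n_res_blocks=2, channels=8, head_cells=8, seed=0)


@pytest.fixture(scope="module")
def small_corpus():
    return fx.make_synthetic_training_corpus(6, (20, 24), "elementwise_min",
                                             seed=21)


def _random_feature(rng, n=16, source="state_a"):
    r = rng.uniform(0.3, 2.0, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    from transpath.featurize import sigmoid_distance
    return DistanceFeature(D=sigmoid_distance(r), source=source)


class TestForward:
    def test_output_symmetric_to_machine_precision(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        da, db = _random_feature(rng), _random_feature(rng)
        out = model.forward(da, db)[0]
        np.testing.assert_array_equal(out, out.T)

    def test_channel_order_matters(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        da, db = _random_feature(rng), _random_feature(rng)
        assert not np.allclose(model.forward(da, db)[0],
                               model.forward(db, da)[0])

    def test_repeated_forward_bitwise_identical(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        da, db = _random_feature(rng), _random_feature(rng)
        np.testing.assert_array_equal(model.forward(da, db)[0],
                                      model.forward(da, db)[0])

    def test_same_seed_same_init(self, tiny_config, rng):
        m1 = md.DistanceMatrixModel(tiny_config)
        m2 = md.DistanceMatrixModel(tiny_config)
        da, db = _random_feature(rng), _random_feature(rng)
        np.testing.assert_array_equal(m1.forward(da, db)[0],
                                      m2.forward(da, db)[0])

    def test_input_smaller_than_kernel_rejected(self, tiny_config):
        model = md.DistanceMatrixModel(tiny_config)
        tiny = DistanceFeature(D=np.full((2, 2), 0.1))
        with pytest.raises(ValueError):
            model.forward(tiny, tiny)

    def test_predict_clamped(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        model.trained = True
        da, db = _random_feature(rng), _random_feature(rng)
        out = model.predict(da, db)[0]
        assert out.min() >= 0.0
        assert out.max() < 1.0

    def test_untrained_predict_warns(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        da = _random_feature(rng)
        with pytest.warns(UserWarning, match="untrained"):
            model.predict(da, da)


class TestWeightedLoss:
    def _masks(self, n, unique_pairs):
        unique = np.zeros((n, n), dtype=bool)
        for i, j in unique_pairs:
            unique[i, j] = unique[j, i] = True
        return ContactMasks(unique=unique, common=np.zeros((n, n), bool),
                            non_unique=~unique)

    def test_zero_iff_equal(self, rng):
        target = rng.uniform(0, 0.7, (8, 8))
        masks = self._masks(8, [(0, 5)])
        assert md.weighted_loss(target, target, masks) == 0.0
        assert md.weighted_loss(target + 0.1, target, masks) > 0.0

    def test_unique_to_non_unique_ratio_is_five(self):
        n = 8
        target = np.zeros((n, n))
        masks = self._masks(n, [(0, 5)])
        pred_u = target.copy()
        pred_u[0, 5] = pred_u[5, 0] = 1.0
        pred_nu = target.copy()
        pred_nu[1, 6] = pred_nu[6, 1] = 1.0
        lu = md.weighted_loss(pred_u, target, masks)
        lnu = md.weighted_loss(pred_nu, target, masks)
        assert lu / lnu == 5.0

    def test_matches_double_loop_oracle(self, rng):
        n = 10
        pred = rng.uniform(0, 0.7, (n, n))
        target = rng.uniform(0, 0.7, (n, n))
        unique = rng.uniform(size=(n, n)) < 0.2
        unique = unique | unique.T
        masks = ContactMasks(unique=unique, common=np.zeros((n, n), bool),
                             non_unique=~unique)
        expected = 0.0
        for i in range(n):
            for j in range(n):
                w = 5.0 if unique[i, j] else 1.0
                expected += w * (pred[i, j] - target[i, j]) ** 2
        assert md.weighted_loss(pred, target, masks) == pytest.approx(
            expected, rel=1e-12)


class TestTrain:
    def test_zero_learning_rate_keeps_loss_constant(self, small_corpus):
        # with lr = 0 every epoch revisits identical per-example losses, so
        # the windowed means after whole epochs coincide
        cfg = md.HesConfig(n_res_blocks=2, channels=8, head_cells=8,
                           learning_rate=0.0, n_steps=12, val_every=6,
                           seed=1)
        res = md.train(small_corpus, cfg, split=(1.0, 0.0))
        losses = [row[1] for row in res.history]
        assert losses[0] == pytest.approx(losses[-1], rel=1e-6)

    def test_same_seed_identical_loss_curves(self, small_corpus):
        cfg = md.HesConfig(n_res_blocks=2, channels=8, head_cells=8,
                           n_steps=60, val_every=20, seed=5)
        r1 = md.train(small_corpus, cfg, split=(0.8, 0.2))
        r2 = md.train(small_corpus, cfg, split=(0.8, 0.2))
        assert r1.history == r2.history

    def test_loss_decreases(self, small_corpus):
        cfg = md.HesConfig(n_res_blocks=2, channels=8, head_cells=8,
                           n_steps=200, val_every=50, seed=2)
        res = md.train(small_corpus, cfg, split=(1.0, 0.0))
        assert res.history[-1][1] < res.history[0][1]

    def test_degenerate_corpus_warns(self):
        d = DistanceFeature(D=np.full((8, 8), 0.3))
        masks = ContactMasks(unique=np.zeros((8, 8), bool),
                             common=np.zeros((8, 8), bool),
                             non_unique=np.ones((8, 8), bool))
        ex = md.TrainingExample(da=d, db=d, target_ts=d, masks=masks)
        cfg = md.HesConfig(n_res_blocks=1, channels=4, head_cells=4,
                           n_steps=2, val_every=1, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            md.train([ex, ex], cfg, split=(1.0, 0.0))

    def test_empty_corpus_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            md.train([], tiny_config)


class TestEvaluateUnique:
    def _masks_all_unique(self, n):
        unique = np.triu(np.ones((n, n), bool), 3)
        unique = unique | unique.T
        return ContactMasks(unique=unique, common=np.zeros((n, n), bool),
                            non_unique=~unique)

    def test_perfect_prediction(self, rng):
        t = rng.uniform(0, 0.7, (10, 10))
        t = (t + t.T) / 2
        r, mae = md.evaluate_unique(t, t, self._masks_all_unique(10))
        assert r == pytest.approx(1.0)
        assert mae == 0.0

    def test_constant_shift(self, rng):
        t = rng.uniform(0, 0.5, (10, 10))
        t = (t + t.T) / 2
        r, mae = md.evaluate_unique(t + 0.1, t, self._masks_all_unique(10))
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(0.1)

    def test_matches_textbook_formula(self, rng):
        n = 12
        pred = rng.uniform(0, 0.7, (n, n))
        target = rng.uniform(0, 0.7, (n, n))
        masks = self._masks_all_unique(n)
        r, mae = md.evaluate_unique(pred, target, masks)
        sel = np.triu(masks.unique, k=1)
        p, t = pred[sel], target[sel]
        # independent Pearson evaluation from the definition
        num = np.sum((p - p.mean()) * (t - t.mean()))
        den = np.sqrt(np.sum((p - p.mean()) ** 2)
                      * np.sum((t - t.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-9)
        assert mae == pytest.approx(np.abs(p - t).mean(), rel=1e-12)

    def test_too_few_unique_pairs(self, rng):
        masks = ContactMasks(unique=np.zeros((6, 6), bool),
                             common=np.zeros((6, 6), bool),
                             non_unique=np.ones((6, 6), bool))
        with pytest.raises(ValueError):
            md.evaluate_unique(np.zeros((6, 6)), np.zeros((6, 6)), masks)


@pytest.fixture(scope="module")
def path_model():
    cfg = md.HesConfig(n_res_blocks=2, channels=8, head_cells=8,
                       mode="path", seed=3)
    model = md.DistanceMatrixModel(cfg)
    model.trained = True
    return model


class TestPathPrediction:
    def test_five_points_are_exactly_the_knots(self, path_model, rng):
        da, db = _random_feature(rng), _random_feature(rng, source="state_b")
        pred = md.predict_pathway(path_model, da, db, n_points=5)
        np.testing.assert_allclose(pred.interpolated[0].D, da.D, atol=1e-12)
        np.testing.assert_allclose(pred.interpolated[-1].D, db.D, atol=1e-12)
        for k, anchor in enumerate(pred.anchors):
            np.testing.assert_allclose(pred.interpolated[k + 1].D, anchor.D,
                                       atol=1e-7)

    def test_endpoints_for_any_length(self, path_model, rng):
        da, db = _random_feature(rng), _random_feature(rng)
        pred = md.predict_pathway(path_model, da, db, n_points=9)
        np.testing.assert_allclose(pred.interpolated[0].D, da.D, atol=1e-12)
        np.testing.assert_allclose(pred.interpolated[-1].D, db.D, atol=1e-12)

    def test_midpoint_between_knots_is_elementwise_mean(self, path_model,
                                                        rng):
        # n_points=9 samples t = 0, 1/8, 1/4, ...; the t = 1/8 matrix is
        # halfway between state A (t=0) and the first anchor (t=1/4)
        da, db = _random_feature(rng), _random_feature(rng)
        pred = md.predict_pathway(path_model, da, db, n_points=9)
        np.testing.assert_allclose(pred.interpolated[1].D,
                                   0.5 * (da.D + pred.anchors[0].D),
                                   atol=1e-7)

    def test_all_symmetric(self, path_model, rng):
        da, db = _random_feature(rng), _random_feature(rng)
        pred = md.predict_pathway(path_model, da, db, n_points=7)
        for m in pred.interpolated:
            np.testing.assert_allclose(m.D, m.D.T, atol=1e-12)

    def test_hes_mode_rejected(self, tiny_config, rng):
        model = md.DistanceMatrixModel(tiny_config)
        da = _random_feature(rng)
        with pytest.raises(ValueError, match="path"):
            md.predict_pathway(model, da, da)

    def test_n_points_minimum(self, path_model, rng):
        da = _random_feature(rng)
        with pytest.raises(ValueError):
            md.predict_pathway(path_model, da, da, n_points=3)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_config, rng, tmp_path):
        model = md.DistanceMatrixModel(tiny_config)
        model.trained = True
        path = tmp_path / "model.npz"
        model.save(path)
        back = md.DistanceMatrixModel.load(path)
        da, db = _random_feature(rng), _random_feature(rng)
        np.testing.assert_array_equal(model.forward(da, db)[0],
                                      back.forward(da, db)[0])
        assert back.trained
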
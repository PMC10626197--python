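"""Architecture contracts: FiLM, symmetric bilinear pairing, training,
order-invariant prediction, the DeepSynergy baseline, and the Model/Results
surface."""

import numpy as np
import pytest

import synergyloop as sl
from synergyloop.dose_response import SynergyRecord
from synergyloop.featurization import DrugRecord, assemble_drug_features
from synergyloop.model import (
    DeepSynergyBaseline,
    RecoverConfig,
    RecoverModel,
    SynergyRegression,
    combine_pair,
    encode_drug,
    film_modulate,
    predict_synergy,
    train_model,
)


class TestFilm:
    def film(self, Wg, bg, Wb, bb):
        return {"Wg": np.asarray(Wg, float), "bg": np.asarray(bg, float),
                "Wb": np.asarray(Wb, float), "bb": np.asarray(bb, float)}

    def test_neutral_transform_is_identity(self):
        p = self.film(np.zeros((2, 3)), np.ones(3), np.zeros((2, 3)), np.zeros(3))
        h = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(film_modulate(h, np.array([0.3, 0.7]), p), h)

    def test_zero_gamma_collapses_to_beta(self):
        p = self.film(np.zeros((1, 2)), np.zeros(2), np.eye(1, 2), np.array([0.0, 5.0]))
        out = film_modulate(np.array([9.0, 9.0]), np.array([2.0]), p)
        np.testing.assert_allclose(out, [2.0, 5.0])  # beta = cell @ Wb + bb

    def test_elementwise_affine_arithmetic(self):
        p = self.film(np.zeros((1, 2)), np.array([2.0, 0.5]),
                      np.zeros((1, 2)), np.array([1.0, -1.0]))
        out = film_modulate(np.array([3.0, 4.0]), np.array([1.0]), p)
        np.testing.assert_allclose(out, [7.0, 1.0])

    def test_width_mismatch(self):
        p = self.film(np.zeros((1, 3)), np.ones(3), np.zeros((1, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            film_modulate(np.ones(2), np.ones(1), p)


class TestBilinearCombination:
    def hand_model(self):
        """k_D = 2, single identity bilinear slice, identity head."""
        cfg = RecoverConfig(single_hidden_dims=[2], drug_embedding_dim=2,
                            bilinear_dim=1, combination_hidden_dims=[1],
                            batch_size=1, patience=1, max_epochs=1)
        m = RecoverModel(cfg, l_D=2, seed=0)
        m.params["B"] = np.eye(2)[None]
        # head: 1 -> 1 -> 1 identity (ReLU transparent for positive z)
        m.params["head.W0"] = np.ones((1, 1))
        m.params["head.b0"] = np.zeros(1)
        m.params["head.W1"] = np.ones((1, 1))
        m.params["head.b1"] = np.zeros(1)
        return m

    def test_hand_computed_bilinear_value(self):
        m = self.hand_model()
        assert combine_pair(m, [1.0, 2.0], [3.0, 4.0]) == pytest.approx(11.0)

    def test_symmetry_of_combination(self):
        cfg = RecoverConfig(single_hidden_dims=[8], drug_embedding_dim=4,
                            bilinear_dim=3, combination_hidden_dims=[4],
                            batch_size=4, patience=1, max_epochs=1)
        m = RecoverModel(cfg, l_D=6, seed=1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            e1, e2 = rng.normal(size=4), rng.normal(size=4)
            assert combine_pair(m, e1, e2) == pytest.approx(
                combine_pair(m, e2, e1), abs=1e-6)

    def test_zero_embedding_collapses_to_head_of_zero(self):
        m = self.hand_model()
        assert combine_pair(m, [0.0, 0.0], [5.0, -7.0]) == pytest.approx(0.0)

    def test_embedding_length_mismatch(self):
        m = self.hand_model()
        with pytest.raises(ValueError):
            combine_pair(m, [1.0, 2.0, 3.0], [1.0, 2.0])


class TestEncoder:
    def test_embedding_dimension_and_determinism(self):
        cfg = RecoverConfig(single_hidden_dims=[32], drug_embedding_dim=128,
                            bilinear_dim=8, combination_hidden_dims=[8],
                            batch_size=8, patience=1, max_epochs=1)
        m = RecoverModel(cfg, l_D=10, seed=0)
        x = np.random.default_rng(0).normal(size=10)
        e1, e2 = encode_drug(m, x), encode_drug(m, x)
        assert e1.shape == (128,)
        np.testing.assert_array_equal(e1, e2)

    def test_zero_weights_give_zero_embedding(self):
        cfg = RecoverConfig(single_hidden_dims=[4], drug_embedding_dim=3,
                            bilinear_dim=2, combination_hidden_dims=[2],
                            batch_size=2, patience=1, max_epochs=1)
        m = RecoverModel(cfg, l_D=5, seed=0)
        for k in list(m.params):
            if k.startswith("enc."):
                m.params[k] = np.zeros_like(m.params[k])
        np.testing.assert_allclose(encode_drug(m, np.ones(5)), 0.0)

    def test_dimension_mismatch(self):
        cfg = RecoverConfig(single_hidden_dims=[4], drug_embedding_dim=3,
                            bilinear_dim=2, combination_hidden_dims=[2],
                            batch_size=2, patience=1, max_epochs=1)
        m = RecoverModel(cfg, l_D=5, seed=0)
        with pytest.raises(ValueError):
            encode_drug(m, np.ones(6))

    def test_neutral_film_matches_unconditioned_model(self):
        cfg = RecoverConfig(single_hidden_dims=[8], drug_embedding_dim=4,
                            bilinear_dim=3, combination_hidden_dims=[4],
                            batch_size=4, patience=1, max_epochs=1)
        plain = RecoverModel(cfg, l_D=6, l_C=0, seed=5)
        cond = RecoverModel(cfg, l_D=6, l_C=2, seed=5)  # FiLM init: gamma=1, beta=0
        rng = np.random.default_rng(2)
        X1, X2 = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        C = rng.normal(size=(5, 2))
        y_plain, _ = plain.forward(X1, X2)
        y_cond, _ = cond.forward(X1, X2, C)
        np.testing.assert_allclose(y_plain, y_cond, atol=1e-12)


@pytest.fixture()
def toy_library():
    rng = np.random.default_rng(0)
    return [DrugRecord(f"d{i}", fingerprint=rng.integers(0, 2, 16).astype(np.uint8))
            for i in range(8)]


@pytest.fixture()
def toy_features(toy_library):
    return assemble_drug_features(toy_library)


def toy_records(values):
    pairs = [(f"d{i}", f"d{j}") for i in range(8) for j in range(i + 1, 8)]
    return [SynergyRecord(a, b, "m", v) for (a, b), v in zip(pairs, values)]


class TestTraining:
    def test_constant_target_learned(self, toy_features):
        cfg = RecoverConfig(single_hidden_dims=[16], drug_embedding_dim=8,
                            bilinear_dim=4, combination_hidden_dims=[4],
                            batch_size=16, learning_rate=3e-3, weight_decay=0.0,
                            max_epochs=200, patience=50)
        recs = toy_records([7.0] * 28)
        model, report = train_model(recs, cfg, toy_features, seed=0)
        preds = model.predict([(r.drug_a, r.drug_b) for r in recs])
        assert np.all(np.abs(preds - 7.0) < 0.5)
        assert report.best_validation_mse < 1e-2
        assert report.epochs_run <= cfg.max_epochs

    def test_conflicting_targets_floor_the_mse(self, toy_features, tiny_config):
        # each pair duplicated with targets +y and -y: best possible MSE is y^2
        y = 3.0
        recs = toy_records([y] * 28) + toy_records([-y] * 28)
        _, report = train_model(recs, tiny_config, toy_features, seed=0,
                                val_fraction=0.5)
        assert report.best_validation_mse >= y ** 2 * 0.5  # generous floor

    def test_empty_dataset_rejected(self, toy_features, tiny_config):
        with pytest.raises(ValueError):
            train_model([], tiny_config, toy_features)

    def test_loss_decreases_on_easy_target(self, toy_features, tiny_config):
        rng = np.random.default_rng(1)
        recs = toy_records(rng.normal(0, 1, 28))
        _, report = train_model(recs, tiny_config, toy_features, seed=0)
        trace = report.train_loss_trace
        assert trace[-1] < trace[0]

    def test_seeded_training_reproducible(self, toy_features, tiny_config):
        recs = toy_records(np.linspace(-5, 5, 28))
        m1, _ = train_model(recs, tiny_config, toy_features, seed=9)
        m2, _ = train_model(recs, tiny_config, toy_features, seed=9)
        pairs = [(r.drug_a, r.drug_b) for r in recs]
        np.testing.assert_array_equal(m1.predict(pairs), m2.predict(pairs))


class TestPrediction:
    def test_pair_order_invariance(self, trained_small_model, small_study):
        model, _ = trained_small_model
        ids = [d.drug_id for d in small_study.library]
        rng = np.random.default_rng(0)
        pairs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(100)]
        fwd = model.predict(pairs)
        rev = model.predict([(b, a) for a, b in pairs])
        np.testing.assert_allclose(fwd, rev, atol=1e-6)

    def test_empty_pairs(self, trained_small_model):
        model, _ = trained_small_model
        assert len(model.predict([])) == 0

    def test_batch_equals_one_by_one(self, trained_small_model, small_study):
        model, _ = trained_small_model
        ids = [d.drug_id for d in small_study.library]
        pairs = [(ids[0], ids[1]), (ids[2], ids[3]), (ids[4], ids[5])]
        batch = model.predict(pairs)
        single = np.array([model.predict([p])[0] for p in pairs])
        np.testing.assert_allclose(batch, single, atol=1e-6)

    def test_unknown_drug_listed(self, trained_small_model):
        model, _ = trained_small_model
        with pytest.raises(KeyError, match="nonexistent"):
            predict_synergy(model, [("nonexistent", "SYN-01")])

    def test_checkpoint_round_trip(self, trained_small_model, small_study, tmp_path):
        model, _ = trained_small_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = RecoverModel.load(path)
        back.drug_features = model.drug_features
        ids = [d.drug_id for d in small_study.library]
        pairs = [(ids[0], ids[1]), (ids[2], ids[3])]
        np.testing.assert_allclose(back.predict(pairs), model.predict(pairs))


class TestModelResultsSurface:
    def test_fit_returns_results_with_summary(self, small_study, small_features,
                                              small_config):
        reg = SynergyRegression(small_study.observed_records(), small_features,
                                config=small_config)
        res = reg.fit(seed=0)
        text = res.summary()
        assert "Synergy Regression Results" in text
        assert res.fittedvalues.shape == (len(reg.records),)
        assert np.isfinite(res.rsquared)
        assert res.resid.shape == res.fittedvalues.shape

    def test_from_dataframe_constructor(self, small_study, small_features,
                                        tiny_config):
        df = small_study.observed_table.copy()
        df["cell_line"] = "SYN"
        reg = SynergyRegression.from_dataframe(df[["drug_a", "drug_b",
                                                   "cell_line", "synergy"]],
                                               small_features, config=tiny_config)
        assert len(reg.records) == len(df)


class TestDeepSynergyBaseline:
    def test_exact_order_invariance_and_eval_determinism(self, toy_features,
                                                         tiny_config):
        recs = toy_records(np.linspace(-10, 10, 28))
        baseline = DeepSynergyBaseline(hidden_dims=(16, 8))
        baseline.fit(recs, tiny_config, toy_features, seed=0)
        p1 = baseline.predict([("d0", "d1"), ("d2", "d3")])
        p2 = baseline.predict([("d1", "d0"), ("d3", "d2")])
        np.testing.assert_array_equal(p1, p2)  # explicit symmetrization
        np.testing.assert_array_equal(p1, baseline.predict([("d0", "d1"), ("d2", "d3")]))

    def test_zero_variance_column_survives_standardization(self, toy_library,
                                                           tiny_config):
        # append a constant fingerprint bit across the library
        for d in toy_library:
            d.fingerprint = np.concatenate([d.fingerprint, [1]]).astype(np.uint8)
        feats = assemble_drug_features(toy_library)
        recs = toy_records(np.linspace(-5, 5, 28))
        baseline = DeepSynergyBaseline(hidden_dims=(8, 4))
        baseline.fit(recs, tiny_config, feats, seed=0)
        preds = baseline.predict([("d0", "d1")])
        assert np.all(np.isfinite(preds))
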
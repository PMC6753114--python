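"""Data splitting, model fitting, evaluation, transfer and search."""

import numpy as np
import pytest
from scipy import stats

from guidehf import (
    GuideActivityModel,
    evaluate_model,
    fine_tune,
    hyperparameter_search,
    kfold_validation,
    simulate_activity_dataset,
    split_dataset,
    train_model,
)
from guidehf.models import ActivityResults, _evaluate
from guidehf.nn import NetConfig

FAST = NetConfig(max_epochs=6, patience=3, hidden_dim=8, embed_dim=4, dense_sizes=(16,))


class TestSplit:
    @pytest.mark.parametrize(
        "n,sizes",
        [(55_604, (42_537, 4_726, 8_341)), (1_000, (765, 85, 150)), (10, (7, 0, 3))],
    )
    def test_floor_floor_remainder_sizes(self, n, sizes):
        assert split_dataset(n, seed=0).sizes == sizes

    def test_partition_covers_everything(self, rng):
        for n in rng.integers(3, 5000, size=10):
            split = split_dataset(int(n), seed=int(n))
            union = np.concatenate([split.train, split.validation, split.test])
            assert sorted(union) == list(range(n))

    def test_seed_changes_assignment_not_sizes(self):
        a, b = split_dataset(200, seed=1), split_dataset(200, seed=2)
        assert a.sizes == b.sizes
        assert not np.array_equal(a.train, b.train)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2)


class TestEvaluate:
    def test_perfect_predictions(self):
        r = _evaluate(np.array([0.1, 0.5, 0.9]), np.array([0.1, 0.5, 0.9]))
        assert r.spearman == pytest.approx(1.0)
        assert r.mse == 0.0

    def test_monotone_transform_keeps_rank_one(self):
        y = np.array([0.1, 0.4, 0.7, 0.9])
        r = _evaluate(y**3, y)
        assert r.spearman == pytest.approx(1.0)

    def test_constant_predictions_flagged_not_crashing(self):
        r = _evaluate(np.full(5, 0.5), np.linspace(0, 1, 5))
        assert r.spearman_undefined
        assert np.isnan(r.spearman)

    def test_matches_brute_force_rank_correlation(self, rng):
        def rank(v):
            order = np.argsort(v)
            ranks = np.empty(len(v))
            ranks[order] = np.arange(1, len(v) + 1)
            # average ties
            for val in np.unique(v):
                m = v == val
                ranks[m] = ranks[m].mean()
            return ranks

        for _ in range(10):
            a = rng.choice([0.1, 0.2, 0.2, 0.5, 0.8], size=12)
            b = rng.random(12)
            ra, rb = rank(a), rank(b)
            expected = np.corrcoef(ra, rb)[0, 1]
            assert _evaluate(a, b).spearman == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    from conftest import random_spacer

    spacers = [random_spacer(rng) for _ in range(120)]
    gc = np.array([s.count("G") + s.count("C") for s in spacers])
    y = 0.2 + 0.02 * gc  # exactly linear in a table feature, within [0,1]
    return spacers, y


class TestConventionalKinds:

    def test_linear_fits_noiseless_linear_target_exactly(self, linear_data):
        spacers, y = linear_data
        res = train_model("linear", spacers, y, seed=0)
        assert res.reports["train"].mse < 1e-8

    def test_ridge_approaches_linear_as_penalty_vanishes(self, linear_data):
        spacers, y = linear_data
        lin = train_model("linear", spacers, y, seed=0)
        mses = []
        for alpha in (100.0, 1e-6):
            r = train_model("ridge", spacers, y, seed=0, sk_params={"alpha": alpha})
            mses.append(r.reports["train"].mse)
        assert mses[1] < mses[0]
        assert mses[1] == pytest.approx(lin.reports["train"].mse, abs=1e-6)

    def test_gbt_learns_gc_rule(self, linear_data):
        spacers, y = linear_data
        res = train_model("gbt", spacers, y, seed=0)
        assert res.reports["test"].spearman > 0.8

    def test_activities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            GuideActivityModel(["A" * 20] * 5, [0.1, 0.2, 1.4, 0.3, 0.2])


@pytest.fixture(scope="module")
def fitted():
    spacers, acts, _ = simulate_activity_dataset(250, seed=7)
    res = train_model("rnn_biofeature", spacers, acts, config=FAST, seed=7)
    return spacers, acts, res


class TestNeuralKinds:

    def test_training_learns_signal(self, fitted):
        _, _, res = fitted
        assert res.reports["test"].spearman > 0.3

    def test_reproducible_given_seed(self):
        spacers, acts, _ = simulate_activity_dataset(80, seed=1)
        cfg = NetConfig(max_epochs=3, hidden_dim=6, embed_dim=3, dense_sizes=(8,))
        r1 = train_model("rnn", spacers, acts, config=cfg, seed=4)
        r2 = train_model("rnn", spacers, acts, config=cfg, seed=4)
        assert r1.reports["test"] == r2.reports["test"]

    def test_summary_mentions_kind_and_split(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "rnn_biofeature" in text
        assert "train" in text and "test" in text

    def test_save_load_round_trip_predicts_identically(self, fitted, tmp_path):
        spacers, _, res = fitted
        path = tmp_path / "model.bin"
        res.save(path)
        loaded = ActivityResults.load(path)
        np.testing.assert_allclose(
            loaded.predict(spacers[:10]), res.predict(spacers[:10]), atol=1e-12
        )

    def test_registry_mismatch_refuses_prediction(self, fitted, tmp_path):
        import joblib

        _, _, res = fitted
        path = tmp_path / "model.bin"
        res.save(path)
        payload = joblib.load(path)
        payload["registry_hash"] = "0" * 16
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="registry"):
            ActivityResults.load(path)

    def test_evaluate_model_wrapper_with_indices(self, fitted):
        spacers, acts, res = fitted
        rep = evaluate_model(res, spacers, acts, indices=np.arange(30))
        assert rep.n == 30
        with pytest.raises(ValueError):
            evaluate_model(res, spacers, acts, indices=np.array([], dtype=int))


@pytest.fixture(scope="module")
def base():
    spacers, acts, _ = simulate_activity_dataset(200, seed=2)
    res = train_model("rnn", spacers, acts, config=FAST, seed=2)
    return spacers, acts, res


class TestFineTune:

    def test_scope_freezes_embedding_and_recurrent_weights(self, base):
        spacers, acts, res = base
        tuned = fine_tune(res, spacers, acts, scope="last_hidden_layer", epochs=2)
        for name in ("W_m", "fwd_Wi", "bwd_Uc"):
            np.testing.assert_array_equal(
                tuned.estimator.params[name], res.estimator.params[name]
            )
        assert not np.array_equal(
            tuned.estimator.params["out_W"], res.estimator.params["out_W"]
        )

    def test_zero_epochs_leaves_model_unchanged(self, base):
        spacers, acts, res = base
        tuned = fine_tune(res, spacers, acts, epochs=0)
        for name, arr in res.estimator.params.items():
            np.testing.assert_array_equal(tuned.estimator.params[name], arr)

    def test_fine_tuning_adapts_to_shifted_labels(self, base):
        spacers, acts, res = base
        shifted = np.clip(1.0 - np.asarray(acts), 0, 1)  # rank-reversed task
        frozen = _evaluate(res.predict(spacers), shifted).spearman
        tuned = fine_tune(res, spacers, shifted, epochs=8, seed=3)
        adapted = _evaluate(tuned.predict(spacers), shifted).spearman
        assert adapted > frozen

    def test_unsupported_for_conventional_kind(self):
        spacers, acts, _ = simulate_activity_dataset(60, seed=3)
        res = train_model("linear", spacers, acts, seed=0)
        with pytest.raises(TypeError, match="unsupported"):
            fine_tune(res, spacers, acts)


@pytest.fixture(scope="module")
def data():
    spacers, acts, _ = simulate_activity_dataset(150, seed=5)
    return spacers, acts


class TestSearchAndValidation:

    def test_single_point_budget(self, data):
        spacers, acts = data
        best, trace = hyperparameter_search(
            "ridge", spacers, acts, {"alpha": [1.0]}, budget=(1, 0), seed=0
        )
        assert best == {"alpha": 1.0}
        assert len(trace) == 1

    def test_trace_length_is_budget(self, data):
        spacers, acts = data
        _, trace = hyperparameter_search(
            "ridge", spacers, acts, {"alpha": [0.1, 1.0, 10.0]}, budget=(2, 3), seed=0
        )
        assert len(trace) == 5

    def test_two_point_space_finds_the_better_config(self, data):
        spacers, acts = data
        # absurd regularization vs a reasonable one: ranking is unambiguous
        best, trace = hyperparameter_search(
            "ridge", spacers, acts, {"alpha": [1.0, 1e9]}, budget=(4, 2), seed=1
        )
        assert best == {"alpha": 1.0}
        scored = {t[0]["alpha"]: t[1] for t in trace}
        assert scored[1.0] > scored[1e9]

    def test_zero_budget_rejected(self, data):
        spacers, acts = data
        with pytest.raises(ValueError):
            hyperparameter_search("ridge", spacers, acts, {"alpha": [1.0]}, budget=(0, 0))

    def test_bayesian_strategy_runs(self, data):
        spacers, acts = data
        best, trace = hyperparameter_search(
            "ridge", spacers, acts, {"alpha": [0.01, 1.0, 1e6]},
            budget=(3, 2), strategy="bayesian", seed=2,
        )
        assert len(trace) == 5
        assert best["alpha"] in (0.01, 1.0)

    def test_kfold_returns_k_scores_and_consistent_mean(self, data):
        spacers, acts = data
        mean, sd, scores = kfold_validation("ridge", spacers, acts, k=4, seed=3)
        assert len(scores) == 4
        assert mean == pytest.approx(np.mean(scores))
        assert sd == pytest.approx(np.std(scores))
        assert sd >= 0

    def test_kfold_rejects_small_k(self, data):
        spacers, acts = data
        with pytest.raises(ValueError):
            kfold_validation("ridge", spacers, acts, k=1)
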
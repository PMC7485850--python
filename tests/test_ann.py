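"""Perceptrons: scaling, backpropagation, search, importance."""

import numpy as np
import pandas as pd
import pytest

import multivol as mv
from multivol.ann import RangeScaler, _logistic, predict_records

from conftest import simulate_mv_records


class TestScaling:
    def test_extremes_map_to_unit_interval(self):
        X = np.array([[0.01], [0.6], [1.2]])
        s = RangeScaler.fit(X)
        z = s.transform(X)
        assert z.min() == 0.0 and z.max() == 1.0

    def test_margin(self):
        X = np.array([[0.0], [1.0]])
        z = RangeScaler.fit(X, margin=0.05).transform(X)
        assert z[0, 0] == pytest.approx(0.05) and z[1, 0] == pytest.approx(0.95)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-3, 7, size=(50, 4))
        s = RangeScaler.fit(X, margin=0.1)
        np.testing.assert_allclose(s.inverse(s.transform(X)), X, atol=1e-12)

    def test_constant_variable_rejected(self):
        records = simulate_mv_records(10, 0.0, seed=0)
        records["TX"] = 0
        with pytest.raises(ValueError, match="constant"):
            mv.scale_records(records)


def _teacher_records(n=400, seed=3):
    """Targets produced by a fixed random 4-3-1 logistic network."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 4))
    W1 = rng.normal(0, 2, size=(3, 4)); b1 = rng.normal(0, 1, 3)
    W2 = rng.normal(0, 2, size=3); b2 = 0.1
    y = _logistic(_logistic(X @ W1.T + b1) @ W2 + b2)
    return pd.DataFrame({"DBH": X[:, 0] * 20 + 8, "H": X[:, 1] * 20 + 10,
                         "TX": X[:, 2], "d": X[:, 3] * 20, "V": y,
                         "volume_label": "TVb", "stem_id": "t"})


class TestTrainMLP:
    def test_learns_self_realizable_function(self):
        records = _teacher_records()
        model = mv.train_mlp(records, n_hidden=6, epochs=30000, seed=0,
                             learning_rate=2.0, margin=0.1, tol=1e-12)
        yhat = predict_records(model, records)
        assert mv.r_squared(records["V"], yhat) > 0.999

    def test_zero_learning_rate_freezes_weights(self):
        records = _teacher_records(n=50)
        a = mv.train_mlp(records, n_hidden=4, learning_rate=0.0, epochs=50, seed=7)
        b = mv.train_mlp(records, n_hidden=4, learning_rate=0.0, epochs=1, seed=7)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_seeded_determinism(self):
        records = _teacher_records(n=80)
        a = mv.train_mlp(records, n_hidden=5, epochs=200, seed=11)
        b = mv.train_mlp(records, n_hidden=5, epochs=200, seed=11)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)
        assert a.b2 == b.b2

    def test_error_non_increasing_at_small_rate(self):
        records = _teacher_records(n=100)
        model = mv.train_mlp(records, n_hidden=3, learning_rate=0.2, momentum=0.0,
                             epochs=400, seed=2)
        trace = model.error_trace
        assert np.all(np.diff(trace) <= 1e-12)

    def test_invalid_hidden_count_rejected(self):
        with pytest.raises(ValueError):
            mv.train_mlp(_teacher_records(n=30), n_hidden=11)


class TestPredict:
    def test_three_input_model_rejects_tx(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=2, epochs=10, seed=0,
                             inputs=("DBH", "H", "d"))
        with pytest.raises(ValueError, match="TX"):
            mv.mlp_predict(model, 15.0, 20.0, TX=1, d=5.0)
        assert np.isfinite(mv.mlp_predict(model, 15.0, 20.0, d=5.0))

    def test_prediction_order_invariant(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=3, epochs=100, seed=0)
        fwd = predict_records(model, records)
        rev = predict_records(model, records.iloc[::-1])[::-1]
        np.testing.assert_allclose(fwd, rev, atol=0)

    def test_output_bounded_by_target_scaling(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=3, epochs=100, seed=0)
        with pytest.warns(UserWarning, match="extrapolating"):
            v = mv.mlp_predict(model, 200.0, 100.0, TX=0.0, d=0.0)
        lo = model.target_scaling.inverse(np.array([[0.0]]))[0, 0]
        hi = model.target_scaling.inverse(np.array([[1.0]]))[0, 0]
        assert lo <= v <= hi

    def test_all_zero_weights_give_midrange(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=3, epochs=1, seed=0)
        model.W1[:] = 0; model.b1[:] = 0; model.W2[:] = 0; model.b2 = 0.0
        v = mv.mlp_predict(model, 15.0, 20.0, TX=0.5, d=5.0)
        mid = model.target_scaling.inverse(np.array([[0.5]]))[0, 0]
        assert v == pytest.approx(mid)


class TestSearch:
    def test_single_trial_retained(self):
        records = _teacher_records(n=60)
        res = mv.architecture_search(records, n_trials=1, retain=1, seed=0, epochs=20)
        assert len(res.retained) == 1 and len(res.log) == 1

    def test_search_determinism(self):
        records = _teacher_records(n=80)
        a = mv.architecture_search(records, n_trials=6, retain=3, seed=4, epochs=30)
        b = mv.architecture_search(records, n_trials=6, retain=3, seed=4, epochs=30)
        pd.testing.assert_frame_equal(a.log, b.log)

    def test_retained_sorted_with_tie_breaks(self):
        records = _teacher_records(n=80)
        res = mv.architecture_search(records, n_trials=10, retain=5, seed=1, epochs=30)
        errors = [e for _, e in res.retained]
        assert errors == sorted(errors)
        assert len(res.retained) == 5
        assert (res.log["error"] >= errors[-1] - 1e-15).sum() >= len(res.log) - 5

    def test_invalid_parameters_rejected(self):
        records = _teacher_records(n=30)
        with pytest.raises(ValueError):
            mv.architecture_search(records, n_trials=2, retain=5)
        with pytest.raises(ValueError):
            mv.architecture_search(records, n_trials=5, validation_fraction=0.9)


class TestImportance:
    def test_shares_sum_to_one_and_nonnegative(self):
        records = _teacher_records(n=80)
        model = mv.train_mlp(records, n_hidden=5, epochs=200, seed=0)
        imp = mv.variable_importance(model)
        shares = np.array([s for _, s in imp])
        assert np.all(shares >= 0)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_input_has_zero_importance(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=4, epochs=5, seed=0)
        k = list(model.input_names).index("TX")
        model.W1[:, k] = 0.0
        imp = dict(mv.variable_importance(model))
        assert imp["TX"] == 0.0

    def test_single_input_importance_is_one(self):
        records = _teacher_records(n=60)
        model = mv.train_mlp(records, n_hidden=3, epochs=10, seed=0, inputs=("DBH",))
        assert mv.variable_importance(model) == [("DBH", 1.0)]

    def test_dbh_dominates_on_simulated_volumes(self):
        first = []
        for rep in range(10):
            records = simulate_mv_records(80, 0.05, seed=700 + rep)
            model = mv.train_mlp(records, n_hidden=5, epochs=4000, seed=rep, margin=0.1)
            first.append(mv.variable_importance(model)[0][0])
        assert sum(name == "DBH" for name in first) >= 9
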
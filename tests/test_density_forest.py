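"""Forest estimation: node-size rule, mtry tuning, OOB statistics,
permutation importance and iterative covariate elimination."""

import numpy as np
import pandas as pd
import pytest

from popforest import (
    ForestParams,
    forest_summary,
    grow_forest,
    make_signal_noise_table,
    select_covariates,
    terminal_node_cap,
    tune_mtry,
)
from popforest.training_table import TrainingTable


def constant_response_table(n=20, c=3.5, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "count": np.full(n, int(round(np.exp(c)))),
            "area_km2": 1.0,
            "response": c,
            "x1": rng.uniform(size=n),
            "x2": rng.uniform(size=n),
        },
        index=pd.Index([f"U{i}" for i in range(n)], name="unit_id"),
    )
    return TrainingTable(data)


class TestNodeCap:
    @pytest.mark.parametrize(
        "n,expected",
        [(800, 1), (999, 1), (1000, 1), (1500, 2), (2500, 2), (3500, 4), (4501, 5)],
    )
    def test_round_half_even_rule(self, n, expected):
        # round-half-to-even: 2500/1000 -> 2, 3500/1000 -> 4
        assert terminal_node_cap(n) == expected


class TestGrowForest:
    def test_constant_response_predicts_constant(self):
        table = constant_response_table(c=2.0)
        model = grow_forest(table, ForestParams(n_trees=30, seed=1))
        pred = model.predict_log(table.X)
        np.testing.assert_allclose(pred, 2.0)
        assert model.oob_mse == 0.0

    def test_predictions_confined_to_response_range(self):
        table = make_signal_noise_table(n=100, n_noise=2, seed=4)
        model = grow_forest(table, ForestParams(n_trees=50, seed=4))
        rng = np.random.default_rng(0)
        X = rng.uniform(-10, 10, size=(500, len(table.covariate_names)))
        pred = model.predict_log(X)
        lo, hi = model.response_range
        assert (pred >= lo).all() and (pred <= hi).all()

    def test_deterministic_given_seed(self):
        table = make_signal_noise_table(n=80, n_noise=3, seed=7)
        a = grow_forest(table, ForestParams(n_trees=40, seed=9))
        b = grow_forest(table, ForestParams(n_trees=40, seed=9))
        np.testing.assert_array_equal(
            a.predict_log(table.X), b.predict_log(table.X)
        )
        pd.testing.assert_frame_equal(a.importance, b.importance)
        assert a.oob_mse == b.oob_mse

    def test_shallow_trees_cannot_beat_deep_on_strong_signal(self):
        wins = 0
        for seed in range(5):
            table = make_signal_noise_table(n=150, n_noise=1, sigma=0.1, seed=seed)
            deep = grow_forest(table, ForestParams(n_trees=60, node_cap=1, seed=seed))
            shallow = grow_forest(
                table, ForestParams(n_trees=60, node_cap=150, seed=seed)
            )
            wins += shallow.oob_mse >= deep.oob_mse
        assert wins >= 4  # monotone capacity property, majority of seeds

    def test_null_importance_centred_on_zero(self):
        # covariates independent of a fully-explained response: importance
        # distributed around zero, mean within 2 SE over repeated fits
        vals = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 120
            signal = rng.uniform(size=n)
            data = pd.DataFrame(
                {
                    "count": 100,
                    "area_km2": 1.0,
                    "response": 2.0 + signal,
                    "signal": signal,
                    "a": rng.uniform(size=n),
                    "b": rng.uniform(size=n),
                },
                index=pd.Index([f"U{i}" for i in range(n)], name="unit_id"),
            )
            model = grow_forest(
                TrainingTable(data), ForestParams(n_trees=150, seed=seed, mtry=3)
            )
            vals += [
                model.importance.loc["a", "permutation"],
                model.importance.loc["b", "permutation"],
            ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * se
        # and the null scores are negligible next to the signal's
        assert np.abs(vals).max() < 0.01 * model.importance.loc["signal", "permutation"]

    def test_pure_noise_model_explains_nothing(self):
        ves = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 100
            data = pd.DataFrame(
                {
                    "count": 100,
                    "area_km2": 1.0,
                    "response": rng.normal(size=n),
                    "a": rng.uniform(size=n),
                    "b": rng.uniform(size=n),
                },
                index=pd.Index([f"U{i}" for i in range(n)], name="unit_id"),
            )
            model = grow_forest(TrainingTable(data), ForestParams(n_trees=100, seed=seed))
            ves.append(model.oob_var_explained)
        assert np.mean(ves) <= 0.1


class TestTuneMtry:
    def test_single_covariate_always_one(self):
        table = make_signal_noise_table(n=60, n_noise=0, seed=0)
        assert tune_mtry(table, ForestParams(seed=0)) == 1

    def test_infinite_improve_threshold_returns_start(self):
        table = make_signal_noise_table(n=80, n_noise=8, seed=1)
        p = len(table.covariate_names)
        start = max(1, p // 3)
        got = tune_mtry(
            table, ForestParams(seed=1, n_trees=50, tune_improve=np.inf)
        )
        assert got == start

    def test_signal_among_noise_pushes_mtry_up(self):
        # response equals one covariate among 9 noise columns: larger mtry
        # finds the signal column more often, so tuning moves above p/3
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            signal = rng.uniform(size=n)
            data = pd.DataFrame(
                {"count": 100, "area_km2": 1.0, "response": signal, "signal": signal},
                index=pd.Index([f"U{i}" for i in range(n)], name="unit_id"),
            )
            for k in range(9):
                data[f"n{k}"] = rng.uniform(size=n)
            table = TrainingTable(data)
            tuned = tune_mtry(table, ForestParams(seed=seed, n_trees=100))
            hits += tuned > 10 // 3
        assert hits >= 8

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            tune_mtry(constant_response_table(), ForestParams())


class TestSelectCovariates:
    def test_single_positive_covariate_kept(self):
        table = make_signal_noise_table(n=80, n_noise=0, seed=3)
        reduced, model, history = select_covariates(
            table, ForestParams(n_trees=50, seed=3)
        )
        assert reduced.covariate_names == ["signal"]
        assert len(history) == 1

    def test_duplicate_signal_never_rejects_everything(self):
        table = make_signal_noise_table(n=80, n_noise=0, seed=5)
        table.data["signal_copy"] = table.data["signal"]
        table = TrainingTable(table.data)
        reduced, model, _ = select_covariates(table, ForestParams(n_trees=50, seed=5))
        assert len(reduced.covariate_names) >= 1
        assert (model.importance["permutation"] > 0).all() or len(
            reduced.covariate_names
        ) == 1

    def test_noise_eliminated_quickly_strong_signal(self):
        # mirror of the documented behaviour: converges in one or two passes
        good = 0
        for seed in range(6):
            table = make_signal_noise_table(n=150, n_noise=5, sigma=0.2, seed=seed)
            reduced, model, history = select_covariates(
                table, ForestParams(n_trees=150, seed=seed)
            )
            noise_left = [c for c in reduced.covariate_names if c.startswith("noise")]
            good += (not noise_left) and len(history) <= 2
        assert good >= 5


class TestForestSummary:
    def test_signal_ranked_first_and_json_round_trip(self):
        import json

        table = make_signal_noise_table(n=120, n_noise=3, sigma=0.1, seed=6)
        model = grow_forest(table, ForestParams(n_trees=80, seed=6))
        report = forest_summary(model)
        assert report["importance"][0]["covariate"] == "signal"
        again = json.loads(json.dumps(report))
        assert again == report
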
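"""Federated strategies: voting, parameter averaging, the FedAvg loop, the
volume-weighted ensemble, and strategy construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from fedcpm.federation import (
    EnsembleModel,
    FedAvgConfig,
    StrategyConfig,
    build_strategy,
    ensemble_predict,
    fedavg_aggregate,
    fedavg_train,
    fit_recalibration_federated,
    vote_select_variables,
)
from fedcpm.model_core import FitFailure, FittedModel, fit_lasso_logistic, fit_recalibration, predict_proba
from fedcpm.synthetic_cohort import CohortTable, generate_cohort, iid_config


class TestFedAvgConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            FedAvgConfig(learning_rate=-0.1)
        with pytest.raises(ValueError):
            FedAvgConfig(max_epochs=0)
        with pytest.raises(ValueError):
            FedAvgConfig(agreement_strength=1.5)


class TestVoting:
    WEIGHTS = {"A": 0.5, "B": 0.3, "C": 0.2}
    SELECTIONS = {"A": {"age", "sex"}, "B": {"age"}, "C": {"sex", "bmi"}}

    def test_union_at_zero(self):
        assert vote_select_variables(self.SELECTIONS, self.WEIGHTS, tau=0.0) == [
            "age", "bmi", "sex",
        ]

    def test_intersection_at_one(self):
        sels = {"A": {"age", "sex"}, "B": {"age"}, "C": {"age", "bmi"}}
        assert vote_select_variables(sels, self.WEIGHTS, tau=1.0) == ["age"]

    def test_weighted_threshold(self):
        # support: age 0.8, sex 0.7, bmi 0.2
        assert vote_select_variables(self.SELECTIONS, self.WEIGHTS, tau=0.5) == [
            "age", "sex",
        ]
        assert vote_select_variables(self.SELECTIONS, self.WEIGHTS, tau=0.75) == ["age"]

    def test_threshold_boundary_inclusive(self):
        assert "sex" in vote_select_variables(self.SELECTIONS, self.WEIGHTS, tau=0.7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vote_select_variables({}, {}, 0.5)
        with pytest.raises(ValueError):
            vote_select_variables({"A": {"x"}}, {"A": 0.7}, 0.5)


class TestAggregate:
    def test_weighted_mean(self):
        m1 = FittedModel(-1.0, {"a": 1.0}, ["a"])
        m2 = FittedModel(-3.0, {"a": 3.0}, ["a"])
        agg = fedavg_aggregate([m1, m2], [0.75, 0.25])
        assert agg.intercept == pytest.approx(-1.5)
        assert agg.coefficients["a"] == pytest.approx(1.5)

    def test_mismatched_variable_sets_rejected(self):
        m1 = FittedModel(0.0, {"a": 1.0}, ["a"])
        m2 = FittedModel(0.0, {"b": 1.0}, ["b"])
        with pytest.raises(ValueError):
            fedavg_aggregate([m1, m2], [0.5, 0.5])

    def test_weights_must_sum_to_one(self):
        m = FittedModel(0.0, {"a": 1.0}, ["a"])
        with pytest.raises(ValueError):
            fedavg_aggregate([m, m], [0.5, 0.4])


def _center_data(seed=0, n_centers=4, n_per=400, beta=(0.8, -0.5)):
    rng = np.random.default_rng(seed)
    data = {}
    for c in range(n_centers):
        X = pd.DataFrame(rng.normal(size=(n_per, 2)), columns=["a", "b"])
        y = rng.binomial(1, expit(-1.0 + X.to_numpy() @ np.array(beta)))
        data[chr(ord("A") + c)] = (X, y)
    return data


class TestFedavgTrain:
    def test_zero_learning_rate_is_a_no_op(self):
        data = _center_data()
        model = fedavg_train(data, ["a", "b"], FedAvgConfig(learning_rate=0.0, max_epochs=5))
        rate = np.mean(np.concatenate([y for _, y in data.values()]))
        assert model.intercept == pytest.approx(logit(rate), abs=1e-12)
        assert all(v == 0.0 for v in model.coefficients.values())

    def test_iid_partitions_converge_to_pooled_fit(self):
        data = _center_data(seed=1)
        model = fedavg_train(
            data, ["a", "b"], FedAvgConfig(learning_rate=1.0, max_epochs=3000,
                                           convergence_tol=1e-9),
        )
        Xp = pd.concat([X for X, _ in data.values()], ignore_index=True)
        yp = np.concatenate([y for _, y in data.values()])
        pooled = fit_lasso_logistic(Xp, yp, lam=0.0)
        assert model.intercept == pytest.approx(pooled.intercept, abs=1e-3)
        for v in ("a", "b"):
            assert model.coefficients[v] == pytest.approx(pooled.coefficients[v], abs=1e-3)

    def test_single_class_centers_skipped_and_recorded(self):
        data = _center_data(seed=2, n_centers=3)
        X, y = data["C"]
        data["C"] = (X, np.zeros_like(y))
        model = fedavg_train(data, ["a", "b"], FedAvgConfig(max_epochs=50))
        assert "C" in model.training_meta["skipped_centers"]
        assert model.training_meta["n"] == 800

    def test_all_degenerate_centers_fail(self):
        data = _center_data(seed=3, n_centers=2)
        data = {c: (X, np.zeros_like(y)) for c, (X, y) in data.items()}
        with pytest.raises(FitFailure):
            fedavg_train(data, ["a"], FedAvgConfig())

    def test_deterministic(self):
        data = _center_data(seed=4)
        cfg = FedAvgConfig(max_epochs=100)
        m1 = fedavg_train(data, ["a", "b"], cfg)
        m2 = fedavg_train(data, ["a", "b"], cfg)
        assert m1.intercept == m2.intercept
        assert m1.coefficients == m2.coefficients


class TestFederatedRecalibration:
    def test_agrees_with_central_recalibration(self):
        rng = np.random.default_rng(5)
        preds, ys = {}, {}
        for c in "ABCD":
            p = rng.uniform(0.05, 0.5, 800)
            preds[c] = p
            ys[c] = rng.binomial(1, expit(0.5 + 1.2 * logit(p)))
        fed = fit_recalibration_federated(preds, ys)
        central = fit_recalibration(
            np.concatenate(list(preds.values())), np.concatenate(list(ys.values()))
        )
        assert fed.a == pytest.approx(central.a, abs=0.02)
        assert fed.b == pytest.approx(central.b, abs=0.02)


class TestEnsemble:
    def test_weighted_mean_of_members(self):
        m1 = FittedModel(0.0, {"a": 1.0}, ["a"])
        m2 = FittedModel(1.0, {"a": -1.0}, ["a"])
        ens = EnsembleModel({"A": m1, "B": m2}, {"A": 0.25, "B": 0.75})
        X = pd.DataFrame({"a": [0.0, 1.0]})
        expected = 0.25 * predict_proba(m1, X) + 0.75 * predict_proba(m2, X)
        np.testing.assert_allclose(ensemble_predict(ens, X), expected)

    def test_recalibration_applied_after_averaging(self):
        m = FittedModel(0.0, {"a": 1.0}, ["a"])
        from fedcpm.model_core import RecalibrationFunction

        ens = EnsembleModel({"A": m}, {"A": 1.0},
                            recalibration=RecalibrationFunction(0.5, 2.0))
        X = pd.DataFrame({"a": [0.3]})
        raw = predict_proba(m, X)
        np.testing.assert_allclose(
            ensemble_predict(ens, X), expit(0.5 + 2.0 * logit(raw))
        )

    def test_validation(self):
        m = FittedModel(0.0, {"a": 1.0}, ["a"])
        with pytest.raises(ValueError):
            EnsembleModel({}, {})
        with pytest.raises(ValueError):
            EnsembleModel({"A": m}, {"B": 1.0})
        with pytest.raises(ValueError):
            EnsembleModel({"A": m}, {"A": 0.8})


class TestBuildStrategy:
    CFG = StrategyConfig(lam=0.02)

    def test_unknown_strategy_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            build_strategy("stacking", small_cohort, self.CFG)

    def test_central_builds_single_model(self, small_cohort):
        sm_ = build_strategy("central", small_cohort, self.CFG)
        p = sm_.predict(small_cohort.predictors)
        assert p.shape == (small_cohort.n,)
        assert ((p > 0) & (p < 1)).all()

    def test_local_builds_one_model_per_hospital(self, small_cohort):
        sm_ = build_strategy("local", small_cohort, self.CFG)
        assert set(sm_.model) == set(small_cohort.hospitals())
        p = sm_.predict(
            small_cohort.predictors, hospital_ids=small_cohort.hospital_id.to_numpy()
        )
        assert np.isfinite(p).all()

    def test_local_prediction_requires_hospital_ids(self, small_cohort):
        sm_ = build_strategy("local", small_cohort, self.CFG)
        with pytest.raises(ValueError):
            sm_.predict(small_cohort.predictors)

    def test_local_failed_center_predicts_nan(self, small_cohort):
        df = small_cohort.data.copy()
        df.loc[df["hospital_id"] == "F", "outcome"] = 0  # no events at F
        crippled = CohortTable(df, dict(small_cohort.kinds))
        sm_ = build_strategy("local", crippled, self.CFG)
        assert "F" in sm_.failures
        p = sm_.predict(crippled.predictors, hospital_ids=crippled.hospital_id.to_numpy())
        f_mask = (crippled.hospital_id == "F").to_numpy()
        assert np.isnan(p[f_mask]).all()
        assert np.isfinite(p[~f_mask]).all()

    def test_fedavg_votes_then_trains(self, small_cohort):
        sm_ = build_strategy("fedavg", small_cohort, self.CFG)
        assert sm_.meta["voted_variables"] == sm_.model.selected_variables
        p = sm_.predict(small_cohort.predictors)
        assert ((p > 0) & (p < 1)).all()

    def test_ensemble_volume_weights(self, small_cohort):
        sm_ = build_strategy("ensemble", small_cohort, self.CFG)
        sizes = {h: small_cohort.center(h).n for h in small_cohort.hospitals()}
        total = sum(sizes.values())
        for h, w in sm_.model.weights.items():
            assert w == pytest.approx(sizes[h] / total)

    def test_recalibration_none_leaves_raw_model(self, small_cohort):
        cfg = StrategyConfig(lam=0.02, recalibration=None)
        sm_ = build_strategy("fedavg", small_cohort, cfg)
        assert sm_.model.recalibration is None

    def test_recalibration_modes_produce_recalibrators(self, small_cohort):
        for mode in ("central", "local", "federated"):
            cfg = StrategyConfig(lam=0.02, recalibration=mode)
            sm_ = build_strategy("ensemble", small_cohort, cfg)
            assert sm_.model.recalibration is not None
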
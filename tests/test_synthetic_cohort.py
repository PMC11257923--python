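"""Generator: configuration invariants, prevalence calibration, determinism,
missingness mechanism, and table IO."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fedcpm.metrics import auc
from fedcpm.synthetic_cohort import (
    CohortTable,
    ConfigurationError,
    GeneratorConfig,
    PredictorSpec,
    analytic_prevalence,
    default_config,
    generate_cohort,
    iid_config,
    inject_missingness,
    true_risk,
)


@pytest.fixture(scope="module")
def registry_config():
    return default_config(seed=101)


@pytest.fixture(scope="module")
def registry_cohort(registry_config):
    return generate_cohort(registry_config)


# ---------------------------------------------------------------------------
# Configuration invariants
# ---------------------------------------------------------------------------

class TestConfigValidation:
    def test_predictor_kind_must_be_known(self):
        with pytest.raises(ConfigurationError):
            PredictorSpec("bad", "categorical")

    def test_binary_predictor_needs_prevalence(self):
        with pytest.raises(ConfigurationError):
            PredictorSpec("b", "binary")

    def test_threshold_predictor_needs_source(self):
        with pytest.raises(ConfigurationError):
            PredictorSpec("t", "threshold", threshold=0.5)

    def test_size_length_mismatch_rejected(self):
        cfg = iid_config(n_records=100, n_hospitals=2, n_predictors=3)
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            replace(cfg, hospital_sizes=(100,)).validate()

    def test_beta_length_mismatch_rejected(self):
        cfg = iid_config(n_records=100, n_hospitals=2, n_predictors=3)
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            replace(cfg, beta=(0.0,)).validate()

    def test_mar_driver_must_exist_and_never_be_missing(self):
        cfg = iid_config(n_records=100, n_hospitals=2, n_predictors=3)
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            replace(cfg, mar_drivers=("nope",)).validate()
        bad = replace(cfg, mar_drivers=("x00",), missing_rates=(0.2, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            bad.validate()

    def test_prevalence_span_ordering_enforced(self):
        cfg = iid_config(n_records=100, n_hospitals=2, n_predictors=3)
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            replace(cfg, prevalence_span=(0.06, 0.01)).validate()


# ---------------------------------------------------------------------------
# Registry-like default: scale and prevalence structure
# ---------------------------------------------------------------------------

class TestDefaultConfig:
    def test_registry_scale(self, registry_config):
        assert registry_config.n_hospitals == 16
        assert sum(registry_config.hospital_sizes) == 16661
        assert registry_config.n_predictors == 33

    def test_mixed_predictor_types(self, registry_config):
        kinds = [p.kind for p in registry_config.predictors]
        assert kinds.count("continuous") == 13
        assert kinds.count("threshold") == 1
        assert kinds.count("binary") == 19

    def test_analytic_prevalence_span_pinned(self, registry_config):
        prevs = [
            analytic_prevalence(registry_config, c)
            for c in range(registry_config.n_hospitals)
        ]
        assert min(prevs) == pytest.approx(0.012, abs=1e-9)
        assert max(prevs) == pytest.approx(0.058, abs=1e-9)

    def test_analytic_weighted_mean_prevalence(self, registry_config):
        sizes = np.array(registry_config.hospital_sizes, float)
        prevs = np.array(
            [
                analytic_prevalence(registry_config, c)
                for c in range(registry_config.n_hospitals)
            ]
        )
        assert float(sizes @ prevs / sizes.sum()) == pytest.approx(0.034, abs=1e-9)

    def test_prevalence_not_monotone_in_volume(self, registry_config):
        prevs = [
            analytic_prevalence(registry_config, c)
            for c in range(registry_config.n_hospitals)
        ]
        # sizes are decreasing; prevalence must not simply follow them
        diffs = np.diff(prevs)
        assert (diffs > 0).any() and (diffs < 0).any()


class TestAnalyticPrevalence:
    def test_matches_monte_carlo(self):
        cfg = iid_config(
            n_records=200_000, n_hospitals=1, seed=3,
            beta={"x00": 0.5, "x12": 0.8}, n_predictors=15, prevalence=0.08,
        )
        table = generate_cohort(cfg)
        expected = analytic_prevalence(cfg, 0)
        emp = table.outcome.mean()
        se = np.sqrt(expected * (1 - expected) / table.n)
        assert abs(emp - expected) < 4 * se

    def test_no_signal_collapses_to_intercept(self):
        cfg = iid_config(n_records=100, n_hospitals=2, n_predictors=4, prevalence=0.10)
        assert analytic_prevalence(cfg, 0) == pytest.approx(0.10, abs=1e-12)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = iid_config(n_records=300, n_hospitals=3, seed=9, n_predictors=6)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_seed_changes_data(self):
        c1 = generate_cohort(iid_config(n_records=300, n_hospitals=3, seed=1, n_predictors=6))
        c2 = generate_cohort(iid_config(n_records=300, n_hospitals=3, seed=2, n_predictors=6))
        assert not c1.data.drop(columns=["record_id", "hospital_id", "year"]).equals(
            c2.data.drop(columns=["record_id", "hospital_id", "year"])
        )

    def test_sizes_and_labels(self, registry_cohort):
        counts = registry_cohort.data["hospital_id"].value_counts()
        assert counts["A"] == 1850 and counts["P"] == 111
        assert registry_cohort.n == 16661

    def test_empirical_prevalence_near_target(self, registry_cohort):
        rate = registry_cohort.outcome.mean()
        se = np.sqrt(0.034 * 0.966 / registry_cohort.n)
        assert abs(rate - 0.034) < 4 * se

    def test_threshold_predictor_consistent_with_source(self, registry_cohort):
        df = registry_cohort.data
        np.testing.assert_array_equal(
            df["bsa_low"].to_numpy(), (df["bsa"] < -0.8).to_numpy(dtype=float)
        )

    def test_outcome_depends_on_predictors(self, registry_config, registry_cohort):
        risks = [
            true_risk(row, h, registry_config)
            for row, h in zip(
                registry_cohort.predictors.to_numpy()[:4000],
                registry_cohort.data["hospital_id"][:4000],
            )
        ]
        assert auc(risks, registry_cohort.outcome[:4000]) > 0.60

    def test_late_starting_hospitals(self, registry_cohort):
        years = registry_cohort.data.groupby("hospital_id")["year"].min()
        assert years["N"] == 2018 and years["O"] == 2019 and years["P"] == 2019
        assert years["A"] == 2013

    def test_low_volume_tail_years(self, registry_cohort):
        # front-loaded year weights leave the late centers below 10/year later on
        counts = (
            registry_cohort.data[registry_cohort.data["hospital_id"] == "O"]
            .groupby("year").size()
        )
        assert (counts < 10).any()


class TestTrueRisk:
    def test_closed_form(self):
        cfg = iid_config(n_records=10, n_hospitals=1, n_predictors=2,
                         beta={"x00": 1.0}, prevalence=0.5)
        x = np.array([2.0, 5.0])
        assert true_risk(x, "A", cfg) == pytest.approx(expit(2.0), abs=1e-12)

    def test_rejects_wrong_length(self):
        cfg = iid_config(n_records=10, n_hospitals=1, n_predictors=3)
        with pytest.raises(ValueError):
            true_risk([1.0], "A", cfg)

    def test_rejects_missing_values(self):
        cfg = iid_config(n_records=10, n_hospitals=1, n_predictors=2)
        with pytest.raises(ValueError):
            true_risk([np.nan, 1.0], "A", cfg)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def masked(registry_config):
    table = generate_cohort(registry_config)
    return inject_missingness(table, registry_config)


class TestInjectMissingness:
    def test_rates_match_configuration(self, masked, registry_config):
        frac = masked.missing_mask.mean()
        for name, rate in zip(
            registry_config.predictor_names, registry_config.missing_rates
        ):
            assert frac[name] == pytest.approx(rate, abs=0.02)

    def test_one_variable_above_exclusion_threshold(self, masked):
        frac = masked.missing_mask.mean()
        assert (frac > 0.30).sum() >= 1
        assert frac["frailty_status"] > 0.30

    def test_outcome_and_drivers_never_missing(self, masked, registry_config):
        assert not masked.data["outcome"].isna().any()
        for drv in registry_config.mar_drivers:
            assert not masked.data[drv].isna().any()

    def test_missingness_depends_on_drivers(self, masked):
        # MAR: masking probability increases with the driver score
        z = masked.data["age_std"].to_numpy()
        m = masked.data["lvef"].isna().to_numpy()
        hi, lo = m[z > np.median(z)].mean(), m[z <= np.median(z)].mean()
        assert hi > lo + 0.02

    def test_deterministic(self, registry_config):
        t = generate_cohort(registry_config)
        a = inject_missingness(t, registry_config)
        b = inject_missingness(t, registry_config)
        pd.testing.assert_frame_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# CohortTable structure and IO
# ---------------------------------------------------------------------------

class TestCohortTable:
    def test_duplicate_record_ids_rejected(self):
        df = pd.DataFrame(
            {"record_id": ["a", "a"], "hospital_id": ["A", "A"], "outcome": [0, 1],
             "x": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            CohortTable(df)

    def test_nonbinary_outcome_rejected(self):
        df = pd.DataFrame(
            {"record_id": ["a", "b"], "hospital_id": ["A", "A"], "outcome": [0, 2],
             "x": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            CohortTable(df)

    def test_missing_outcome_rejected(self):
        df = pd.DataFrame(
            {"record_id": ["a", "b"], "hospital_id": ["A", "A"],
             "outcome": [0.0, np.nan], "x": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            CohortTable(df)

    def test_subset_and_center(self, tiny_table):
        sub = tiny_table.center("A")
        assert set(sub.data["hospital_id"]) == {"A"}
        assert sub.n == 20

    def test_drop_variables(self, tiny_table):
        dropped = tiny_table.drop_variables(["v"])
        assert "v" not in dropped.predictor_names
        assert "v" not in dropped.kinds

    def test_csv_round_trip(self, tmp_path, missing_cohort):
        path = tmp_path / "cohort.csv"
        missing_cohort.to_csv(path)
        back = CohortTable.read_csv(path)
        assert back.kinds == missing_cohort.kinds
        assert back.n == missing_cohort.n
        a = missing_cohort.data.reset_index(drop=True)
        b = back.data.reset_index(drop=True)
        np.testing.assert_allclose(
            a[missing_cohort.predictor_names].to_numpy(),
            b[missing_cohort.predictor_names].to_numpy(),
            rtol=0, atol=1e-12,
        )
        assert (a["record_id"] == b["record_id"]).all()
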